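"""Propensity model fitting and inverse-probability weight construction."""

import numpy as np
import pandas as pd
import pytest

import stochmsm as sm
from stochmsm import _engine
from stochmsm._engine import LogisticFit
from stochmsm.ipw import (
    censoring_weight,
    combine_and_truncate,
    compute_ipw_weights,
    fit_propensity_models,
    treatment_weight,
)
from stochmsm.regimens import LONGER_TERM, SHORT_TERM, discontinuation_law, evaluate_compliance


class TestModelFitting:
    def test_continuation_coefficients_recovered(self, default_cohort):
        """On a 20,000-subject panel the continuation model recovers the
        generating coefficients within 3 standard errors."""
        models = fit_propensity_models(default_cohort)
        fit = models.continuation
        tm = default_cohort.config.treatment
        truth = {
            "const": tm.continuation_intercept,
            "L_obs": tm.cont_L,
            "frailty": tm.cont_frailty,
            "cum_prev": tm.cont_cumulative,
            "L_imputed": 0.0,
            "age_std": 0.0,
            "t": 0.0,
            "time_since_meas": 0.0,
        }
        for f, b, se in zip(fit.features, fit.coef, fit.se):
            assert abs(b - truth[f]) < 3 * se, (f, b, truth[f], se)

    def test_solver_matches_statsmodels(self, small_cohort):
        """The in-package Newton solver agrees with statsmodels GLM."""
        statsmodels = pytest.importorskip("statsmodels.api")
        pa = _engine.panel_arrays_from_cohort(small_cohort)
        fidx = {f: k for k, f in enumerate(_engine.FEATURES)}
        mask = _engine._model_fit_mask(pa, "continuation")
        i, j = np.nonzero(mask)
        feats = _engine.MODEL_FEATURES["continuation"]
        X = pa.F[i, j][:, [fidx[f] for f in feats]]
        y = _engine._model_response(pa, "continuation")[i, j].astype(float)
        beta, se = _engine.fit_logistic(X, y)
        ref = statsmodels.GLM(y, X, family=statsmodels.families.Binomial()).fit()
        assert np.allclose(beta, ref.params, atol=1e-6)
        assert np.allclose(se, ref.bse, rtol=1e-4, atol=1e-6)

    def test_cause_with_zero_events_flagged_degenerate(self):
        cfg = sm.scaled_config(500, seed=2)
        cfg.censoring.disenroll_intercept = -60.0
        panel = sm.simulate_cohort(cfg)
        models = fit_propensity_models(panel)
        assert models.disenroll.degenerate
        assert models.disenroll.constant_p == 0.0
        # degenerate cause contributes probability 0, i.e. factor 1, downstream
        cw = censoring_weight(panel, models)
        assert np.isfinite(cw["censoring_weight"]).all()

    def test_fair_coin_treatment_recovers_half(self):
        cfg = sm.DGPConfig(n_subjects=4000, seed=3)
        for f in ("initiation", "reinitiation", "continuation"):
            setattr(cfg.treatment, f + "_intercept", 0.0)
        cfg.treatment.init_L = cfg.treatment.cont_L = 0.0
        cfg.treatment.init_frailty = cfg.treatment.cont_frailty = 0.0
        cfg.treatment.cont_cumulative = 0.0
        panel = sm.simulate_cohort(cfg)
        pa = _engine.panel_arrays_from_cohort(panel)
        fits = _engine.fit_panel_models(pa)
        p_cont = _engine.predict_cells(pa, fits["continuation"])
        sel = pa.valid & pa.prev_on
        assert abs(p_cont[sel].mean() - 0.5) < 0.01


def _stub_models(p_init, p_cont, p_cens=0.0):
    """Constant-probability model set built from degenerate fits."""
    mk = lambda name, p: LogisticFit(name, (), np.zeros(0), np.zeros(0), 0, 0, True, p)
    return {
        "initiation": mk("initiation", p_init),
        "continuation": mk("continuation", p_cont),
        "death": mk("death", p_cens),
        "disenroll": mk("disenroll", 0.0),
        "exclusion": mk("exclusion", 0.0),
    }


def _panel_from_sequences(seqs, events=None):
    rows = []
    for sid, seq in enumerate(seqs):
        ev_q = events.get(sid) if events else None
        for t, a in enumerate(seq, start=1):
            rows.append(
                {
                    "subject_id": sid,
                    "t": t,
                    "on_treatment": a,
                    "cumulative_on_quarters": sum(seq[:t]),
                    "L": -2.5,
                    "L_obs": -2.5,
                    "L_category": "-2.5_to_-2.9",
                    "L_imputed": 0,
                    "time_since_meas": t,
                    "age": 70.0,
                    "frailty": 0,
                    "event": int(ev_q == t),
                    "censor_cause": "none",
                }
            )
    return pd.DataFrame(rows)


class TestTreatmentWeight:
    def test_identity_when_fitted_equals_intervention(self):
        """Fitted probabilities equal to the law's at every quarter give
        weight exactly 1."""
        # a subject off from entry under the short-term law: intervention
        # probs are 1/12 at t=1 then 1 thereafter
        panel = _panel_from_sequences([[0, 0, 0]])
        from stochmsm.ipw import PropensityModelSet

        stubs = _stub_models(p_init=11 / 12, p_cont=0.5)
        models = PropensityModelSet(**{
            "continuation": stubs["continuation"], "initiation": stubs["initiation"],
            "death": stubs["death"], "disenroll": stubs["disenroll"],
            "exclusion": stubs["exclusion"], "admin_end": stubs["death"],
        })
        spec = discontinuation_law(SHORT_TERM)
        compliance = evaluate_compliance(panel, spec)
        tw = treatment_weight(panel, models, compliance, SHORT_TERM)
        # t=1: num = 1/12, den = 1 - 11/12 = 1/12 -> 1; later: num 1, den 1 - p_reinit
        assert tw["treatment_weight"].iloc[0] == pytest.approx(1.0)

    def test_hand_product_two_quarters(self):
        """Two-quarter discontinuer against fitted probs (0.2, 0.5): the
        cumulative weight is the hand-computed product of ratios."""
        panel = _panel_from_sequences([[0, 0]])
        from stochmsm.ipw import PropensityModelSet

        stubs = _stub_models(p_init=0.8, p_cont=0.5)
        # observed off at t=1: num 1/12, den 1-0.8 = 0.2
        # observed off at t=2 (prior off -> initiation model): num 1, den 1-0.8
        models = PropensityModelSet(**{
            "continuation": stubs["continuation"], "initiation": stubs["initiation"],
            "death": stubs["death"], "disenroll": stubs["disenroll"],
            "exclusion": stubs["exclusion"], "admin_end": stubs["death"],
        })
        spec = discontinuation_law(SHORT_TERM)
        compliance = evaluate_compliance(panel, spec)
        tw = treatment_weight(panel, models, compliance, SHORT_TERM)
        w1 = (1 / 12) / 0.2
        w2 = w1 * (1.0 / 0.2)
        assert tw["treatment_weight"].tolist() == pytest.approx([w1, w2])

    def test_restart_zeroes_weight_from_restart_quarter(self, small_cohort):
        models = fit_propensity_models(small_cohort)
        spec = discontinuation_law(SHORT_TERM)
        panel = small_cohort.to_frame()
        compliance = evaluate_compliance(panel, spec)
        tw = treatment_weight(small_cohort, models, compliance, SHORT_TERM)
        merged = tw.merge(
            compliance[["subject_id", "t", "compatible"]], on=["subject_id", "t"]
        )
        assert (merged.loc[~merged["compatible"], "treatment_weight"] == 0).all()
        assert (merged.loc[merged["compatible"], "treatment_weight"] > 0).all()


class TestCensoringWeight:
    def test_no_censoring_gives_unit_component(self):
        cfg = sm.DGPConfig(n_subjects=200, seed=4)
        for c in ("death", "disenroll", "exclusion"):
            setattr(cfg.censoring, c + "_intercept", -60.0)
        panel = sm.simulate_cohort(cfg)
        models = fit_propensity_models(panel)
        cw = censoring_weight(panel, models)
        assert cw["censoring_weight"].to_numpy() == pytest.approx(1.0, abs=1e-6)

    def test_covariate_free_censoring_centers_at_one(self, rng):
        """Censoring independent of covariates: stabilization cancels the
        marginal hazard and the component stays near 1."""
        cfg = sm.DGPConfig(n_subjects=20_000, seed=5)
        cz = cfg.censoring
        cz.death_age = cz.death_frailty = 0.0
        cz.disenroll_age = cz.disenroll_frailty = 0.0
        cz.exclusion_age = cz.exclusion_frailty = 0.0
        panel = sm.simulate_cohort(cfg)
        models = fit_propensity_models(panel)
        cw = censoring_weight(panel, models)
        assert abs(cw["censoring_weight"].mean() - 1.0) < 0.02

    def test_informative_censoring_rebalances_risk_set(self):
        """Single-cause censoring loaded on frailty: weighting restores the
        uncensored population's frailty mean in the late risk set."""
        cfg = sm.DGPConfig(n_subjects=20_000, seed=6)
        cz = cfg.censoring
        cz.disenroll_intercept = -60.0
        cz.exclusion_intercept = -60.0
        cz.death_intercept = -4.0
        cz.death_age = 0.0
        cz.death_frailty = 2.0
        panel = sm.simulate_cohort(cfg)
        models = fit_propensity_models(panel)
        cw = censoring_weight(panel, models)
        pa = _engine.panel_arrays_from_cohort(panel)
        w = np.zeros(pa.A.shape)
        w[cw["subject_id"].to_numpy(), cw["t"].to_numpy() - 1] = cw["censoring_weight"].to_numpy()
        t = 20
        sel = pa.atrisk[:, t - 1]
        frail = panel.frailty.astype(float)
        weighted_mean = (w[sel, t - 1] * frail[sel]).sum() / w[sel, t - 1].sum()
        crude_mean = frail[sel].mean()
        target = frail.mean()
        # weighting moves the risk-set frailty mean to the population value
        assert abs(weighted_mean - target) < abs(crude_mean - target) / 3
        assert abs(weighted_mean - target) < 0.02


class TestCombineAndTruncate:
    def test_unit_components(self):
        tw = pd.DataFrame(
            {"subject_id": [0], "t": [1], "arm": [SHORT_TERM], "treatment_weight": [1.0]}
        )
        cw = pd.DataFrame({"subject_id": [0], "t": [1], "censoring_weight": [1.0]})
        out = combine_and_truncate(tw, cw)
        assert out["w"].tolist() == [1.0]
        assert out["truncated"].tolist() == [0]

    def test_truncation_at_bound(self):
        tw = pd.DataFrame(
            {"subject_id": [0], "t": [1], "arm": [SHORT_TERM], "treatment_weight": [60.0]}
        )
        cw = pd.DataFrame({"subject_id": [0], "t": [1], "censoring_weight": [2.0]})
        out = combine_and_truncate(tw, cw, bound=50.0)
        assert out["w"].tolist() == [50.0]
        assert out["truncated"].tolist() == [1]

    def test_misaligned_inputs_rejected(self):
        tw = pd.DataFrame(
            {"subject_id": [0, 1], "t": [1, 1], "arm": [SHORT_TERM] * 2,
             "treatment_weight": [1.0, 1.0]}
        )
        cw = pd.DataFrame({"subject_id": [0], "t": [1], "censoring_weight": [1.0]})
        with pytest.raises(ValueError):
            combine_and_truncate(tw, cw)


class TestWeightInvariants:
    def test_zero_propagation(self, small_cohort):
        """w(t) = 0 implies w(t') = 0 for all later t' (absorbing)."""
        wdf, _ = compute_ipw_weights(small_cohort)
        for (sid, arm), g in wdf.groupby(["subject_id", "arm"]):
            w = g.sort_values("t")["w"].to_numpy()
            zeros = w == 0
            if zeros.any():
                first = zeros.argmax()
                assert (w[first:] == 0).all()

    def test_truncation_monotonicity(self, small_cohort):
        """Lowering the truncation bound never increases any weight."""
        w50, _ = compute_ipw_weights(small_cohort, truncation_bound=50.0)
        w10, _ = compute_ipw_weights(small_cohort, truncation_bound=10.0)
        assert (w10["w"].to_numpy() <= w50["w"].to_numpy() + 1e-12).all()

    def test_weights_nonnegative_and_bounded(self, small_cohort):
        wdf, diag = compute_ipw_weights(small_cohort)
        assert (wdf["w"] >= 0).all()
        assert (wdf["w"] <= 50.0 + 1e-9).all()
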