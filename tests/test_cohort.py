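"""Synthetic cohort generator, dispensing emission, and the ground-truth oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import stochmsm as sm
from stochmsm.cohort import _event_prob, expected_event_count
from stochmsm.config import DGPConfig, InvalidConfigError
from stochmsm.exposure import build_person_quarters
from stochmsm.pipeline import covariate_stream_from_cohort
from stochmsm.regimens import LONGER_TERM, SHORT_TERM, discontinuation_law


class TestSimulateCohort:
    def test_seed_determinism(self):
        cfg = sm.scaled_config(500, seed=3)
        a = sm.simulate_cohort(cfg)
        b = sm.simulate_cohort(cfg)
        assert np.array_equal(a.A, b.A)
        assert np.array_equal(a.L, b.L)
        assert np.array_equal(a.terminal_quarter, b.terminal_quarter)
        c = sm.simulate_cohort(cfg.replace(seed=4))
        assert not np.array_equal(a.A, c.A)

    def test_zero_event_hazard_gives_zero_events(self):
        cfg = sm.DGPConfig(n_subjects=500, seed=1)
        cfg.event.intercept = -60.0
        panel = sm.simulate_cohort(cfg)
        assert panel.n_events == 0

    def test_forced_continuation_without_censoring(self):
        """Continuation probability 1 and no censoring: every non-event
        subject stays on treatment for all 40 quarters."""
        cfg = sm.DGPConfig(n_subjects=300, seed=2)
        for f in ("initiation", "reinitiation", "continuation"):
            setattr(cfg.treatment, f + "_intercept", 60.0)
        cfg.treatment.init_L = cfg.treatment.cont_L = 0.0
        for c in ("death", "disenroll", "exclusion"):
            setattr(cfg.censoring, c + "_intercept", -60.0)
        panel = sm.simulate_cohort(cfg)
        non_event = panel.terminal_cause == "admin"
        assert (panel.A[non_event].sum(axis=1) == 40).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            DGPConfig(n_subjects=0)
        with pytest.raises(InvalidConfigError):
            DGPConfig(n_quarters=0)

    def test_event_count_consistent_with_exact_compensator(self, default_cohort):
        """Realized events fall within 3 SD of the hazard-sum oracle computed
        by a forward pass over the exact per-subject hazard sequences."""
        expected, sd = expected_event_count(default_cohort.config, default_cohort)
        assert abs(default_cohort.n_events - expected) < 3 * sd

    def test_treatment_prevalence_declines(self, default_cohort):
        prev = [
            default_cohort.A[default_cohort.valid[:, t], t].mean() for t in (0, 5, 11)
        ]
        assert prev[0] > prev[1] > prev[2]

    def test_rare_event_regime_marginal_hazard(self, default_cohort):
        """Population-average per-quarter event hazard stays below 1e-3."""
        atrisk = default_cohort.valid & ~default_cohort.censored_at
        assert default_cohort.n_events / atrisk.sum() < 1e-3

    def test_panel_frame_round_trips_through_arrays(self, small_cohort):
        from stochmsm import _engine

        df = small_cohort.to_frame()
        pa = _engine.panel_arrays_from_frame(df)
        pb = _engine.panel_arrays_from_cohort(small_cohort)
        assert np.array_equal(pa.A, pb.A)
        assert np.array_equal(pa.valid, pb.valid)
        assert np.array_equal(pa.event, pb.event)
        assert np.array_equal(pa.atrisk, pb.atrisk)
        # feature tensors agree on every valid cell (cells after the terminal
        # quarter are undefined and masked out of all fits)
        i, j = np.nonzero(pb.valid)
        assert np.allclose(pa.F[i, j], pb.F[i, j])


class TestRareEventScaling:
    def test_doubling_log_odds_intercept_scales_expected_count(self):
        """On 100 fixed covariate paths, the closed-form per-path event
        probability scales like exp(delta) for rare hazards."""
        cfg = sm.DGPConfig(n_subjects=100, seed=5)
        cfg.event.intercept = -60.0  # no events: full paths observed
        panel = sm.simulate_cohort(cfg)
        base = cfg.replace()
        base.event = sm.DGPConfig().event
        e1, _ = expected_event_count(base, panel)
        shifted = cfg.replace()
        shifted.event = sm.DGPConfig().event
        shifted.event.intercept = base.event.intercept + np.log(2)
        e2, _ = expected_event_count(shifted, panel)
        assert e2 / e1 == pytest.approx(2.0, rel=5e-3)


class TestEmitDispensings:
    def test_round_trip_reproduces_on_off_flags(self, small_cohort):
        """Day-level PDC re-classification of emitted records recovers the
        simulator's quarterly exposure flags exactly."""
        records = sm.emit_dispensings(small_cohort, seed=7)
        stream = covariate_stream_from_cohort(small_cohort)
        terminal = small_cohort.subjects_frame()[
            ["subject_id", "terminal_quarter", "terminal_cause"]
        ]
        sub = terminal[terminal["subject_id"] < 1000]
        rebuilt = build_person_quarters(
            records[records["subject_id"] < 1000], stream[stream["subject_id"] < 1000], sub
        )
        sim = small_cohort.to_frame()
        sim = sim[sim["subject_id"] < 1000][["subject_id", "t", "on_treatment"]]
        merged = rebuilt.merge(sim, on=["subject_id", "t"], suffixes=("", "_sim"))
        assert len(merged) == len(rebuilt)
        assert (merged["on_treatment"] == merged["on_treatment_sim"]).all()

    def test_never_treated_subject_emits_nothing(self):
        cfg = sm.DGPConfig(n_subjects=50, seed=1)
        cfg.treatment.initiation_intercept = -60.0
        cfg.treatment.reinitiation_intercept = -60.0
        cfg.treatment.init_L = 0.0
        panel = sm.simulate_cohort(cfg)
        assert panel.A.sum() == 0
        assert len(sm.emit_dispensings(panel, seed=1)) == 0

    def test_forced_overlap_stockpiles_and_round_trips(self):
        cfg = sm.DGPConfig(n_subjects=40, seed=3)
        cfg.dispensing.overlap_prob = 1.0
        panel = sm.simulate_cohort(cfg)
        records = sm.emit_dispensings(panel, config=cfg, seed=9)
        # overlapping pairs exist and every overlap is <= 30 days
        overlaps = []
        for _, g in records.groupby("subject_id"):
            g = g.sort_values("start_day")
            end = None
            for r in g.itertuples():
                if end is not None and r.start_day < end:
                    overlaps.append(end - r.start_day)
                end = r.start_day + r.days_supply if end is None or r.start_day >= end else end + r.days_supply
        assert overlaps and max(overlaps) <= 30
        # round trip unchanged
        stream = covariate_stream_from_cohort(panel)
        terminal = panel.subjects_frame()[["subject_id", "terminal_quarter", "terminal_cause"]]
        rebuilt = build_person_quarters(records, stream, terminal)
        sim = panel.to_frame()[["subject_id", "t", "on_treatment"]]
        merged = rebuilt.merge(sim, on=["subject_id", "t"], suffixes=("", "_sim"))
        assert (merged["on_treatment"] == merged["on_treatment_sim"]).all()


class TestOracle:
    def test_zero_hazard_zero_risk(self):
        cfg = sm.DGPConfig(n_subjects=10, seed=1)
        cfg.event.intercept = -60.0
        curve = sm.oracle_counterfactual_risk(cfg, discontinuation_law(SHORT_TERM), n_mc=2000, seed=1)
        assert (curve.risk == 0).all()

    def test_small_n_mc_warns(self):
        cfg = sm.DGPConfig(n_subjects=10, seed=1)
        with pytest.warns(UserWarning):
            sm.oracle_counterfactual_risk(cfg, discontinuation_law(SHORT_TERM), n_mc=100, seed=1)

    def test_null_dgp_arms_agree(self):
        """Treatment-independent hazard: both regimens share one truth."""
        cfg = sm.null_effect_config(2000, seed=1)
        a = sm.oracle_counterfactual_risk(cfg, discontinuation_law(SHORT_TERM), n_mc=60_000, seed=2)
        b = sm.oracle_counterfactual_risk(cfg, discontinuation_law(LONGER_TERM), n_mc=60_000, seed=3)
        for q in (20, 40):
            se = np.hypot(a.se_at(q), b.se_at(q))
            assert abs(a.risk_at(q) - b.risk_at(q)) < 3 * se

    def test_positive_duration_effect_orders_arms(self):
        cfg = sm.DGPConfig(seed=1)
        a = sm.oracle_counterfactual_risk(cfg, discontinuation_law(SHORT_TERM), n_mc=60_000, seed=2)
        b = sm.oracle_counterfactual_risk(cfg, discontinuation_law(LONGER_TERM), n_mc=60_000, seed=3)
        assert b.risk_at(40) > a.risk_at(40)

    def test_matches_exact_recursion_on_coarsened_dgp(self):
        """With degenerate baseline and dynamics noise, the intervened process
        is a finite-state chain over (discontinuation quarter, frailty); the
        oracle must agree with the exact recursion within MC error."""
        cfg = sm.DGPConfig(n_subjects=10, n_quarters=20, seed=1)
        cfg.baseline.age_sd = 0.0
        cfg.baseline.L0_sd = 0.0
        cfg.dynamics.noise_sd = 0.0
        cfg.event.intercept += np.log(50)  # lift the rate so MC error is relative
        spec = discontinuation_law(SHORT_TERM, horizon=20)
        T = cfg.n_quarters

        q = np.array([spec.conditional_discontinuation_prob(t) for t in range(1, T + 1)])
        age_std = (cfg.baseline.age_mean - 70.0) / 10.0
        cz = cfg.censoring

        # enumerate states: frailty x discontinuation quarter d (off from d)
        states = []  # (prob, frailty, d) with d in 1..T+1 (T+1 = never within horizon)
        for frail, pf in ((0, 1 - cfg.baseline.frailty_prob), (1, cfg.baseline.frailty_prob)):
            surv = 1.0
            for d in range(1, T + 1):
                states.append((pf * surv * q[d - 1], frail, d))
                surv *= 1 - q[d - 1]
            states.append((pf * surv, frail, T + 1))

        h_expected = np.zeros(T)
        num = np.zeros(T)
        den = np.zeros(T)
        for prob, frail, d in states:
            alive = prob
            L = cfg.baseline.L0_mean
            cum = 0
            p_death = expit(cz.death_intercept + cz.death_age * age_std + cz.death_frailty * frail)
            for t in range(1, T + 1):
                if t > 1:
                    on_prev = 1 if (t - 1) < d else 0
                    L = L + cfg.dynamics.drift + cfg.dynamics.treatment_effect * on_prev
                on = 1 if t < d else 0
                cum += on
                alive *= 1 - p_death
                p_ev = float(_event_prob(cfg, cum, L, frail))
                num[t - 1] += alive * p_ev
                den[t - 1] += alive
                alive *= 1 - p_ev
        h_expected = num / den
        risk_expected = 1 - np.cumprod(1 - h_expected)

        curve = sm.oracle_counterfactual_risk(cfg, spec, n_mc=120_000, seed=4)
        for t in (5, 10, 20):
            assert abs(curve.risk_at(t) - risk_expected[t - 1]) < 4 * max(curve.se_at(t), 1e-9)

    def test_oracle_matches_crude_follower_risk_without_confounding(self):
        """With a treatment-independent hazard and covariate-free treatment,
        the oracle equals the crude risk among regimen-followers in the
        observational cohort within Monte-Carlo error."""
        cfg = sm.null_effect_config(6000, seed=6)
        cfg.event.intercept = -6.5  # lift the flat hazard so MC error is relative
        cfg.censoring.disenroll_intercept = -60.0
        cfg.censoring.exclusion_intercept = -60.0
        panel = sm.simulate_cohort(cfg)
        spec = discontinuation_law(SHORT_TERM)
        from stochmsm import _engine

        pa = _engine.panel_arrays_from_cohort(panel)
        arms = _engine.arm_matrices(pa, 40, None)
        am = arms["short_term"]
        h, num, den = _engine.weighted_hazard_arrays(pa, np.ones(pa.A.shape), am.compatible)
        risk = 1 - np.cumprod(1 - h)
        # Greenwood SE of the crude follower estimate
        terms = np.where(den > 0, h / np.maximum(den * (1 - h), 1e-300), 0.0)
        se_crude = (1 - risk) * np.sqrt(np.cumsum(terms))
        oracle = sm.oracle_counterfactual_risk(cfg, spec, n_mc=80_000, seed=7)
        for t in (10, 30):
            se = np.hypot(oracle.se_at(t), se_crude[t - 1])
            assert abs(risk[t - 1] - oracle.risk_at(t)) < 3 * se
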