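"""Synthetic quarterly cohorts with treatment-confounder feedback.

The generator emulates the structure of a pharmacoepidemiologic new-user
cohort followed quarterly for up to 10 years:

* baseline covariates: an age-like continuous covariate, a binary frailty
  indicator, and an initial bone-density-like score L0;
* a dynamic score L(t) that responds to treatment (treatment slows its
  decline) and confounds both future treatment and the outcome — the
  classic time-dependent-confounding topology;
* an on/off treatment process whose continuation probability rises as the
  (last measured) score falls, with separate initiation / re-initiation
  intercepts and a cumulative-exposure habituation term;
* a sparse measurement process for L (baseline score missing for a
  configurable fraction of subjects; re-measurement at a small per-quarter
  probability) with carry-forward and mean imputation, so decisions are
  driven by what a prescriber could actually see;
* a rare terminal event whose per-quarter log-odds increase with cumulative
  exposure and with a low true score;
* three stochastic censoring causes (death, disenrollment, exclusion) plus
  deterministic administrative end at the horizon.

Within a quarter the order of operations is: update L -> maybe re-measure
-> draw treatment -> draw censoring (death, then disenrollment, then
exclusion) -> draw the event among the uncensored.

The module also provides the ground-truth oracle: the counterfactual risk
under any stochastic regimen, computed by direct Monte-Carlo intervention
on the treatment process (disenrollment/exclusion censoring disabled; death
retained as a censoring event, matching the estimation target).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DGPConfig, InvalidConfigError
from .exposure import QUARTER_DAYS, l_category
from .regimens import RegimenSpec

CAUSES = ("event", "death", "disenroll", "exclusion", "admin")


@dataclass
class CohortPanel:
    """Dense per-subject-per-quarter arrays for a simulated cohort.

    Arrays are (n, T); cells after a subject's terminal quarter are
    undefined and masked out by ``valid``.  ``censored_at`` marks the
    quarter in which a stochastic censoring cause struck (the subject is
    not at risk for the event in that quarter); administrative end is not a
    ``censored_at`` quarter — those subjects remain at risk through T.
    """

    config: DGPConfig
    age: np.ndarray
    frailty: np.ndarray
    L0: np.ndarray
    A: np.ndarray
    L: np.ndarray
    L_obs: np.ndarray
    L_imputed: np.ndarray
    t_since_meas: np.ndarray
    cum_on: np.ndarray
    valid: np.ndarray
    event: np.ndarray
    censored_at: np.ndarray
    terminal_quarter: np.ndarray
    terminal_cause: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.age)

    @property
    def n_quarters(self) -> int:
        return self.A.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def validate(self) -> None:
        """Check the panel invariants (one terminal state, no post-terminal rows)."""
        n, T = self.A.shape
        tq = self.terminal_quarter
        assert np.all((tq >= 1) & (tq <= T))
        cols = np.arange(1, T + 1)
        assert np.array_equal(self.valid, cols[None, :] <= tq[:, None])
        assert not np.any(self.event & self.censored_at)
        ev_q = np.where(self.event.any(axis=1), self.event.argmax(axis=1) + 1, 0)
        assert np.all((ev_q == 0) | (ev_q == tq))
        assert np.all((self.terminal_cause == "event") == (ev_q > 0))

    # -- tabular views -------------------------------------------------------

    def subjects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": np.arange(self.n_subjects),
                "age": self.age,
                "frailty": self.frailty,
                "L0": self.L0,
                "terminal_quarter": self.terminal_quarter,
                "terminal_cause": self.terminal_cause,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long panel: one row per valid subject-quarter (the analysis atom)."""
        n, T = self.A.shape
        sid, t = np.nonzero(self.valid)
        cause = np.full(len(sid), "none", dtype=object)
        terminal = (t + 1) == self.terminal_quarter[sid]
        is_censor = terminal & np.isin(self.terminal_cause[sid], ("death", "disenroll", "exclusion", "admin"))
        cause[is_censor] = self.terminal_cause[sid][is_censor]
        df = pd.DataFrame(
            {
                "subject_id": sid,
                "t": t + 1,
                "on_treatment": self.A[sid, t].astype(int),
                "cumulative_on_quarters": self.cum_on[sid, t].astype(int),
                "L": self.L[sid, t],
                "L_obs": self.L_obs[sid, t],
                "L_category": [l_category(v) for v in self.L_obs[sid, t]],
                "L_imputed": self.L_imputed[sid, t].astype(int),
                "time_since_meas": self.t_since_meas[sid, t].astype(int),
                "age": self.age[sid],
                "frailty": self.frailty[sid].astype(int),
                "event": self.event[sid, t].astype(int),
                "censor_cause": cause,
            }
        )
        return df

    def write_csvs(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "subjects": out / "subjects.csv",
            "panel": out / "panel.csv",
        }
        self.subjects_frame().to_csv(paths["subjects"], index=False)
        self.to_frame().to_csv(paths["panel"], index=False)
        return paths


def _treatment_prob(cfg: DGPConfig, prev_on, L_obs, frailty, cum_prev, t):
    """P(on at t | history); vectorized over subjects."""
    tm = cfg.treatment
    if t == 1:
        logit = tm.initiation_intercept + tm.init_L * L_obs + tm.init_frailty * frailty
    else:
        cont = (
            tm.continuation_intercept
            + tm.cont_L * L_obs
            + tm.cont_frailty * frailty
            + tm.cont_cumulative * cum_prev
        )
        reinit = tm.reinitiation_intercept + tm.init_L * L_obs + tm.init_frailty * frailty
        logit = np.where(prev_on, cont, reinit)
    return expit(logit)


def _censoring_probs(cfg: DGPConfig, age_std, frailty, alive_n):
    cz = cfg.censoring
    p_death = expit(cz.death_intercept + cz.death_age * age_std + cz.death_frailty * frailty)
    p_dis = expit(
        cz.disenroll_intercept + cz.disenroll_age * age_std + cz.disenroll_frailty * frailty
    )
    p_exc = expit(
        cz.exclusion_intercept + cz.exclusion_age * age_std + cz.exclusion_frailty * frailty
    )
    return p_death, p_dis, p_exc


def _event_prob(cfg: DGPConfig, cum_on, L, frailty):
    ev = cfg.event
    return expit(
        ev.intercept + ev.cumulative_exposure * cum_on + ev.L * L + ev.frailty * frailty
    )


def simulate_cohort(config: DGPConfig, seed: int | None = None) -> CohortPanel:
    """Simulate one cohort under the observational (confounded) regime.

    ``seed`` overrides ``config.seed`` when given.  Identical (config, seed)
    pairs produce identical panels.
    """
    if config.n_subjects < 1 or config.n_quarters < 1:
        raise InvalidConfigError("n_subjects and n_quarters must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, T = config.n_subjects, config.n_quarters
    bl = config.baseline

    age = rng.normal(bl.age_mean, bl.age_sd, size=n)
    age_std = (age - 70.0) / 10.0
    frailty = (rng.random(n) < bl.frailty_prob).astype(np.int8)
    L0 = rng.normal(bl.L0_mean, bl.L0_sd, size=n)
    baseline_measured = rng.random(n) >= bl.baseline_missing_prob

    A = np.zeros((n, T), dtype=np.int8)
    L = np.zeros((n, T))
    L_obs = np.zeros((n, T))
    L_imputed = np.zeros((n, T), dtype=np.int8)
    t_since = np.zeros((n, T), dtype=np.int16)
    cum_on = np.zeros((n, T), dtype=np.int16)
    valid = np.zeros((n, T), dtype=bool)
    event = np.zeros((n, T), dtype=bool)
    censored_at = np.zeros((n, T), dtype=bool)
    terminal_quarter = np.full(n, T, dtype=np.int32)
    terminal_cause = np.full(n, "admin", dtype=object)

    active = np.ones(n, dtype=bool)
    cur_L = L0.copy()
    cur_obs = np.where(baseline_measured, L0, bl.fill_value)
    cur_imp = (~baseline_measured).astype(np.int8)
    last_meas = np.where(baseline_measured, 0, -1)  # quarter of last measurement
    prev_on = np.zeros(n, dtype=bool)
    cum = np.zeros(n, dtype=np.int16)

    dyn = config.dynamics
    for t in range(1, T + 1):
        idx = np.nonzero(active)[0]
        if len(idx) == 0:
            break
        if t > 1:
            cur_L[idx] = (
                cur_L[idx]
                + dyn.drift
                + dyn.treatment_effect * prev_on[idx]
                + rng.normal(0.0, dyn.noise_sd, size=len(idx))
            )
            meas = rng.random(len(idx)) < bl.remeasure_prob
            mi = idx[meas]
            cur_obs[mi] = cur_L[mi]
            cur_imp[mi] = 0
            last_meas[mi] = t
        valid[idx, t - 1] = True
        L[idx, t - 1] = cur_L[idx]
        L_obs[idx, t - 1] = cur_obs[idx]
        L_imputed[idx, t - 1] = cur_imp[idx]
        t_since[idx, t - 1] = np.where(last_meas[idx] >= 0, t - last_meas[idx], t)

        p_on = _treatment_prob(config, prev_on[idx], cur_obs[idx], frailty[idx], cum[idx], t)
        a_t = rng.random(len(idx)) < p_on
        A[idx, t - 1] = a_t
        cum[idx] += a_t
        cum_on[idx, t - 1] = cum[idx]

        p_death, p_dis, p_exc = _censoring_probs(config, age_std[idx], frailty[idx], len(idx))
        u = rng.random((len(idx), 3))
        died = u[:, 0] < p_death
        disen = ~died & (u[:, 1] < p_dis)
        excl = ~died & ~disen & (u[:, 2] < p_exc)
        censored = died | disen | excl
        cidx = idx[censored]
        censored_at[cidx, t - 1] = True
        terminal_quarter[cidx] = t
        terminal_cause[idx[died]] = "death"
        terminal_cause[idx[disen]] = "disenroll"
        terminal_cause[idx[excl]] = "exclusion"

        survivors = idx[~censored]
        p_ev = _event_prob(config, cum[survivors], cur_L[survivors], frailty[survivors])
        ev = rng.random(len(survivors)) < p_ev
        eidx = survivors[ev]
        event[eidx, t - 1] = True
        terminal_quarter[eidx] = t
        terminal_cause[eidx] = "event"

        active[cidx] = False
        active[eidx] = False
        prev_on = A[:, t - 1].astype(bool)

    panel = CohortPanel(
        config=config,
        age=age,
        frailty=frailty,
        L0=L0,
        A=A,
        L=L,
        L_obs=L_obs,
        L_imputed=L_imputed,
        t_since_meas=t_since,
        cum_on=cum_on,
        valid=valid,
        event=event,
        censored_at=censored_at,
        terminal_quarter=terminal_quarter,
        terminal_cause=terminal_cause,
    )
    panel.validate()
    return panel


def expected_event_count(config: DGPConfig, panel: CohortPanel) -> tuple[float, float]:
    """Expected event count and its SD given the panel's realized paths.

    A brute-force forward pass over the exact per-subject hazard sequences:
    every observed at-risk person-quarter contributes its event hazard
    (the compensator of the event counting process), so the realized event
    count minus this sum is a martingale with mean 0 and variance
    sum p(1-p).  Serves as the Binomial-consistency oracle for the realized
    count.
    """
    total = 0.0
    var = 0.0
    n, T = panel.A.shape
    for i in range(n):
        for t in range(panel.terminal_quarter[i]):
            if panel.censored_at[i, t]:
                break
            p = float(
                _event_prob(config, panel.cum_on[i, t], panel.L[i, t], panel.frailty[i])
            )
            total += p
            var += p * (1.0 - p)
    return total, float(np.sqrt(var))


def emit_dispensings(
    panel: CohortPanel, config: DGPConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Render quarterly on/off exposure as raw dispensing records.

    For each maximal run of on-treatment quarters one record is emitted per
    quarter: the first starts a few days into the quarter (refill delay);
    subsequent refills either follow the prior supply or are picked up a few
    days early (overlap <= 30 days, so the stockpiling rule applies on
    re-classification).  Off quarters emit nothing.  With the default
    emission parameters the day-level PDC re-classification reproduces the
    panel's on/off flags exactly (round-trip property).
    """
    cfg = config or panel.config
    em = cfg.dispensing
    if em.max_delay_days > 44 or em.max_overlap_days > 30:
        raise InvalidConfigError(
            "emission parameters must keep refill delay <= 44 days and overlap <= 30 days"
        )
    rng = np.random.default_rng(seed)
    rows: list[tuple[int, int, int]] = []
    n, T = panel.A.shape
    for i in range(n):
        prev_end = None
        for t in range(panel.terminal_quarter[i]):
            if not panel.A[i, t]:
                prev_end = None
                continue
            q_start = t * QUARTER_DAYS
            if prev_end is None:
                start = q_start + int(rng.integers(0, em.max_delay_days + 1))
            elif rng.random() < em.overlap_prob and em.max_overlap_days >= 1:
                start = prev_end - int(rng.integers(1, em.max_overlap_days + 1))
            else:
                start = q_start + int(rng.integers(0, em.max_delay_days + 1))
            rows.append((i, start, em.days_supply))
            # supply runs contiguously once overlaps stockpile; track the
            # nominal end of the current contiguous supply chain
            if prev_end is None or start >= prev_end:
                prev_end = start + em.days_supply
            else:
                prev_end = prev_end + em.days_supply
    return pd.DataFrame(rows, columns=["subject_id", "start_day", "days_supply"])


def _km_curve(event_mat: np.ndarray, atrisk_mat: np.ndarray):
    """Hazard/survival/risk with Greenwood standard errors from count matrices."""
    events = event_mat.sum(axis=0).astype(float)
    atrisk = atrisk_mat.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(atrisk > 0, events / np.maximum(atrisk, 1.0), 0.0)
    S = np.cumprod(1.0 - h)
    risk = 1.0 - S
    # Greenwood variance of S(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            (atrisk > 0) & (h < 1), h / np.maximum(atrisk * (1.0 - h), 1e-300), 0.0
        )
    var = S**2 * np.cumsum(terms)
    return h, S, risk, np.sqrt(var)


@dataclass
class OracleCurve:
    """True counterfactual risk under a regimen, by direct intervention."""

    arm_label: str
    t: np.ndarray
    hazard: np.ndarray
    survival: np.ndarray
    risk: np.ndarray
    mc_se: np.ndarray
    n_mc: int

    def risk_at(self, t: int) -> float:
        return float(self.risk[t - 1])

    def se_at(self, t: int) -> float:
        return float(self.mc_se[t - 1])


def oracle_counterfactual_risk(
    config: DGPConfig, regimen: RegimenSpec, n_mc: int = 100_000, seed: int = 0
) -> OracleCurve:
    """Ground-truth risk under a stochastic regimen by direct intervention.

    Treatment is drawn from the regimen's intervention law instead of the
    confounded observational model; covariate dynamics and the event hazard
    are unchanged.  Disenrollment and exclusion censoring are disabled (the
    estimand adjusts them away via censoring weights); death is retained and
    handled as in the weighted estimator (subjects leave the risk set at
    death).  Returns risk(t) for t = 1..n_quarters with Monte-Carlo SE.
    """
    if n_mc < 1000:
        warnings.warn("n_mc < 1000 gives an unstable ground truth", stacklevel=2)
    rng = np.random.default_rng(seed)
    n, T = n_mc, config.n_quarters
    bl = config.baseline
    age = rng.normal(bl.age_mean, bl.age_sd, size=n)
    age_std = (age - 70.0) / 10.0
    frailty = (rng.random(n) < bl.frailty_prob).astype(np.int8)
    cur_L = rng.normal(bl.L0_mean, bl.L0_sd, size=n)

    q = np.array(
        [regimen.conditional_discontinuation_prob(t) for t in range(1, T + 1)]
    )
    still_on = np.ones(n, dtype=bool)
    prev_on = np.zeros(n, dtype=bool)
    cum = np.zeros(n, dtype=np.int32)
    alive = np.ones(n, dtype=bool)
    event_mat = np.zeros((n, T), dtype=bool)
    atrisk_mat = np.zeros((n, T), dtype=bool)
    dyn, cz = config.dynamics, config.censoring
    for t in range(1, T + 1):
        idx = np.nonzero(alive)[0]
        if len(idx) == 0:
            break
        if t > 1:
            cur_L[idx] = (
                cur_L[idx]
                + dyn.drift
                + dyn.treatment_effect * prev_on[idx]
                + rng.normal(0.0, dyn.noise_sd, size=len(idx))
            )
        # intervened treatment draw
        disc = still_on[idx] & (rng.random(len(idx)) < q[t - 1])
        still_on_idx = still_on[idx] & ~disc
        a_t = still_on_idx  # on iff still on under the law (restart prob 0)
        still_on[idx] = still_on_idx
        cum[idx] += a_t
        # death censoring retained under intervention
        p_death = expit(
            cz.death_intercept + cz.death_age * age_std[idx] + cz.death_frailty * frailty[idx]
        )
        died = rng.random(len(idx)) < p_death
        survivors = idx[~died]
        atrisk_mat[survivors, t - 1] = True
        p_ev = _event_prob(config, cum[survivors], cur_L[survivors], frailty[survivors])
        ev = rng.random(len(survivors)) < p_ev
        event_mat[survivors[ev], t - 1] = True
        alive[idx[died]] = False
        alive[survivors[ev]] = False
        prev_on = np.zeros(n, dtype=bool)
        prev_on[idx] = a_t

    h, S, risk, se = _km_curve(event_mat, atrisk_mat)
    return OracleCurve(
        arm_label=regimen.arm_label,
        t=np.arange(1, T + 1),
        hazard=h,
        survival=S,
        risk=risk,
        mc_se=se,
        n_mc=n_mc,
    )
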