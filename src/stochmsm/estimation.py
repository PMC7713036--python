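"""Counterfactual hazard, survival, risk-difference and curve-area estimation.

The marginal structural model is saturated — one free hazard parameter per
arm-quarter — so the IPW fit reduces to the weighted empirical discrete-time
hazard

    h_a(t) = sum_i w_i(t) event_i(t) / sum_i w_i(t) atrisk_i(t)

over person-quarters compatible with arm a, which maps to survival
S_a(t) = prod_{k<=t} (1 - h_a(k)), cumulative risk 1 - S_a(t), risk
differences between arms, and the area under each discrete-time survival
curve (one-quarter rectangle rule).  Uncertainty comes from a subject-level
nonparametric bootstrap with full re-fit of the propensity models in every
replicate: percentile confidence intervals and SD-based standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from ._engine import BootstrapResult
from .ipw import _as_arrays
from .regimens import LONGER_TERM, SHORT_TERM


@dataclass
class HazardCurve:
    arm: str
    t: np.ndarray
    hazard: np.ndarray
    weighted_events: np.ndarray
    weighted_atrisk: np.ndarray
    empty_risk_set: np.ndarray

    def __post_init__(self) -> None:
        assert np.all((self.hazard >= 0) & (self.hazard <= 1))


@dataclass
class SurvivalCurve:
    arm: str
    t: np.ndarray
    survival: np.ndarray
    risk: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def risk_at(self, t: int) -> float:
        return float(self.risk[t - 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"arm": self.arm, "t": self.t, "S": self.survival, "risk": self.risk}
        )
        if self.ci_low is not None:
            df["risk_ci_low"] = self.ci_low
            df["risk_ci_high"] = self.ci_high
        return df


@dataclass
class RiskDifferenceEstimate:
    t: int
    rd: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str = "percentile_bootstrap"
    replicates: int = 0

    def per_100k(self) -> float:
        return self.rd * 1e5


@dataclass
class AUCTestResult:
    """Difference in areas under the two discrete-time survival curves."""

    auc_short: float
    auc_long: float
    difference: float  # short - long (positive when longer treatment is worse)
    se: float
    p_value: float
    replicates: int
    seed: int


def weighted_hazard(panel, weights: pd.DataFrame, compliance: pd.DataFrame, arm: str) -> HazardCurve:
    """Weighted empirical discrete-time hazard for one arm.

    ``weights`` is a long frame (subject_id, t, arm, w); ``compliance`` the
    arm's compatibility frame.  Quarters with an empty weighted risk set get
    h = 0 and an emptiness flag.
    """
    pa = _as_arrays(panel)
    n, T = pa.A.shape
    w = np.zeros((n, T))
    wa = weights[weights["arm"] == arm] if "arm" in weights.columns else weights
    w[wa["subject_id"].to_numpy(), wa["t"].to_numpy() - 1] = wa["w"].to_numpy()
    compat = np.zeros((n, T), dtype=bool)
    ca = compliance[compliance["arm"] == arm] if "arm" in compliance.columns else compliance
    compat[ca["subject_id"].to_numpy(), ca["t"].to_numpy() - 1] = ca["compatible"].to_numpy()
    h, num, den = _engine.weighted_hazard_arrays(pa, w, compat)
    return HazardCurve(
        arm=arm, t=np.arange(1, T + 1), hazard=h,
        weighted_events=num, weighted_atrisk=den, empty_risk_set=den == 0,
    )


def survival_from_hazard(h: HazardCurve) -> SurvivalCurve:
    S, risk = _engine.survival_arrays(h.hazard)
    return SurvivalCurve(arm=h.arm, t=h.t, survival=S, risk=risk)


def risk_difference(
    curves: dict[str, SurvivalCurve],
    t: int,
    bootstrap: BootstrapResult | None = None,
) -> RiskDifferenceEstimate:
    """RD(t) = risk_longer(t) - risk_short(t), with percentile CI if given."""
    for arm in (SHORT_TERM, LONGER_TERM):
        if t > len(curves[arm].t):
            raise IndexError(f"quarter {t} beyond curve horizon")
    rd = curves[LONGER_TERM].risk_at(t) - curves[SHORT_TERM].risk_at(t)
    est = RiskDifferenceEstimate(t=t, rd=float(rd))
    if bootstrap is not None:
        reps = bootstrap.risk[LONGER_TERM][:, t - 1] - bootstrap.risk[SHORT_TERM][:, t - 1]
        lo, hi = np.percentile(reps, [2.5, 97.5])
        est.ci_low, est.ci_high = float(min(lo, rd)), float(max(hi, rd))
        est.replicates = len(reps)
    return est


@dataclass
class EstimationResult:
    """Full pipeline output on one panel: curves, RDs, AUC test, diagnostics."""

    curves: dict[str, SurvivalCurve]
    hazards: dict[str, HazardCurve]
    risk_differences: dict[int, RiskDifferenceEstimate]
    auc_test: AUCTestResult | None
    bootstrap: BootstrapResult | None
    diagnostics: _engine.WeightDiagnostics
    models: dict
    crude_curves: dict[str, SurvivalCurve] = field(default_factory=dict)


def estimate_counterfactual_curves(
    panel,
    horizon: int = 40,
    never_mass: float | None = None,
    truncation_bound: float = 50.0,
    propensity_floor: float = 1e-4,
    B: int = 0,
    seed: int = 0,
    rd_quarters: tuple[int, ...] = (16, 20, 40),
    include_crude: bool = False,
) -> EstimationResult:
    """End-to-end IPW estimation on a quarterly panel.

    With ``B`` > 0, runs the subject-level bootstrap (full model re-fit per
    replicate) for percentile CIs, standard errors and the curve-area test.
    """
    pa = _as_arrays(panel)
    T = pa.n_quarters
    arms = _engine.arm_matrices(pa, horizon=horizon, never_mass=never_mass)
    point = _engine.estimate_once(
        pa, arms, truncation_bound=truncation_bound, propensity_floor=propensity_floor
    )
    tgrid = np.arange(1, T + 1)
    curves, hazards = {}, {}
    for arm in arms:
        hazards[arm] = HazardCurve(
            arm=arm, t=tgrid, hazard=point.hazard[arm],
            weighted_events=np.full(T, np.nan), weighted_atrisk=np.full(T, np.nan),
            empty_risk_set=point.empty_risk_set[arm],
        )
        curves[arm] = SurvivalCurve(
            arm=arm, t=tgrid, survival=point.survival[arm], risk=point.risk[arm]
        )

    boot = None
    auc_test = None
    if B:
        boot = _engine.bootstrap_panel(
            pa, arms, B=B, seed=seed, truncation_bound=truncation_bound,
            propensity_floor=propensity_floor, warm=point.fits,
        )
        for arm in arms:
            lo, hi = np.percentile(boot.risk[arm], [2.5, 97.5], axis=0)
            curves[arm].ci_low = np.minimum(lo, curves[arm].risk)
            curves[arm].ci_high = np.maximum(hi, curves[arm].risk)
        auc_test = _auc_test_from_bootstrap(point, boot, seed)

    rds = {
        t: risk_difference(curves, t, bootstrap=boot)
        for t in rd_quarters
        if t <= T
    }
    result = EstimationResult(
        curves=curves, hazards=hazards, risk_differences=rds,
        auc_test=auc_test, bootstrap=boot, diagnostics=point.diagnostics,
        models={k: f.summary() for k, f in point.fits.items()},
    )
    if include_crude:
        crude = _engine.estimate_once(pa, arms, crude=True)
        result.crude_curves = {
            arm: SurvivalCurve(arm=arm, t=tgrid, survival=crude.survival[arm], risk=crude.risk[arm])
            for arm in arms
        }
    return result


def _auc_test_from_bootstrap(point, boot: BootstrapResult, seed: int) -> AUCTestResult:
    diff = point.auc[SHORT_TERM] - point.auc[LONGER_TERM]
    reps = boot.auc[SHORT_TERM] - boot.auc[LONGER_TERM]
    se = float(np.std(reps, ddof=1))
    if se == 0.0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / se
        p = float(2.0 * stats.norm.sf(abs(z)))
    return AUCTestResult(
        auc_short=float(point.auc[SHORT_TERM]),
        auc_long=float(point.auc[LONGER_TERM]),
        difference=float(diff),
        se=se,
        p_value=p,
        replicates=boot.n_kept,
        seed=seed,
    )


def bootstrap_inference(panel, B: int = 200, seed: int = 0, **kwargs) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the full IPW pipeline."""
    pa = _as_arrays(panel)
    arms = _engine.arm_matrices(
        pa, horizon=kwargs.pop("horizon", 40), never_mass=kwargs.pop("never_mass", None)
    )
    return _engine.bootstrap_panel(pa, arms, B=B, seed=seed, **kwargs)


def auc_difference_test(panel, B: int = 200, seed: int = 0, horizon: int = 40, **kwargs) -> AUCTestResult:
    """Bootstrap Wald test for the difference in survival-curve areas."""
    res = estimate_counterfactual_curves(panel, horizon=horizon, B=B, seed=seed, **kwargs)
    assert res.auc_test is not None
    return res.auc_test
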