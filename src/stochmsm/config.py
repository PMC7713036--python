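"""Configuration objects for the synthetic cohort and the estimation pipeline.

All data-generating-process (DGP) parameters live in :class:`DGPConfig`.
The defaults describe the reference study conditions: a 20,000-subject
cohort followed quarterly for up to 40 quarters (10 years), an on/off
treatment process confounded by a treatment-responsive bone-density-like
score L(t), a rare terminal event whose log-odds rise with cumulative
exposure, and three stochastic censoring processes (death, disenrollment,
exclusion) plus a deterministic administrative end at the horizon.

Coefficient conventions: logistic (log-odds) scale throughout; ``age_std``
denotes (age - 70)/10.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


class InvalidConfigError(ValueError):
    pass


@dataclass
class BaselineCovariateParams:
    age_mean: float = 68.6
    age_sd: float = 9.1
    frailty_prob: float = 0.20
    L0_mean: float = -2.5
    L0_sd: float = 0.7
    #: probability that the baseline bone-density score is never measured
    baseline_missing_prob: float = 0.276
    #: per-quarter probability of a new measurement during follow-up
    remeasure_prob: float = 0.05
    #: cohort-mean fill value used when the score is unmeasured
    fill_value: float = -2.5


@dataclass
class TreatmentModelCoefs:
    """Logistic models for quarterly treatment status.

    Quarter 1 uses the initiation intercept (everyone enters at a first
    dispensing, so quarter-1 "on" prevalence is high); later quarters use the
    continuation intercept when on in the prior quarter and the
    re-initiation intercept when off.  Treatment decisions depend on the
    *last measured* score (what a prescriber can see), not the latent one.
    """

    initiation_intercept: float = 3.0
    reinitiation_intercept: float = -3.5
    continuation_intercept: float = -1.95
    #: shared covariate effects for initiation / re-initiation.  The score
    #: does not enter these transitions: score-driven re-initiation makes
    #: long off-treatment histories all but impossible for exactly the
    #: high-risk (low-score) subjects, a practical positivity failure that
    #: would leave the short-term arm's counterfactual risk inestimable at
    #: realistic cohort sizes.  Confounding lives in the continuation model.
    init_L: float = 0.0
    init_frailty: float = -0.3
    #: covariate effects for continuation
    cont_L: float = -1.5
    cont_frailty: float = -0.3
    cont_cumulative: float = 0.04


@dataclass
class CovariateDynamicsCoefs:
    """L(t) = L(t-1) + drift + treatment_effect * on_treatment(t-1) + noise."""

    drift: float = -0.02
    treatment_effect: float = 0.05
    noise_sd: float = 0.05


@dataclass
class EventHazardCoefs:
    """Per-quarter logistic event hazard: intercept + cum-exposure + L + frailty."""

    intercept: float = -13.4
    cumulative_exposure: float = 0.10
    L: float = -1.0
    frailty: float = 0.5


@dataclass
class CensoringHazardCoefs:
    """Per-quarter logistic hazards for the three stochastic censoring causes.

    Administrative end-of-study is deterministic at the horizon and has no
    coefficients.  Each cause: intercept + age_std + frailty terms.
    """

    death_intercept: float = -6.3
    death_age: float = 0.35
    death_frailty: float = 0.8
    disenroll_intercept: float = -4.6
    disenroll_age: float = -0.10
    disenroll_frailty: float = 0.0
    exclusion_intercept: float = -6.0
    exclusion_age: float = 0.0
    exclusion_frailty: float = 0.3


@dataclass
class DispensingEmissionParams:
    """How quarterly on/off exposure is rendered as dispensing records."""

    days_supply: int = 90
    #: refill delay after a quarter boundary, uniform on [0, max_delay_days]
    max_delay_days: int = 9
    #: probability a refill is picked up early, overlapping the prior supply
    overlap_prob: float = 0.3
    #: early-pickup overlap, uniform on [1, max_overlap_days] (<= 30 so the
    #: stockpiling rule applies rather than precedence)
    max_overlap_days: int = 9


@dataclass
class DGPConfig:
    n_subjects: int = 20_000
    n_quarters: int = 40
    seed: int = 0
    baseline: BaselineCovariateParams = field(default_factory=BaselineCovariateParams)
    treatment: TreatmentModelCoefs = field(default_factory=TreatmentModelCoefs)
    dynamics: CovariateDynamicsCoefs = field(default_factory=CovariateDynamicsCoefs)
    event: EventHazardCoefs = field(default_factory=EventHazardCoefs)
    censoring: CensoringHazardCoefs = field(default_factory=CensoringHazardCoefs)
    dispensing: DispensingEmissionParams = field(default_factory=DispensingEmissionParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1")
        if self.n_quarters < 1:
            raise InvalidConfigError("n_quarters must be >= 1")

    def replace(self, **kwargs) -> "DGPConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DGPConfig":
        d = dict(d)
        sub = {
            "baseline": BaselineCovariateParams,
            "treatment": TreatmentModelCoefs,
            "dynamics": CovariateDynamicsCoefs,
            "event": EventHazardCoefs,
            "censoring": CensoringHazardCoefs,
            "dispensing": DispensingEmissionParams,
        }
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)


def null_effect_config(n_subjects: int = 2_000, seed: int = 0) -> DGPConfig:
    """DGP with a treatment-independent event hazard (both arms share one truth).

    The hazard ignores cumulative exposure *and* the treatment-affected score
    (otherwise treatment would still move risk through L), so the two
    regimens have identical counterfactual risk by construction.  The flat
    per-quarter hazard is 5e-4, giving a few dozen events per 2,000-subject
    cohort — enough that the large-sample curve-comparison test is
    exercised, while staying in the rare-event regime.
    """
    cfg = DGPConfig(n_subjects=n_subjects, seed=seed)
    cfg.event = EventHazardCoefs(
        intercept=-7.6, cumulative_exposure=0.0, L=0.0, frailty=0.0
    )
    return cfg


def randomized_treatment_config(n_subjects: int = 20_000, seed: int = 0) -> DGPConfig:
    """DGP whose treatment process ignores covariates (marginally randomized).

    Initiation/continuation/re-initiation keep realistic marginal rates but
    drop every covariate and cumulative-exposure term, so weighting and the
    crude compatible-person-time estimator target the same quantity.
    """
    cfg = DGPConfig(n_subjects=n_subjects, seed=seed)
    tm = cfg.treatment
    tm.init_L = tm.cont_L = 0.0
    tm.init_frailty = tm.cont_frailty = 0.0
    tm.cont_cumulative = 0.0
    tm.initiation_intercept = 2.9
    tm.continuation_intercept = 2.0
    tm.reinitiation_intercept = -3.4
    return cfg


def strong_effect_config(n_subjects: int = 2_000, seed: int = 0) -> DGPConfig:
    """DGP with a strong duration effect (cumulative-exposure log-odds 0.15/quarter)."""
    cfg = scaled_config(n_subjects, seed=seed)
    cfg.event.cumulative_exposure = 0.15
    return cfg


def scaled_config(n_subjects: int, seed: int = 0) -> DGPConfig:
    """Reference DGP rescaled to a smaller cohort.

    The event-hazard intercept is shifted by log(20000/n) so the expected
    number of events — what drives estimator stability — stays at the
    reference cohort's scale; confounding structure is unchanged.
    """
    cfg = DGPConfig(n_subjects=n_subjects, seed=seed)
    cfg.event.intercept = _rescaled_intercept(cfg.event.intercept, n_subjects)
    return cfg


def _rescaled_intercept(intercept: float, n_subjects: int, reference_n: int = 20_000) -> float:
    return float(intercept + np.log(reference_n / n_subjects))


@dataclass
class EstimationConfig:
    bootstrap_replicates: int = 200
    truncation_bound: float = 50.0
    propensity_floor: float = 1e-4
    never_mass: float | None = None  # default 1/(horizon-12+1)
    horizon: int = 40
    seed: int = 0


@dataclass
class PipelineConfig:
    out_dir: str = "stochmsm_out"
    dgp: DGPConfig = field(default_factory=DGPConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    write_plots: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "dgp" in d and isinstance(d["dgp"], dict):
            d["dgp"] = DGPConfig.from_dict(d["dgp"])
        if "estimation" in d and isinstance(d["estimation"], dict):
            d["estimation"] = EstimationConfig(**d["estimation"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if "dgp" not in raw or raw["dgp"] is None or "seed" not in raw.get("dgp", {}):
        raise InvalidConfigError("config must set dgp.seed explicitly")
    return PipelineConfig.from_dict(raw)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
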