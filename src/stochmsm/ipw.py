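"""Propensity models and inverse-probability weights.

Six models define the weights: logistic regressions for treatment
initiation (entry or re-initiation after a gap) and treatment continuation
(with a cumulative-exposure main term), and per-quarter hazards for each of
the four censoring causes — death, disenrollment, exclusion, and
administrative end of study.  Administrative end falls at the fixed
follow-up horizon for every subject here, so its model is degenerate by
construction and contributes weight 1.

Weights are cumulative over follow-up, stabilized (intervention-law
numerator for the treatment component, pooled marginal per-quarter
uncensored fractions for the censoring component) and truncated at 50 by
default.  A subject-quarter incompatible with an arm gets weight 0 from the
first incompatible quarter onwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine
from ._engine import LogisticFit, PanelArrays, WeightDiagnostics
from .cohort import CohortPanel


@dataclass
class PropensityModelSet:
    """Fitted treatment and censoring models plus a degenerate admin record."""

    continuation: LogisticFit
    initiation: LogisticFit
    death: LogisticFit
    disenroll: LogisticFit
    exclusion: LogisticFit
    admin_end: LogisticFit

    def as_dict(self) -> dict[str, LogisticFit]:
        return {
            "continuation": self.continuation,
            "initiation": self.initiation,
            "death": self.death,
            "disenroll": self.disenroll,
            "exclusion": self.exclusion,
        }

    def summary(self) -> dict:
        out = {k: v.summary() for k, v in self.as_dict().items()}
        out["admin_end"] = self.admin_end.summary()
        return out

    def write_report(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _as_arrays(panel) -> PanelArrays:
    if isinstance(panel, PanelArrays):
        return panel
    if isinstance(panel, CohortPanel):
        return _engine.panel_arrays_from_cohort(panel)
    return _engine.panel_arrays_from_frame(panel)


def fit_propensity_models(panel) -> PropensityModelSet:
    """Fit all propensity models on a quarterly panel.

    ``panel`` may be a :class:`CohortPanel`, a long panel DataFrame, or the
    engine's dense arrays.  Censoring causes with zero observed transitions
    are flagged degenerate (probability 0 downstream).
    """
    pa = _as_arrays(panel)
    fits = _engine.fit_panel_models(pa)
    admin = LogisticFit(
        "admin_end", (), np.zeros(0), np.zeros(0),
        n_obs=int(pa.valid.sum()), n_pos=0, degenerate=True, constant_p=0.0,
    )
    return PropensityModelSet(
        continuation=fits["continuation"],
        initiation=fits["initiation"],
        death=fits["death"],
        disenroll=fits["disenroll"],
        exclusion=fits["exclusion"],
        admin_end=admin,
    )


def _weight_frame(pa: PanelArrays, weights: dict[str, np.ndarray], bound: float) -> pd.DataFrame:
    frames = []
    for arm, w in weights.items():
        i, j = np.nonzero(pa.valid)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": i,
                    "t": j + 1,
                    "arm": arm,
                    "w": w[i, j],
                    "truncated": (w[i, j] >= bound).astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def compute_ipw_weights(
    panel,
    models: PropensityModelSet | None = None,
    horizon: int = 40,
    never_mass: float | None = None,
    truncation_bound: float = 50.0,
    propensity_floor: float = 1e-4,
) -> tuple[pd.DataFrame, WeightDiagnostics]:
    """Combined stabilized, truncated weights for both arms.

    Returns a long frame (subject_id, t, arm, w, truncated) and the weight
    diagnostics (median/IQR per arm, truncated fraction, floored cells).
    """
    pa = _as_arrays(panel)
    fits = (
        models.as_dict() if models is not None else _engine.fit_panel_models(pa)
    )
    arms = _engine.arm_matrices(pa, horizon=horizon, never_mass=never_mass)
    weights, diagnostics = _engine.compute_weights(
        pa, fits, arms,
        truncation_bound=truncation_bound, propensity_floor=propensity_floor,
    )
    return _weight_frame(pa, weights, truncation_bound), diagnostics


def treatment_weight(panel, models: PropensityModelSet, compliance: pd.DataFrame, arm: str) -> pd.DataFrame:
    """Treatment-only weight component for one arm (cumulative, stabilized).

    ``compliance`` is the output of :func:`stochmsm.regimens.evaluate_compliance`
    for the arm and supplies the intervention-law numerators.
    """
    pa = _as_arrays(panel)
    fits = models.as_dict()
    p_init = _engine.predict_cells(pa, fits["initiation"])
    p_cont = _engine.predict_cells(pa, fits["continuation"])
    p_on = np.where(pa.prev_on, p_cont, p_init)
    den = np.where(pa.A == 1, p_on, 1.0 - p_on)
    den = np.maximum(den, 1e-4)
    num = np.zeros_like(den)
    compat = np.zeros(pa.A.shape, dtype=bool)
    c = compliance[compliance["arm"] == arm]
    num[c["subject_id"].to_numpy(), c["t"].to_numpy() - 1] = c["intervention_prob"].to_numpy()
    compat[c["subject_id"].to_numpy(), c["t"].to_numpy() - 1] = c["compatible"].to_numpy()
    ratio = np.where(pa.valid, num / den, 1.0)
    tw = np.where(compat, np.cumprod(ratio, axis=1), 0.0)
    i, j = np.nonzero(pa.valid)
    return pd.DataFrame(
        {"subject_id": i, "t": j + 1, "arm": arm, "treatment_weight": tw[i, j]}
    )


def censoring_weight(panel, models: PropensityModelSet) -> pd.DataFrame:
    """Censoring-only weight component (shared across arms)."""
    pa = _as_arrays(panel)
    fits = models.as_dict()
    n, T = pa.A.shape
    p_unc = np.ones((n, T))
    for c in _engine.CENSOR_CAUSES:
        p_unc *= 1.0 - _engine.predict_cells(pa, fits[c])
    p_unc = np.maximum(p_unc, 1e-4)
    cens_any = np.zeros((n, T), dtype=bool)
    for c in _engine.CENSOR_CAUSES:
        cens_any |= pa.cens[c]
    denom_t = pa.valid.sum(axis=0)
    num_t = np.where(
        denom_t > 0, (pa.valid & ~cens_any).sum(axis=0) / np.maximum(denom_t, 1), 1.0
    )
    ratio = np.where(pa.valid, num_t[None, :] / p_unc, 1.0)
    cw = np.cumprod(ratio, axis=1)
    i, j = np.nonzero(pa.valid)
    return pd.DataFrame({"subject_id": i, "t": j + 1, "censoring_weight": cw[i, j]})


def combine_and_truncate(
    treatment_ws: pd.DataFrame, censoring_ws: pd.DataFrame, bound: float = 50.0
) -> pd.DataFrame:
    """w = treatment x censoring component, truncated at ``bound``.

    Adds a ``truncated`` flag and reports per-arm median/IQR and the
    truncated fraction as frame attrs.
    """
    merged = treatment_ws.merge(censoring_ws, on=["subject_id", "t"], validate="many_to_one")
    if len(merged) != len(treatment_ws):
        raise ValueError("treatment and censoring components are misaligned")
    raw = merged["treatment_weight"] * merged["censoring_weight"]
    merged["w"] = np.minimum(raw, bound)
    merged["truncated"] = (raw > bound).astype(int)
    summary = {}
    for arm, g in merged.groupby("arm"):
        active = g[g["treatment_weight"] > 0]
        summary[arm] = {
            "median": float(active["w"].median()) if len(active) else float("nan"),
            "iqr": (
                (float(active["w"].quantile(0.25)), float(active["w"].quantile(0.75)))
                if len(active)
                else (float("nan"),) * 2
            ),
            "fraction_truncated": float(active["truncated"].mean()) if len(active) else 0.0,
        }
    merged.attrs["summary"] = summary
    return merged[["subject_id", "t", "arm", "w", "truncated"]]
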