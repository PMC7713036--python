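"""End-to-end pipeline: simulate -> dispensing records -> quarterly panel ->
compliance -> weights -> counterfactual curves -> report.

Every run is driven by a :class:`stochmsm.config.PipelineConfig`, stamps its
outputs with a hash of that config, and is byte-reproducible under a fixed
seed.  The module also provides the test fixtures: a hand-written tiny
cohort whose estimates can be checked by exhaustive enumeration, and
simulated small/default cohorts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from . import _engine
from .cohort import CohortPanel, emit_dispensings, simulate_cohort
from .config import DGPConfig, PipelineConfig, scaled_config
from .estimation import estimate_counterfactual_curves
from .exposure import build_person_quarters
from .regimens import ARMS

log = logging.getLogger("stochmsm")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs of the run were removed."""


@dataclass
class RunManifest:
    config_hash: str
    version: str
    n_subjects: int
    n_events: int
    arm_entry_counts: dict[str, list[int]]  # at-risk compatible count per quarter
    panel_roundtrip_mismatches: int
    warnings: dict

    def validate(self) -> None:
        for arm, counts in self.arm_entry_counts.items():
            arr = np.asarray(counts)
            assert np.all(np.diff(arr) <= 0), f"{arm}: arm attrition not monotone"

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "n_subjects": self.n_subjects,
            "n_events": self.n_events,
            "arm_entry_counts": self.arm_entry_counts,
            "panel_roundtrip_mismatches": self.panel_roundtrip_mismatches,
            "warnings": self.warnings,
        }


def config_hash(config: PipelineConfig) -> str:
    """Hash of the scientific configuration (paths excluded)."""
    d = config.to_dict()
    d.pop("out_dir", None)
    payload = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def covariate_stream_from_cohort(panel: CohortPanel) -> pd.DataFrame:
    """Measurement stream (baseline + re-measurement quarters) for panel rebuild."""
    base_measured = panel.L_imputed[:, 0] == 0
    rows = pd.DataFrame(
        {
            "subject_id": np.arange(panel.n_subjects),
            "t": 0,
            "L_meas": np.where(base_measured, panel.L_obs[:, 0], np.nan),
            "age": panel.age,
            "frailty": panel.frailty,
        }
    )
    # re-measurement quarters are exactly the cells with time_since_meas == 0
    i, j = np.nonzero(panel.valid & (panel.t_since_meas == 0))
    upd = pd.DataFrame(
        {
            "subject_id": i,
            "t": j + 1,
            "L_meas": panel.L_obs[i, j],
            "age": panel.age[i],
            "frailty": panel.frailty[i],
        }
    )
    return pd.concat([rows, upd], ignore_index=True)


def rebuild_panel_from_records(panel: CohortPanel, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Emit dispensing records and rebuild the quarterly panel from them.

    Returns (rebuilt panel frame, dispensing records, number of
    on/off-classification mismatches against the simulated flags).
    """
    records = emit_dispensings(panel, seed=seed)
    stream = covariate_stream_from_cohort(panel)
    terminal = panel.subjects_frame()[["subject_id", "terminal_quarter", "terminal_cause"]]
    rebuilt = build_person_quarters(records, stream, terminal, fill_value=panel.config.baseline.fill_value)
    sim = panel.to_frame()[["subject_id", "t", "on_treatment"]]
    merged = rebuilt.merge(sim, on=["subject_id", "t"], suffixes=("", "_sim"))
    mismatches = int((merged["on_treatment"] != merged["on_treatment_sim"]).sum())
    return rebuilt, records, mismatches


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write the declared outputs under config.out_dir.

    A failing stage aborts with the stage name; files already written by the
    aborted run are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    est = config.estimation
    written: list[Path] = []
    stage = "simulate"
    try:
        log.info("stage simulate: n=%d T=%d seed=%d", config.dgp.n_subjects, config.dgp.n_quarters, config.dgp.seed)
        panel = simulate_cohort(config.dgp)
        written.extend(panel.write_csvs(out).values())

        stage = "dispense+rebuild"
        log.info("stage dispense+rebuild")
        rebuilt, records, mismatches = rebuild_panel_from_records(panel, seed=config.dgp.seed)
        records.to_csv(out / "dispensings.csv", index=False)
        rebuilt.to_csv(out / "panel_rebuilt.csv", index=False)
        written += [out / "dispensings.csv", out / "panel_rebuilt.csv"]

        stage = "estimate"
        log.info("stage estimate: B=%d", est.bootstrap_replicates)
        pa = _engine.panel_arrays_from_frame(rebuilt)
        result = estimate_counterfactual_curves(
            pa,
            horizon=est.horizon,
            never_mass=est.never_mass,
            truncation_bound=est.truncation_bound,
            propensity_floor=est.propensity_floor,
            B=est.bootstrap_replicates,
            seed=est.seed,
            include_crude=True,
        )

        stage = "report"

        def _surv_frame(curve_map):
            df = pd.concat([c.to_frame() for c in curve_map.values()], ignore_index=True)
            df["risk_per_100k"] = df["risk"] * 1e5
            df.insert(0, "config_hash", chash)
            return df

        _surv_frame(result.curves).to_csv(out / "survival.csv", index=False, float_format="%.10g")
        _surv_frame(result.crude_curves).to_csv(
            out / "crude_survival.csv", index=False, float_format="%.10g"
        )
        written += [out / "survival.csv", out / "crude_survival.csv"]

        arms = _engine.arm_matrices(pa, horizon=est.horizon, never_mass=est.never_mass)
        comp_frames = []
        for arm, am in arms.items():
            i, j = np.nonzero(pa.valid)
            comp_frames.append(
                pd.DataFrame(
                    {
                        "subject_id": i,
                        "t": j + 1,
                        "arm": arm,
                        "compatible": am.compatible[i, j].astype(int),
                        "intervention_prob": am.num[i, j],
                    }
                )
            )
        pd.concat(comp_frames, ignore_index=True).to_csv(
            out / "compliance.csv", index=False, float_format="%.10g"
        )
        written.append(out / "compliance.csv")

        rd_rows = []
        for t, rd in sorted(result.risk_differences.items()):
            rd_rows.append(
                {
                    "t": t,
                    "rd": rd.rd,
                    "rd_per_100k": rd.per_100k(),
                    "ci_low": rd.ci_low,
                    "ci_high": rd.ci_high,
                    "ci_method": rd.ci_method,
                    "replicates": rd.replicates,
                }
            )
        pd.DataFrame(rd_rows).to_csv(out / "risk_differences.csv", index=False, float_format="%.10g")
        written.append(out / "risk_differences.csv")

        if result.auc_test is not None:
            with open(out / "auc_test.json", "w") as fh:
                json.dump(
                    {
                        "config_hash": chash,
                        "auc_short": result.auc_test.auc_short,
                        "auc_long": result.auc_test.auc_long,
                        "difference": result.auc_test.difference,
                        "se": result.auc_test.se,
                        "p_value": result.auc_test.p_value,
                        "replicates": result.auc_test.replicates,
                        "seed": result.auc_test.seed,
                    },
                    fh,
                    indent=2,
                )
            written.append(out / "auc_test.json")
        with open(out / "models.json", "w") as fh:
            json.dump({"config_hash": chash, "models": result.models}, fh, indent=2)
        written.append(out / "models.json")

        if config.write_plots:
            from .plotting import plot_survival_curves

            written.append(plot_survival_curves(result.curves, out / "survival_curves.png"))

        entry_counts = {
            arm: (arms[arm].compatible & pa.atrisk).sum(axis=0).astype(int).tolist()
            for arm in ARMS
        }
        manifest = RunManifest(
            config_hash=chash,
            version=_version,
            n_subjects=panel.n_subjects,
            n_events=panel.n_events,
            arm_entry_counts=entry_counts,
            panel_roundtrip_mismatches=mismatches,
            warnings={
                "floored_propensity_cells": result.diagnostics.floored_cells,
                "truncated_fraction": result.diagnostics.truncated_fraction,
                "weight_median": result.diagnostics.median,
                "empty_risk_set_quarters": {
                    arm: int(h.empty_risk_set.sum()) for arm, h in result.hazards.items()
                },
            },
        )
        manifest.validate()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2)
        log.info("pipeline complete: %d events, hash %s", panel.n_events, chash)
        return manifest
    except Exception as exc:
        for path in written:
            Path(path).unlink(missing_ok=True)
        raise PipelineStageError(f"pipeline stage {stage!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# fixtures

#: Hand-written tiny cohort, 10 subjects x 8 quarters.  Treatment strings use
#: one character per quarter (1 on / 0 off); terminal events are
#: (cause, quarter) with "admin" meaning follow-up ran to the horizon.
#:
#: subject  exposure   terminal          arm compatibility (see regimens)
#: 0        11111111   admin @8          short 1-8, long 1-8
#: 1        11111...   event @5          short 1-5, long 1-5 (event both arms)
#: 2        11100000   admin @8          short 1-8, long 1-3
#: 3        110000     event @6          short 1-6 (event short only), long 1-2
#: 4        00000000   admin @8          short 1-8 (discontinue at 1), long never
#: 5        11110100   death @7          short 1-5 (restart @6), long 1-4
#: 6        1111....   death @4          short 1-4, long 1-4 (at risk 1-3)
#: 7        111.....   disenroll @3      short 1-3, long 1-3 (at risk 1-2)
#: 8        00111111   event @8          short 1-2 (restart @3), long never
#: 9        11111100   admin @8          short 1-8, long 1-6
TINY_SUBJECTS = [
    ("11111111", "admin", 8),
    ("11111", "event", 5),
    ("11100000", "admin", 8),
    ("110000", "event", 6),
    ("00000000", "admin", 8),
    ("1111010", "death", 7),
    ("1111", "death", 4),
    ("111", "disenroll", 3),
    ("00111111", "event", 8),
    ("11111100", "admin", 8),
]

TINY_QUARTERS = 8


def tiny_panel() -> CohortPanel:
    """Build the documented 10-subject, 8-quarter fixture as a CohortPanel."""
    n, T = len(TINY_SUBJECTS), TINY_QUARTERS
    cfg = DGPConfig(n_subjects=n, n_quarters=T, seed=0)
    A = np.zeros((n, T), dtype=np.int8)
    valid = np.zeros((n, T), dtype=bool)
    event = np.zeros((n, T), dtype=bool)
    censored_at = np.zeros((n, T), dtype=bool)
    terminal_quarter = np.zeros(n, dtype=np.int32)
    terminal_cause = np.empty(n, dtype=object)
    for i, (pattern, cause, tq) in enumerate(TINY_SUBJECTS):
        assert len(pattern) == tq
        A[i, :tq] = [int(ch) for ch in pattern]
        valid[i, :tq] = True
        terminal_quarter[i] = tq
        terminal_cause[i] = cause
        if cause == "event":
            event[i, tq - 1] = True
        elif cause in ("death", "disenroll", "exclusion"):
            censored_at[i, tq - 1] = True
    cum = np.cumsum(A, axis=1) * valid
    L = np.full((n, T), -2.5) * valid
    panel = CohortPanel(
        config=cfg,
        age=np.full(n, 70.0),
        frailty=np.zeros(n, dtype=np.int8),
        L0=np.full(n, -2.5),
        A=A,
        L=L,
        L_obs=L.copy(),
        L_imputed=np.zeros((n, T), dtype=np.int8),
        t_since_meas=(np.arange(1, T + 1)[None, :] * valid).astype(np.int16),
        cum_on=cum.astype(np.int16),
        valid=valid,
        event=event,
        censored_at=censored_at,
        terminal_quarter=terminal_quarter,
        terminal_cause=terminal_cause,
    )
    panel.validate()
    return panel


def make_fixture(scale: str, seed: int = 0, out_dir: str | Path | None = None):
    """Fixture cohorts: tiny (hand-written), small (2,000), default (20,000).

    Returns the CohortPanel; when ``out_dir`` is given, also writes
    subjects.csv / panel.csv / dispensings.csv there.
    """
    if scale == "tiny":
        panel = tiny_panel()
    elif scale == "small":
        panel = simulate_cohort(scaled_config(2_000, seed=seed))
    elif scale == "default":
        panel = simulate_cohort(DGPConfig(n_subjects=20_000, seed=seed))
    else:
        raise ValueError(f"unknown fixture scale {scale!r}")
    if out_dir is not None:
        panel.write_csvs(out_dir)
        emit_dispensings(panel, seed=seed).to_csv(
            Path(out_dir) / "dispensings.csv", index=False
        )
    return panel
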