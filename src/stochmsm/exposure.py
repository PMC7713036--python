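"""Quarterly exposure panel from dispensing records.

Drug exposure is reconstructed from pharmacy-style dispensing records
(subject, start day, days' supply).  Day 0 is the index date; quarter t
(1-based) is the half-open day interval [90(t-1), 90t).  A quarter counts as
"on treatment" when at least half of its 90 days are covered by dispensed
supply (proportion of days covered, PDC >= 0.50).

Overlapping prescriptions follow a stockpiling rule: when a refill arrives
while 30 or fewer covered days remain from the prior supply, the remainder
is carried forward (the new supply is appended after the old one runs out);
when more than 30 covered days remain, the new prescription takes precedence
and the earlier surplus is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

QUARTER_DAYS = 90
PDC_THRESHOLD = 0.50
STOCKPILE_LIMIT_DAYS = 30


class InvalidRecordError(ValueError):
    pass


@dataclass(frozen=True)
class DispensingRecord:
    subject_id: int
    start_day: int
    days_supply: int

    def __post_init__(self) -> None:
        if self.start_day < 0:
            raise InvalidRecordError(f"negative start_day {self.start_day}")
        if self.days_supply < 1:
            raise InvalidRecordError(f"nonpositive days_supply {self.days_supply}")


@dataclass
class CoverageCalendar:
    """Per-day covered/uncovered indicator over the follow-up horizon."""

    subject_id: int
    covered: np.ndarray  # bool, length horizon_days

    @property
    def horizon_days(self) -> int:
        return len(self.covered)


def expand_daily_coverage(
    records: list[DispensingRecord] | pd.DataFrame,
    horizon_days: int,
    subject_id: int | None = None,
) -> CoverageCalendar:
    """Apply dispensing records sequentially to build a day-level calendar.

    Records are processed in order of start day.  Coverage is tracked as a
    single running supply interval: a refill arriving with ``remaining``
    covered days left extends the interval by its full supply when
    ``remaining <= 30`` (stockpiling, coverage stays contiguous) and resets
    the interval end to ``start + supply`` when ``remaining > 30`` (the
    second prescription takes precedence; the earlier surplus beyond that
    point is discarded).  Coverage is clipped at ``horizon_days``.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    if isinstance(records, pd.DataFrame):
        recs = [
            DispensingRecord(int(r.subject_id), int(r.start_day), int(r.days_supply))
            for r in records.itertuples()
        ]
    else:
        recs = list(records)
    if subject_id is None:
        subject_id = recs[0].subject_id if recs else -1
    if any(r.subject_id != subject_id for r in recs):
        raise InvalidRecordError("records belong to multiple subjects")
    covered = np.zeros(horizon_days, dtype=bool)
    recs.sort(key=lambda r: (r.start_day, r.days_supply))
    cur_start = cur_end = 0  # current supply interval [cur_start, cur_end)
    for r in recs:
        s, d = r.start_day, r.days_supply
        if s >= cur_end:
            # no overlap: finalize previous interval, start fresh
            covered[cur_start : min(cur_end, horizon_days)] = True
            cur_start, cur_end = s, s + d
        else:
            remaining = cur_end - s
            if remaining <= STOCKPILE_LIMIT_DAYS:
                cur_end += d  # stockpile: append after prior supply ends
            else:
                # precedence: coverage before s is already consumed and kept;
                # from s the new prescription governs
                covered[cur_start : min(s, horizon_days)] = True
                cur_start, cur_end = s, s + d
    if cur_start < horizon_days:
        covered[cur_start : min(cur_end, horizon_days)] = True
    return CoverageCalendar(subject_id, covered)


def quarter_pdc(calendar: CoverageCalendar, t: int) -> float:
    """Proportion of quarter t's 90 days covered by supply."""
    if t < 1 or t * QUARTER_DAYS > calendar.horizon_days:
        raise IndexError(f"quarter {t} beyond calendar horizon")
    window = calendar.covered[(t - 1) * QUARTER_DAYS : t * QUARTER_DAYS]
    return float(window.sum()) / QUARTER_DAYS


def classify_on_treatment(pdc: float) -> bool:
    """On treatment iff PDC >= 0.50 (strict threshold at the boundary)."""
    if not 0.0 <= pdc <= 1.0:
        raise ValueError(f"pdc {pdc} outside [0, 1]")
    return pdc >= PDC_THRESHOLD


# -- quarterly panel assembly -------------------------------------------------

#: bone-density score categories used for reporting (worst to best ordering
#: follows clinical convention: above -2.0, -2.0..-2.4, -2.5..-2.9, <= -3.0)
L_CATEGORY_LABELS = ("above_-2.0", "-2.0_to_-2.4", "-2.5_to_-2.9", "<=_-3.0")


def l_category(value: float) -> str:
    if value > -2.0:
        return L_CATEGORY_LABELS[0]
    if value > -2.45:  # -2.0 to -2.4 at one-decimal clinical resolution
        return L_CATEGORY_LABELS[1]
    if value > -2.95:
        return L_CATEGORY_LABELS[2]
    return L_CATEGORY_LABELS[3]


def build_person_quarters(
    records: pd.DataFrame,
    covariate_stream: pd.DataFrame,
    terminal_events: pd.DataFrame,
    fill_value: float = -2.5,
) -> pd.DataFrame:
    """Assemble the quarterly analysis panel (one row per subject-quarter).

    Parameters
    ----------
    records : dispensing records (subject_id, start_day, days_supply).
    covariate_stream : measurements (subject_id, t, L_meas) plus one row per
        subject at t=0 for baseline (L_meas NaN when unmeasured), and
        baseline columns ``age`` and ``frailty`` on the t=0 rows.
    terminal_events : subject_id, terminal_quarter, terminal_cause in
        {"event", "death", "disenroll", "exclusion", "admin"}.

    Covariates are updated when a new measurement falls in the quarter and
    carried forward otherwise (no expiry); subjects never measured carry the
    cohort-mean fill value with an imputation indicator.
    """
    req = {"subject_id", "terminal_quarter", "terminal_cause"}
    if not req.issubset(terminal_events.columns):
        raise ValueError(f"terminal_events needs columns {sorted(req)}")
    bad = terminal_events.groupby("subject_id").size()
    if (bad > 1).any():
        raise ValueError("multiple terminal events for one subject")

    rec_by_subject = dict(tuple(records.groupby("subject_id"))) if len(records) else {}
    meas = covariate_stream.sort_values(["subject_id", "t"])
    base = meas[meas["t"] == 0].set_index("subject_id")
    follow = {
        sid: g[g["t"] > 0] for sid, g in meas.groupby("subject_id")
    }

    rows = []
    for te in terminal_events.sort_values("subject_id").itertuples():
        sid = te.subject_id
        T = int(te.terminal_quarter)
        if T < 1:
            raise ValueError(f"subject {sid}: terminal quarter {T} < 1")
        cal = expand_daily_coverage(
            rec_by_subject.get(sid, pd.DataFrame(columns=records.columns)),
            horizon_days=T * QUARTER_DAYS,
            subject_id=sid,
        )
        b = base.loc[sid]
        L_obs, imputed = (float(b.L_meas), 0) if np.isfinite(b.L_meas) else (fill_value, 1)
        last_meas_t = 0
        updates = follow.get(sid)
        upd = (
            {int(r.t): float(r.L_meas) for r in updates.itertuples()} if updates is not None else {}
        )
        cum_on = 0
        for t in range(1, T + 1):
            if t in upd:
                L_obs, imputed, last_meas_t = upd[t], 0, t
            pdc = quarter_pdc(cal, t)
            on = classify_on_treatment(pdc)
            cum_on += int(on)
            is_terminal = t == T
            rows.append(
                {
                    "subject_id": sid,
                    "t": t,
                    "pdc": pdc,
                    "on_treatment": int(on),
                    "cumulative_on_quarters": cum_on,
                    "L_obs": L_obs,
                    "L_category": l_category(L_obs),
                    "L_imputed": imputed,
                    "time_since_meas": t - last_meas_t,
                    "age": float(b.age),
                    "frailty": int(b.frailty),
                    "event": int(is_terminal and te.terminal_cause == "event"),
                    "censor_cause": (
                        te.terminal_cause
                        if is_terminal and te.terminal_cause not in ("event",)
                        else "none"
                    ),
                }
            )
    return pd.DataFrame(rows)


def impute_with_indicator(
    panel: pd.DataFrame, field: str, fill_value: float
) -> pd.DataFrame:
    """Replace missing values of ``field`` by ``fill_value``; add ``{field}_imputed``."""
    if field not in panel.columns:
        raise KeyError(f"unknown field {field!r}")
    out = panel.copy()
    missing = out[field].isna()
    out[field] = out[field].fillna(fill_value)
    out[f"{field}_imputed"] = missing.astype(int)
    return out
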