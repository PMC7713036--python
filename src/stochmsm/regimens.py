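"""Stochastic treatment regimens: discontinuation laws and compliance.

Two arms are compared.  Under the *short-term* arm a subject discontinues
treatment during the first 3 years (12 quarters), with the discontinuation
quarter uniform on {1, ..., 12}, and stays off afterwards (restarting is
incompatible with the arm).  Under the *longer-term* arm a subject stays on
treatment for the first 12 quarters and then either discontinues in one of
quarters 13..40 or never discontinues; by default every discontinuation
quarter and the "never" outcome carry equal mass (1/29 each), and the mass
of the "never" atom is configurable.

A subject whose observed treatment history has positive probability under an
arm's law is *compatible* with that arm and contributes person-time to it;
compatibility is absorbing-once-lost (artificial censoring).  A subject
continuously on treatment is compatible with both arms at once while her
history has positive probability under both laws (dual-arm contribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SHORT_TERM = "short_term"
LONGER_TERM = "longer_term"
ARMS = (SHORT_TERM, LONGER_TERM)

#: quarters in the forced window (3 years)
FORCED_QUARTERS = 12
#: default follow-up horizon in quarters (10 years)
HORIZON = 40


class InvalidArmError(ValueError):
    pass


@dataclass(frozen=True)
class RegimenSpec:
    """One stochastic arm: a probability law over the discontinuation quarter.

    ``masses`` maps discontinuation quarter d -> P(discontinue at d), where
    "discontinue at d" means on treatment for quarters < d and off from
    quarter d onwards with no restart.  ``never_mass`` is the probability of
    staying on treatment through the whole horizon (zero for the short-term
    arm).
    """

    arm_label: str
    horizon: int
    masses: dict[int, float] = field(repr=False)
    never_mass: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.masses.values()) + self.never_mass
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"discontinuation law masses sum to {total}, not 1")
        if any(m < 0 for m in self.masses.values()) or self.never_mass < 0:
            raise ValueError("negative probability mass in discontinuation law")

    def conditional_discontinuation_prob(self, t: int) -> float:
        """P(discontinue at quarter t | on treatment through t-1, compatible).

        The marginal uniform law is converted to a per-quarter conditional
        hazard: mass at t divided by the mass of all outcomes still possible
        at t (quarters >= t plus the "never" atom).
        """
        if not 1 <= t <= self.horizon:
            raise ValueError(f"quarter {t} outside 1..{self.horizon}")
        m_t = self.masses.get(t, 0.0)
        tail = sum(m for d, m in self.masses.items() if d >= t) + self.never_mass
        if tail <= 0:
            # history impossible under the law (e.g. still on after forced
            # discontinuation); caller treats observed "on" as probability 0
            return 1.0
        return m_t / tail


def discontinuation_law(
    arm_label: str, horizon: int = HORIZON, never_mass: float | None = None
) -> RegimenSpec:
    """Build the discontinuation law for one arm.

    short_term: uniform mass 1/12 on quarters 1..12 (discontinue within the
    first 3 years).  longer_term: forced continuation through quarter 12,
    then equal mass on each of quarters 13..horizon and on never
    discontinuing; ``never_mass`` overrides the weight of the "never" atom
    (default 1/(horizon-12+1), i.e. 1/29 at the 40-quarter horizon).
    """
    if arm_label == SHORT_TERM:
        if never_mass not in (None, 0.0):
            raise ValueError("short_term arm has no 'never discontinue' atom")
        masses = {d: 1.0 / FORCED_QUARTERS for d in range(1, FORCED_QUARTERS + 1)}
        return RegimenSpec(SHORT_TERM, horizon, masses, 0.0)
    if arm_label == LONGER_TERM:
        n_quarters = horizon - FORCED_QUARTERS
        if never_mass is None:
            never_mass = 1.0 / (n_quarters + 1)
        if not 0.0 <= never_mass < 1.0:
            raise ValueError("never_mass must lie in [0, 1)")
        per_quarter = (1.0 - never_mass) / n_quarters
        masses = {d: per_quarter for d in range(FORCED_QUARTERS + 1, horizon + 1)}
        return RegimenSpec(LONGER_TERM, horizon, masses, never_mass)
    raise InvalidArmError(f"unknown arm {arm_label!r}; expected one of {ARMS}")


def conditional_discontinuation_prob(spec: RegimenSpec, t: int) -> float:
    """Functional alias for :meth:`RegimenSpec.conditional_discontinuation_prob`."""
    return spec.conditional_discontinuation_prob(t)


def intervention_probability_matrix(
    on_treatment: np.ndarray, valid: np.ndarray, spec: RegimenSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell intervention probabilities and compatibility for one arm.

    Parameters
    ----------
    on_treatment : (n, T) 0/1 array of observed quarterly exposure.
    valid : (n, T) bool array; False after a subject's terminal quarter.
    spec : the arm's discontinuation law.

    Returns
    -------
    prob : (n, T) float array; the law's probability of the *observed*
        treatment value at each valid cell given the (compatible) history.
        Zero exactly where the observed action is impossible under the law.
    compatible : (n, T) bool array; True while the observed history through t
        has positive probability under the law.  Nonincreasing along t.
    """
    n, T = on_treatment.shape
    if T > spec.horizon:
        raise ValueError("panel horizon exceeds regimen horizon")
    q = np.array(
        [spec.conditional_discontinuation_prob(t) for t in range(1, T + 1)]
    )
    prob = np.zeros((n, T))
    compatible = np.zeros((n, T), dtype=bool)
    a = on_treatment.astype(bool)
    still_on = np.ones(n, dtype=bool)  # on through t-1, never discontinued
    alive_compat = np.ones(n, dtype=bool)
    for t in range(T):
        p_on = np.where(still_on, 1.0 - q[t], 0.0)  # restart prob is 0 once off
        p_obs = np.where(a[:, t], p_on, 1.0 - p_on)
        alive_compat &= p_obs > 0
        compatible[:, t] = alive_compat & valid[:, t]
        prob[:, t] = np.where(compatible[:, t], p_obs, 0.0)
        still_on &= a[:, t]
    return prob, compatible


def evaluate_compliance(panel: pd.DataFrame, spec: RegimenSpec) -> pd.DataFrame:
    """Per subject-quarter compatibility and intervention probability.

    ``panel`` needs columns ``subject_id``, ``t`` (1-based, contiguous per
    subject) and ``on_treatment``.  Returns a frame with columns
    ``subject_id, t, arm, compatible, intervention_prob``.
    """
    panel = panel.sort_values(["subject_id", "t"])
    grouped = panel.groupby("subject_id", sort=True)
    # panel integrity: quarters contiguous from 1
    for sid, g in grouped:
        tv = g["t"].to_numpy()
        if not np.array_equal(tv, np.arange(1, len(tv) + 1)):
            raise ValueError(f"subject {sid}: quarters not contiguous from 1")
    n = grouped.ngroups
    T = int(panel["t"].max())
    on = np.zeros((n, T), dtype=np.int8)
    valid = np.zeros((n, T), dtype=bool)
    sids = []
    for i, (sid, g) in enumerate(grouped):
        k = len(g)
        on[i, :k] = g["on_treatment"].to_numpy()
        valid[i, :k] = True
        sids.append(sid)
    prob, compat = intervention_probability_matrix(on, valid, spec)
    rows = []
    for i, sid in enumerate(sids):
        for t in range(T):
            if valid[i, t]:
                rows.append((sid, t + 1, spec.arm_label, bool(compat[i, t]), prob[i, t]))
    return pd.DataFrame(
        rows, columns=["subject_id", "t", "arm", "compatible", "intervention_prob"]
    )
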