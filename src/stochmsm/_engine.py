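"""Internal estimation engine on dense (n_subjects, n_quarters) arrays.

The public modules (:mod:`stochmsm.ipw`, :mod:`stochmsm.estimation`) are thin
wrappers over this engine.  Everything here is vectorized so that the
subject-level nonparametric bootstrap — which re-fits every propensity model
and recomputes every weight per replicate — runs at interactive speed:
bootstrap multiplicities enter the logistic fits as frequency weights on the
original design matrices (fitting on resampled stacked rows is algebraically
identical), and replicates are processed in batches through shared
per-cell Gram tensors.

Logistic fits use a Newton/IRLS solver written against numpy directly; it is
cross-validated against statsmodels GLM in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortPanel
from .regimens import (
    ARMS,
    RegimenSpec,
    discontinuation_law,
    intervention_probability_matrix,
)

CENSOR_CAUSES = ("death", "disenroll", "exclusion")

#: feature column order of the shared dense feature tensor
FEATURES = (
    "const",
    "entry",
    "L_obs",
    "L_imputed",
    "frailty",
    "age_std",
    "cum_prev",
    "t",
    "time_since_meas",
)

MODEL_FEATURES: dict[str, tuple[str, ...]] = {
    "initiation": ("const", "entry", "L_obs", "L_imputed", "frailty", "age_std", "t", "time_since_meas"),
    "continuation": ("const", "L_obs", "L_imputed", "frailty", "age_std", "cum_prev", "t", "time_since_meas"),
    "death": ("const", "L_obs", "L_imputed", "frailty", "age_std", "cum_prev", "t"),
    "disenroll": ("const", "L_obs", "L_imputed", "frailty", "age_std", "cum_prev", "t"),
    "exclusion": ("const", "L_obs", "L_imputed", "frailty", "age_std", "cum_prev", "t"),
}


class InferenceError(RuntimeError):
    pass


class FitError(RuntimeError):
    """A propensity model failed to converge (e.g. complete separation)."""


# ---------------------------------------------------------------------------
# panel arrays


@dataclass
class PanelArrays:
    """Dense estimation-facing view of a cohort panel."""

    A: np.ndarray            # (n, T) int8 observed on/off
    valid: np.ndarray        # (n, T) bool rows that exist
    atrisk: np.ndarray       # (n, T) bool at risk for the event (valid, not censored at t)
    event: np.ndarray        # (n, T) bool
    cens: dict[str, np.ndarray]  # cause -> (n, T) bool censored by that cause at t
    F: np.ndarray            # (n, T, q) shared feature tensor (FEATURES order)
    prev_on: np.ndarray      # (n, T) bool A(t-1)==1 (False at t=1)

    @property
    def n_subjects(self) -> int:
        return self.A.shape[0]

    @property
    def n_quarters(self) -> int:
        return self.A.shape[1]


def panel_arrays_from_cohort(panel: CohortPanel) -> PanelArrays:
    n, T = panel.A.shape
    cens = {c: np.zeros((n, T), dtype=bool) for c in CENSOR_CAUSES}
    for c in CENSOR_CAUSES:
        hit = panel.terminal_cause == c
        cens[c][hit, panel.terminal_quarter[hit] - 1] = True
    return _assemble(
        A=panel.A.astype(np.int8),
        valid=panel.valid,
        event=panel.event,
        cens=cens,
        L_obs=panel.L_obs,
        L_imputed=panel.L_imputed.astype(float),
        frailty=panel.frailty.astype(float)[:, None] * np.ones((1, T)),
        age_std=((panel.age - 70.0) / 10.0)[:, None] * np.ones((1, T)),
        t_since=panel.t_since_meas.astype(float),
        cum=panel.cum_on.astype(float),
    )


def panel_arrays_from_frame(df: pd.DataFrame) -> PanelArrays:
    """Build dense arrays from a long panel frame (see CohortPanel.to_frame)."""
    df = df.sort_values(["subject_id", "t"])
    sids = df["subject_id"].unique()
    n = len(sids)
    T = int(df["t"].max())
    pos = {s: i for i, s in enumerate(sids)}
    i = df["subject_id"].map(pos).to_numpy()
    j = df["t"].to_numpy() - 1

    def dense(col, dtype=float, fill=0.0):
        out = np.full((n, T), fill, dtype=dtype)
        out[i, j] = df[col].to_numpy()
        return out

    valid = np.zeros((n, T), dtype=bool)
    valid[i, j] = True
    cause = np.full((n, T), "none", dtype=object)
    cause[i, j] = df["censor_cause"].to_numpy()
    cens = {c: cause == c for c in CENSOR_CAUSES}
    return _assemble(
        A=dense("on_treatment", np.int8),
        valid=valid,
        event=dense("event", bool, False),
        cens=cens,
        L_obs=dense("L_obs"),
        L_imputed=dense("L_imputed"),
        frailty=dense("frailty"),
        age_std=(dense("age") - 70.0) / 10.0,
        t_since=dense("time_since_meas"),
        cum=dense("cumulative_on_quarters"),
    )


def _assemble(A, valid, event, cens, L_obs, L_imputed, frailty, age_std, t_since, cum):
    n, T = A.shape
    prev_on = np.zeros((n, T), dtype=bool)
    prev_on[:, 1:] = A[:, :-1] == 1
    cum_prev = np.zeros((n, T))
    cum_prev[:, 1:] = cum[:, :-1]
    tgrid = np.broadcast_to(np.arange(1, T + 1, dtype=float), (n, T))
    entry = np.zeros((n, T))
    entry[:, 0] = 1.0
    F = np.stack(
        [
            np.ones((n, T)),
            entry,
            L_obs,
            L_imputed,
            frailty,
            age_std,
            cum_prev,
            tgrid,
            t_since,
        ],
        axis=-1,
    )
    censored_at = np.zeros((n, T), dtype=bool)
    for c in CENSOR_CAUSES:
        censored_at |= cens[c]
    atrisk = valid & ~censored_at
    return PanelArrays(
        A=A, valid=valid, atrisk=atrisk, event=event, cens=cens, F=F, prev_on=prev_on
    )


# ---------------------------------------------------------------------------
# logistic fitting


@dataclass
class LogisticFit:
    name: str
    features: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    n_obs: int
    n_pos: int
    degenerate: bool = False
    constant_p: float = 0.0  # used when degenerate

    def summary(self) -> dict:
        return {
            "model": self.name,
            "n": self.n_obs,
            "events": self.n_pos,
            "degenerate": self.degenerate,
            "coef": {f: float(c) for f, c in zip(self.features, self.coef)},
            "se": {f: float(s) for f, s in zip(self.features, self.se)},
        }


def fit_logistic(X, y, freq_weight=None, beta0=None, max_iter=30, tol=1e-10, ridge=1e-10):
    """Newton/IRLS logistic regression with optional frequency weights.

    Returns (coef, se); raises :class:`FitError` when the Newton iteration
    has clearly not converged after ``max_iter`` steps (complete separation
    or a degenerate design).
    """
    m, p = X.shape
    w = np.ones(m) if freq_weight is None else freq_weight
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    H = np.empty((p, p))
    step_size = np.inf
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        r = w * (y - mu)
        grad = X.T @ r
        wirls = w * mu * (1.0 - mu)
        H = (X * wirls[:, None]).T @ X
        H[np.diag_indices_from(H)] += ridge
        step = np.linalg.solve(H, grad)
        beta += step
        step_size = np.max(np.abs(step))
        if step_size < tol:
            break
    if not np.isfinite(step_size) or step_size > 1e-4:
        raise FitError(f"logistic fit did not converge (last step {step_size:.3g})")
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


def _model_fit_mask(pa: PanelArrays, name: str) -> np.ndarray:
    if name == "initiation":
        return pa.valid & ~pa.prev_on
    if name == "continuation":
        return pa.valid & pa.prev_on
    if name == "death":
        return pa.valid
    if name == "disenroll":
        return pa.valid & ~pa.cens["death"]
    if name == "exclusion":
        return pa.valid & ~pa.cens["death"] & ~pa.cens["disenroll"]
    raise KeyError(name)


def _model_response(pa: PanelArrays, name: str) -> np.ndarray:
    if name in ("initiation", "continuation"):
        return pa.A == 1
    return pa.cens[name]


def fit_panel_models(
    pa: PanelArrays, freq: np.ndarray | None = None, warm: dict | None = None
) -> dict[str, LogisticFit]:
    """Fit the treatment and censoring propensity models on one panel.

    ``freq`` gives per-subject frequency weights (bootstrap multiplicities).
    A censoring cause with zero observed transitions is flagged degenerate
    and contributes probability 0 downstream.
    """
    fits: dict[str, LogisticFit] = {}
    fidx = {f: k for k, f in enumerate(FEATURES)}
    for name, feats in MODEL_FEATURES.items():
        mask = _model_fit_mask(pa, name)
        i, j = np.nonzero(mask)
        X = pa.F[i, j][:, [fidx[f] for f in feats]]
        y = _model_response(pa, name)[i, j].astype(float)
        w = None if freq is None else freq[i]
        wsum = y.sum() if freq is None else (w * y).sum()
        total = len(y) if freq is None else w.sum()
        if wsum == 0 or wsum == total:
            fits[name] = LogisticFit(
                name, feats, np.zeros(len(feats)), np.zeros(len(feats)),
                int(total), int(wsum), degenerate=True,
                constant_p=float(wsum > 0),
            )
            continue
        beta0 = warm[name].coef if warm and not warm[name].degenerate else None
        try:
            coef, se = fit_logistic(X, y, w, beta0=beta0)
        except FitError as e:
            raise FitError(f"{name} model: {e}") from e
        fits[name] = LogisticFit(name, feats, coef, se, int(total), int(round(float(wsum))))
    return fits


def predict_cells(pa: PanelArrays, fit: LogisticFit) -> np.ndarray:
    """Fitted probability at every cell (n, T) for one model."""
    if fit.degenerate:
        return np.full(pa.A.shape, fit.constant_p)
    fidx = {f: k for k, f in enumerate(FEATURES)}
    beta_full = np.zeros(len(FEATURES))
    for f, c in zip(fit.features, fit.coef):
        beta_full[fidx[f]] = c
    eta = np.clip(pa.F @ beta_full, -30.0, 30.0)
    return expit(eta)


# ---------------------------------------------------------------------------
# weights


@dataclass
class ArmMatrices:
    spec: RegimenSpec
    num: np.ndarray        # (n, T) intervention-law prob of observed action
    compatible: np.ndarray  # (n, T) bool


def arm_matrices(pa: PanelArrays, horizon: int, never_mass: float | None) -> dict[str, ArmMatrices]:
    out = {}
    for arm in ARMS:
        spec = discontinuation_law(
            arm, horizon=horizon, never_mass=never_mass if arm == "longer_term" else None
        )
        num, compat = intervention_probability_matrix(pa.A, pa.valid, spec)
        out[arm] = ArmMatrices(spec, num, compat)
    return out


@dataclass
class WeightDiagnostics:
    floored_cells: int = 0
    truncated_fraction: dict[str, float] = field(default_factory=dict)
    median: dict[str, float] = field(default_factory=dict)
    iqr: dict[str, tuple[float, float]] = field(default_factory=dict)


def compute_weights(
    pa: PanelArrays,
    fits: dict[str, LogisticFit],
    arms: dict[str, ArmMatrices],
    freq: np.ndarray | None = None,
    truncation_bound: float = 50.0,
    propensity_floor: float = 1e-4,
    collect_diagnostics: bool = True,
):
    """Cumulative stabilized, truncated weights per subject-quarter-arm.

    Treatment component: prod_k [law prob of observed action / fitted prob],
    i.e. self-stabilized by the intervention law.  Censoring component:
    prod_k [pooled marginal uncensored fraction / fitted joint uncensored
    probability].  Combined weights are truncated at ``truncation_bound``.
    Returns (weights dict arm -> (n, T), diagnostics).
    """
    n, T = pa.A.shape
    p_init = predict_cells(pa, fits["initiation"])
    p_cont = predict_cells(pa, fits["continuation"])
    p_on = np.where(pa.prev_on, p_cont, p_init)
    a = pa.A == 1
    den_trt = np.where(a, p_on, 1.0 - p_on)

    p_unc = np.ones((n, T))
    for c in CENSOR_CAUSES:
        p_unc *= 1.0 - predict_cells(pa, fits[c])

    # pooled marginal per-quarter uncensored fraction (stabilization numerator)
    fw = np.ones(n) if freq is None else freq
    valid_w = fw[:, None] * pa.valid
    cens_any = np.zeros((n, T), dtype=bool)
    for c in CENSOR_CAUSES:
        cens_any |= pa.cens[c]
    denom_t = valid_w.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        num_unc_t = np.where(
            denom_t > 0, (fw[:, None] * (pa.valid & ~cens_any)).sum(axis=0) / np.maximum(denom_t, 1.0), 1.0
        )

    floored = int(((den_trt < propensity_floor) & pa.valid).sum()) + int(
        ((p_unc < propensity_floor) & pa.valid).sum()
    )
    den_trt = np.maximum(den_trt, propensity_floor)
    p_unc = np.maximum(p_unc, propensity_floor)

    cens_ratio = np.where(pa.valid, num_unc_t[None, :] / p_unc, 1.0)
    cw = np.cumprod(cens_ratio, axis=1)

    diagnostics = WeightDiagnostics(floored_cells=floored)
    weights = {}
    for arm, am in arms.items():
        ratio = np.where(pa.valid, am.num / den_trt, 1.0)
        tw = np.cumprod(ratio, axis=1)
        w = tw * cw
        w = np.where(am.compatible, w, 0.0)
        truncated = w > truncation_bound
        w = np.minimum(w, truncation_bound)
        weights[arm] = w
        if collect_diagnostics:
            sel = am.compatible & pa.atrisk
            vals = w[sel]
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                diagnostics.median[arm] = float(med)
                diagnostics.iqr[arm] = (float(q1), float(q3))
                diagnostics.truncated_fraction[arm] = float(truncated[sel].mean())
            else:
                diagnostics.median[arm] = float("nan")
                diagnostics.iqr[arm] = (float("nan"), float("nan"))
                diagnostics.truncated_fraction[arm] = 0.0
    return weights, diagnostics


# ---------------------------------------------------------------------------
# hazards and curves


def weighted_hazard_arrays(
    pa: PanelArrays,
    w: np.ndarray,
    compatible: np.ndarray,
    freq: np.ndarray | None = None,
):
    """Weighted discrete-time hazard h(t) and the weighted sums behind it."""
    fw = np.ones(pa.n_subjects) if freq is None else freq
    sel = compatible & pa.atrisk
    wn = fw[:, None] * w
    num = (wn * (sel & pa.event)).sum(axis=0)
    den = (wn * sel).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return h, num, den


def survival_arrays(h: np.ndarray):
    S = np.cumprod(1.0 - h)
    return S, 1.0 - S


# ---------------------------------------------------------------------------
# full estimate on one (possibly reweighted) panel


@dataclass
class PointEstimate:
    arms: tuple[str, ...]
    hazard: dict[str, np.ndarray]
    survival: dict[str, np.ndarray]
    risk: dict[str, np.ndarray]
    auc: dict[str, float]
    empty_risk_set: dict[str, np.ndarray]
    diagnostics: WeightDiagnostics
    fits: dict[str, LogisticFit]


def estimate_once(
    pa: PanelArrays,
    arms: dict[str, ArmMatrices],
    freq: np.ndarray | None = None,
    warm: dict | None = None,
    truncation_bound: float = 50.0,
    propensity_floor: float = 1e-4,
    crude: bool = False,
) -> PointEstimate:
    """One full pass: fit models, compute weights, map to curves.

    ``crude=True`` skips weighting entirely (all weights 1 on compatible
    person-time) — the unadjusted comparator.
    """
    if crude:
        fits = {}
        weights = {arm: np.ones(pa.A.shape) for arm in arms}
        diagnostics = WeightDiagnostics()
    else:
        fits = fit_panel_models(pa, freq=freq, warm=warm)
        weights, diagnostics = compute_weights(
            pa, fits, arms, freq=freq,
            truncation_bound=truncation_bound, propensity_floor=propensity_floor,
        )
    hazard, survival, risk, auc, empty = {}, {}, {}, {}, {}
    for arm, am in arms.items():
        h, num, den = weighted_hazard_arrays(pa, weights[arm], am.compatible, freq)
        hazard[arm] = h
        empty[arm] = den == 0
        S, r = survival_arrays(h)
        survival[arm], risk[arm] = S, r
        auc[arm] = float(S.sum())
    return PointEstimate(
        arms=tuple(arms), hazard=hazard, survival=survival, risk=risk,
        auc=auc, empty_risk_set=empty, diagnostics=diagnostics, fits=fits,
    )


# ---------------------------------------------------------------------------
# batched bootstrap


def _fit_logistic_batch(X, y, cell_subject, M, beta0, n_iter=2, ridge=1e-6, G=None):
    """IRLS for K bootstrap replicates at once on a shared design matrix.

    M : (K, n) multiplicities; frequency weight of cell c in replicate k is
    M[k, cell_subject[c]].  Runs a fixed number of warm-started Newton
    steps — quadratic convergence from the full-data solution makes a short
    fixed schedule accurate far beyond bootstrap noise.  Works in float32
    (the batched path is memory-bandwidth bound); returns (K, p) float64
    coefficients.  ``G`` optionally carries the precomputed per-cell outer
    products X_c X_c' as an (m, p*p) float32 array.
    """
    m, p = X.shape
    K = M.shape[0]
    X32 = X.astype(np.float32, copy=False)
    y32 = y.astype(np.float32, copy=False)
    Wc = M[:, cell_subject].astype(np.float32)     # (K, m)
    if G is None:
        G = (X32[:, :, None] * X32[:, None, :]).reshape(m, p * p)
    beta = np.tile(beta0.astype(np.float32), (K, 1))
    eye = (np.eye(p) * ridge).astype(np.float32)
    for _ in range(n_iter):
        eta = X32 @ beta.T                         # (m, K)
        mu = expit(eta)
        R = Wc * (y32[:, None] - mu).T             # (K, m)
        grad = R @ X32                             # (K, p)
        wirls = Wc * (mu * (1.0 - mu)).T           # (K, m)
        H = (wirls @ G).reshape(K, p, p) + eye
        step = np.linalg.solve(H.astype(np.float64), grad[:, :, None].astype(np.float64))[:, :, 0]
        beta += step.astype(np.float32)
    return beta.astype(np.float64)


def _predict_batch(F32: np.ndarray, feats, beta):
    """(n, T, K) fitted probabilities for a batch of coefficient vectors."""
    fidx = {f: k for k, f in enumerate(FEATURES)}
    K = beta.shape[0]
    beta_full = np.zeros((K, len(FEATURES)), dtype=np.float32)
    for col, f in enumerate(feats):
        beta_full[:, fidx[f]] = beta[:, col]
    n, T, q = F32.shape
    eta = (F32.reshape(n * T, q) @ beta_full.T).reshape(n, T, K)
    return expit(eta)


@dataclass
class BootstrapResult:
    arms: tuple[str, ...]
    risk: dict[str, np.ndarray]   # (B_kept, T) replicate risk curves
    auc: dict[str, np.ndarray]    # (B_kept,)
    n_requested: int
    n_dropped: int
    seed: int

    @property
    def n_kept(self) -> int:
        return self.n_requested - self.n_dropped


def bootstrap_panel(
    pa: PanelArrays,
    arms: dict[str, ArmMatrices],
    B: int,
    seed: int,
    truncation_bound: float = 50.0,
    propensity_floor: float = 1e-4,
    warm: dict | None = None,
    max_drop_fraction: float = 0.20,
    chunk_size: int | None = None,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap with full model re-fit.

    Each replicate resamples subjects with replacement (encoded as
    multiplicities), re-fits all propensity models, recomputes weights and
    curves.  Replicates with an empty weighted risk set in any quarter of
    either arm are dropped; more than ``max_drop_fraction`` dropped raises
    :class:`InferenceError`.
    """
    if B < 50:
        raise ValueError("need at least 50 bootstrap replicates")
    n, T = pa.A.shape
    rng = np.random.default_rng(seed)
    if warm is None:
        warm = fit_panel_models(pa)
    if chunk_size is None:
        # keep the (n, T, K) work arrays near ~64 MB each
        chunk_size = max(1, min(B, int(8e6 // max(n * T, 1)), 128))

    fidx = {f: k for k, f in enumerate(FEATURES)}
    model_cells = {}
    for name, feats in MODEL_FEATURES.items():
        mask = _model_fit_mask(pa, name)
        i, j = np.nonzero(mask)
        X = pa.F[i, j][:, [fidx[f] for f in feats]].astype(np.float32)
        y = _model_response(pa, name)[i, j].astype(np.float32)
        m, p = X.shape
        G = (X[:, :, None] * X[:, None, :]).reshape(m, p * p)
        model_cells[name] = (X, y, i, G)
    F32 = pa.F.astype(np.float32)

    a = pa.A == 1
    cens_any = np.zeros((n, T), dtype=bool)
    for c in CENSOR_CAUSES:
        cens_any |= pa.cens[c]
    uncens = pa.valid & ~cens_any

    risk_out = {arm: [] for arm in arms}
    auc_out = {arm: [] for arm in arms}
    dropped = 0
    done = 0
    while done < B:
        K = min(chunk_size, B - done)
        M = rng.multinomial(n, np.full(n, 1.0 / n), size=K)
        betas = {}
        degenerate_p = {}
        for name, (X, y, cell_subj, G) in model_cells.items():
            if warm[name].degenerate:
                degenerate_p[name] = warm[name].constant_p
                continue
            betas[name] = _fit_logistic_batch(X, y, cell_subj, M, warm[name].coef, G=G)

        def batch_pred(name):
            if name in degenerate_p:
                return np.full((n, T, K), degenerate_p[name], dtype=np.float32)
            return _predict_batch(F32, MODEL_FEATURES[name], betas[name])

        p_on = np.where(
            pa.prev_on[:, :, None], batch_pred("continuation"), batch_pred("initiation")
        )
        den_trt = np.where(a[:, :, None], p_on, np.float32(1.0) - p_on)
        np.maximum(den_trt, np.float32(propensity_floor), out=den_trt)
        p_unc = np.ones((n, T, K), dtype=np.float32)
        for c in CENSOR_CAUSES:
            p_unc *= np.float32(1.0) - batch_pred(c)
        np.maximum(p_unc, np.float32(propensity_floor), out=p_unc)

        Mf = M.astype(np.float32)                  # (K, n)
        denom_t = Mf @ pa.valid                    # (K, T)
        with np.errstate(divide="ignore", invalid="ignore"):
            num_unc = np.where(denom_t > 0, (Mf @ uncens) / np.maximum(denom_t, 1.0), 1.0)
        cens_ratio = np.where(
            pa.valid[:, :, None], num_unc.T[None, :, :].astype(np.float32) / p_unc, np.float32(1.0)
        )
        cw = np.cumprod(cens_ratio, axis=1)

        keep = np.ones(K, dtype=bool)
        chunk_risk = {}
        chunk_auc = {}
        valid32 = pa.valid[:, :, None]
        for arm, am in arms.items():
            ratio = np.where(valid32, am.num[:, :, None].astype(np.float32) / den_trt, np.float32(1.0))
            w = np.cumprod(ratio, axis=1)
            w *= cw
            w = np.where(am.compatible[:, :, None], w, np.float32(0.0))
            np.minimum(w, np.float32(truncation_bound), out=w)
            sel = (am.compatible & pa.atrisk)
            wsel = w * sel[:, :, None]
            den = np.einsum("itk,ki->kt", wsel, Mf)
            num = np.einsum("itk,ki->kt", wsel * (pa.event & sel)[:, :, None], Mf)
            keep &= (den > 0).all(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.where(den > 0, num / np.maximum(den, np.float32(1e-30)), 0.0).astype(np.float64)
            S = np.cumprod(1.0 - h, axis=1)
            chunk_risk[arm] = 1.0 - S
            chunk_auc[arm] = S.sum(axis=1)
        dropped += int((~keep).sum())
        for arm in arms:
            risk_out[arm].append(chunk_risk[arm][keep])
            auc_out[arm].append(chunk_auc[arm][keep])
        done += K

    if dropped > max_drop_fraction * B:
        raise InferenceError(
            f"{dropped}/{B} bootstrap replicates had empty weighted risk sets"
        )
    return BootstrapResult(
        arms=tuple(arms),
        risk={arm: np.concatenate(risk_out[arm], axis=0) for arm in arms},
        auc={arm: np.concatenate(auc_out[arm]) for arm in arms},
        n_requested=B,
        n_dropped=dropped,
        seed=seed,
    )
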