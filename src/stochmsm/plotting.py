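"""Survival-curve figures for pipeline reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .estimation import SurvivalCurve

_ARM_LABELS = {"short_term": "Short-term (< 3 years)", "longer_term": "Longer-term (≥ 3 years)"}
_ARM_COLORS = {"short_term": "#1f77b4", "longer_term": "#d62728"}


def plot_survival_curves(
    curves: dict[str, SurvivalCurve], path: str | Path, per_100k: bool = True
) -> Path:
    """Step plot of per-arm cumulative event risk (with CI bands if present)."""
    scale = 1e5 if per_100k else 1.0
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for arm, c in curves.items():
        color = _ARM_COLORS.get(arm)
        ax.step(c.t, c.risk * scale, where="post", label=_ARM_LABELS.get(arm, arm), color=color)
        if c.ci_low is not None:
            ax.fill_between(
                c.t, c.ci_low * scale, c.ci_high * scale, step="post", alpha=0.15, color=color
            )
    ax.set_xlabel("Quarter of follow-up")
    ax.set_ylabel("Cumulative event risk" + (" (per 100,000)" if per_100k else ""))
    ax.legend(frameon=False)
    ax.set_xlim(0, max(int(c.t[-1]) for c in curves.values()))
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
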