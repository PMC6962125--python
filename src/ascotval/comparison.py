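"""Full-state-space scoring under two tariffs and agreement statistics.

Scores all 4^8 = 65,536 states under two tariff/conversion pairs and
reports: how often one tariff scores strictly higher, the Pearson
correlation, and the intraclass correlation.  The default ICC is the
two-way, absolute-agreement, single-measures form ICC(A,1) — the
conventional choice when the question is whether two tariffs assign the
*same* value to a state, not merely proportional values — and all six
common variants are reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .states import state_level_matrix
from .tariffs import ConversionParams, WeightTable, latent_scores_all_states

__all__ = [
    "ComparisonReport",
    "compare_tariffs",
    "icc_agreement",
    "icc_variants",
    "plot_comparison",
]

ICC_VARIANTS = ("icc1", "icc_a1", "icc_c1", "icc1k", "icc_ak", "icc_ck")


def _icc_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_variants(a: np.ndarray, b: np.ndarray) -> dict[str, float]:
    """All six common ICC forms for paired scores (two raters)."""
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    msr, msc, mse, n, k = _icc_mean_squares(x)
    msw = (x.var(axis=1, ddof=0).sum() * k / (k - 1)) / n  # one-way within MS
    denom_a1 = msr + (k - 1) * mse + k / n * (msc - mse)
    # degenerate inputs (zero row variance) legitimately yield inf/nan
    # for the consistency forms; callers see them in the variant sweep
    with np.errstate(divide="ignore", invalid="ignore"):
        out = {
            "icc1": (msr - msw) / (msr + (k - 1) * msw),
            "icc_a1": (msr - mse) / denom_a1,
            "icc_c1": (msr - mse) / (msr + (k - 1) * mse),
            "icc1k": (msr - msw) / msr,
            "icc_ak": (msr - mse) / (msr + (msc - mse) / n),
            "icc_ck": (msr - mse) / msr,
        }
    return {k_: float(v) for k_, v in out.items()}


def icc_agreement(a: np.ndarray, b: np.ndarray, variant: str = "icc_a1") -> float:
    """ICC of paired scores; default two-way absolute-agreement single-measures."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("ICC undefined: both score vectors are constant")
    values = icc_variants(a, b)
    if variant not in values:
        raise ValueError(f"unknown ICC variant {variant!r}; choose from {ICC_VARIANTS}")
    return values[variant]


@dataclass
class ComparisonReport:
    """Cross-tariff comparison over the full state space."""

    label_a: str
    label_b: str
    n_states: int
    n_b_higher: int  # strict B > A
    n_a_higher: int
    n_ties: int
    pct_b_higher: float
    pearson: float
    icc: float
    icc_variant: str
    icc_all_variants: dict[str, float]
    min_a: float
    max_a: float
    min_b: float
    max_b: float
    scores: pd.DataFrame | None = field(default=None, repr=False)

    def summary_dict(self) -> dict:
        return {
            k: v for k, v in self.__dict__.items() if k != "scores"
        }

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.summary_dict(), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def compare_tariffs(
    tariff_a: WeightTable,
    conv_a: ConversionParams,
    tariff_b: WeightTable,
    conv_b: ConversionParams,
    icc_variant: str = "icc_a1",
    keep_scores: bool = False,
) -> ComparisonReport:
    """Score all 65,536 states under both tariffs and compare.

    "Higher" is strict inequality; ties are counted separately so the
    three counts always sum to 65,536.
    """
    score_a = np.asarray(conv_a.apply(latent_scores_all_states(tariff_a)))
    score_b = np.asarray(conv_b.apply(latent_scores_all_states(tariff_b)))
    n = len(score_a)
    n_b = int((score_b > score_a).sum())
    n_a = int((score_a > score_b).sum())
    variants = icc_variants(score_a, score_b)
    scores = None
    if keep_scores:
        levels = state_level_matrix()
        strings = np.array(
            ["".join(map(str, row)) for row in levels], dtype=object
        )
        scores = pd.DataFrame(
            {"state": strings, "score_a": score_a, "score_b": score_b}
        )
    report = ComparisonReport(
        label_a=tariff_a.label,
        label_b=tariff_b.label,
        n_states=n,
        n_b_higher=n_b,
        n_a_higher=n_a,
        n_ties=n - n_a - n_b,
        pct_b_higher=100.0 * n_b / n,
        pearson=float(np.corrcoef(score_a, score_b)[0, 1]),
        icc=variants[icc_variant],
        icc_variant=icc_variant,
        icc_all_variants=variants,
        min_a=float(score_a.min()),
        max_a=float(score_a.max()),
        min_b=float(score_b.min()),
        max_b=float(score_b.max()),
        scores=scores,
    )
    return report


def plot_comparison(
    score_a: np.ndarray,
    score_b: np.ndarray,
    label_a: str = "A",
    label_b: str = "B",
    path: str | Path | None = None,
):
    """Scatter plot of paired state scores with the identity line.

    Requires matplotlib (an optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(score_a, score_b, ".", markersize=1, alpha=0.2, rasterized=True)
    lo = min(float(np.min(score_a)), float(np.min(score_b)))
    hi = max(float(np.max(score_a)), float(np.max(score_b)))
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=0.8)
    ax.set_xlabel(f"{label_a} SC-QALY score")
    ax.set_ylabel(f"{label_b} SC-QALY score")
    ax.set_aspect("equal")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
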