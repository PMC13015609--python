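"""Uncertainty-based triage: answer the confident cases, defer the rest.

A selective predictor retains only cases whose uncertainty falls at or below
a threshold; *coverage* is the retained fraction and *selective accuracy* the
accuracy among retained cases.  Besides thresholding on a single signal
(combined / aleatoric / epistemic), a weighted signal
``w_a * aleatoric + (1 - w_a) * epistemic`` can be scanned over a grid of
weights and coverage levels to find the mix that best ranks errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoverageCurve",
    "WeightGrid",
    "combined_uncertainty",
    "coverage_accuracy_curve",
    "accuracy_at_coverage",
    "weight_coverage_grid",
    "plot_coverage_curves",
]


@dataclass(frozen=True)
class CoverageCurve:
    """Coverage and selective accuracy as the retention threshold sweeps up."""

    signal: str
    thresholds: np.ndarray
    coverage: np.ndarray
    selective_accuracy: np.ndarray   # NaN where no case is retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"signal": self.signal, "threshold": self.thresholds,
                             "coverage": self.coverage,
                             "selective_accuracy": self.selective_accuracy})


@dataclass(frozen=True)
class WeightGrid:
    """Accuracy over (aleatoric weight) x (coverage level) cells."""

    w_a: np.ndarray
    coverages: np.ndarray
    accuracy: np.ndarray             # shape (|w_a|, |coverages|)
    best_w_a: np.ndarray             # argmax w_a per coverage (first on ties)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"w_a": wa, "coverage": cov, "accuracy": self.accuracy[i, j]}
                for i, wa in enumerate(self.w_a)
                for j, cov in enumerate(self.coverages)]
        return pd.DataFrame(rows)


def combined_uncertainty(aleatoric_norm: np.ndarray, epistemic_norm: np.ndarray,
                         w_a: float | None = None) -> np.ndarray:
    """Weighted mix of the two normalized components.

    With ``w_a=None`` ("sum" mode) the plain sum is returned, which equals the
    normalized total uncertainty by the additive identity.  Otherwise the mix
    is ``w_a * aleatoric + (1 - w_a) * epistemic``.
    """
    a = np.asarray(aleatoric_norm, dtype=float)
    e = np.asarray(epistemic_norm, dtype=float)
    if w_a is None:
        return a + e
    if not 0.0 <= w_a <= 1.0:
        raise ValueError("w_a must lie in [0, 1]")
    return w_a * a + (1.0 - w_a) * e


def coverage_accuracy_curve(uncertainties: np.ndarray, correct: np.ndarray,
                            thresholds: np.ndarray | None = None,
                            signal: str = "combined") -> CoverageCurve:
    """Sweep retention thresholds; retained = uncertainty <= threshold.

    At the largest threshold the curve ends at coverage 1 and overall
    accuracy.  Empty retained sets record NaN selective accuracy.
    """
    u = np.asarray(uncertainties, dtype=float)
    c = np.asarray(correct, dtype=float)
    if len(u) == 0 or len(u) != len(c):
        raise ValueError("need equal-length, non-empty inputs")
    if thresholds is None:
        thresholds = np.unique(u)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    cov = np.empty(len(thresholds))
    acc = np.empty(len(thresholds))
    for i, tau in enumerate(thresholds):
        keep = u <= tau
        cov[i] = keep.mean()
        acc[i] = c[keep].mean() if keep.any() else np.nan
    return CoverageCurve(signal=signal, thresholds=thresholds,
                         coverage=cov, selective_accuracy=acc)


def accuracy_at_coverage(uncertainties: np.ndarray, correct: np.ndarray,
                         coverage_target: float) -> float:
    """Accuracy among the ``floor(coverage * n)`` lowest-uncertainty cases.

    Rank-based (stable mergesort on ties) rather than threshold-based, so the
    realized coverage is exact, and the result is invariant to any strictly
    monotone transform of the uncertainty signal.
    """
    if not 0.0 < coverage_target <= 1.0:
        raise ValueError("coverage_target must lie in (0, 1]")
    u = np.asarray(uncertainties, dtype=float)
    c = np.asarray(correct, dtype=float)
    n_keep = math.floor(coverage_target * len(u))
    if n_keep == 0:
        raise ValueError("coverage target retains zero cases")
    order = np.argsort(u, kind="stable")
    return float(c[order[:n_keep]].mean())


def weight_coverage_grid(aleatoric_norm: np.ndarray, epistemic_norm: np.ndarray,
                         correct: np.ndarray,
                         w_a_grid: np.ndarray | None = None,
                         coverage_grid: np.ndarray = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
                         ) -> WeightGrid:
    """Scan aleatoric/epistemic weightings across coverage levels."""
    if w_a_grid is None:
        w_a_grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    w_a_grid = np.asarray(w_a_grid, dtype=float)
    coverage_grid = np.asarray(coverage_grid, dtype=float)
    if len(w_a_grid) == 0 or len(coverage_grid) == 0:
        raise ValueError("grids must be non-empty")
    acc = np.empty((len(w_a_grid), len(coverage_grid)))
    for i, wa in enumerate(w_a_grid):
        u = combined_uncertainty(aleatoric_norm, epistemic_norm, wa)
        for j, cov in enumerate(coverage_grid):
            acc[i, j] = accuracy_at_coverage(u, correct, cov)
    best = w_a_grid[np.argmax(acc, axis=0)]
    return WeightGrid(w_a=w_a_grid, coverages=coverage_grid,
                      accuracy=acc, best_w_a=best)


def plot_coverage_curves(curves: list[CoverageCurve], out_path=None):
    """Accuracy and coverage vs threshold, one panel per uncertainty signal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(curves), figsize=(4 * len(curves), 3.2),
                             squeeze=False)
    for ax, curve in zip(axes[0], curves):
        ax.plot(curve.thresholds, curve.selective_accuracy, label="selective accuracy")
        ax.plot(curve.thresholds, curve.coverage, "--", label="coverage")
        ax.set_xlabel(f"{curve.signal} uncertainty threshold")
        ax.set_ylim(0, 1.05)
        ax.legend(fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
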