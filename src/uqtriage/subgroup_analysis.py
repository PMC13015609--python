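"""Kyoto-threshold categorization and the subgroup statistical battery.

Cases are categorized along four clinically motivated dimensions — dysplasia
risk group, IPMN type (BD vs MD), type-specific size bin (cyst diameter bins
<15 / 15-30 / >30 mm for BD; main-duct diameter <10 / >=10 mm for MD),
anatomical region and extent of pancreatic involvement.  Accuracy differences
across categories are tested with exact conditional tests on r x 2
correct/incorrect contingency tables (Fisher for 2 x 2, the Freeman-Halton
generalization for r > 2, both by full enumeration of margin-fixed tables);
continuous uncertainty differences with one-way ANOVA plus Tukey-adjusted
pairwise comparisons; and discrimination with ROC/AUC, the Youden operating
point, and the Brier score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import f_oneway

from .synthetic_data import REGION_TO_EXTENT, CaseRecord

__all__ = [
    "CategoryAssignment",
    "ContingencyTable",
    "MetricSet",
    "categorize_case",
    "subgroup_accuracy_table",
    "fisher_exact",
    "anova_tukey",
    "roc_youden_brier",
    "subgroup_report",
]

BD_BINS = ("<15", "15-30", ">30")
MD_BINS = ("<10", ">=10")


@dataclass(frozen=True)
class CategoryAssignment:
    risk: str
    ipmn_type: str
    size_bin: str
    region: str
    extent: str


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 [correct, incorrect] counts per category."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] != len(self.labels):
            raise ValueError("counts must be r x 2 with one row per label")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    def accuracies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1)
        return np.divide(self.counts[:, 0], totals, where=totals > 0,
                         out=np.full(len(totals), np.nan))


@dataclass(frozen=True)
class MetricSet:
    auc: float
    sensitivity: float
    specificity: float
    youden_threshold: float
    brier: float
    accuracy: float


def categorize_case(record: CaseRecord) -> CategoryAssignment:
    """Deterministic four-dimensional category assignment.

    BD bins by maximum cyst diameter with the upper bin strictly above 30 mm
    (so exactly 30.0 mm falls in "15-30"); MD bins by main pancreatic duct
    diameter at the 10 mm high-risk-stigma cut (10.0 mm falls in ">=10").
    """
    if record.size_mm <= 0:
        raise ValueError("size_mm must be positive")
    if record.ipmn_type == "BD":
        if record.size_mm < 15:
            size_bin = "<15"
        elif record.size_mm <= 30:
            size_bin = "15-30"
        else:
            size_bin = ">30"
    else:
        size_bin = "<10" if record.size_mm < 10 else ">=10"
    return CategoryAssignment(risk=record.label, ipmn_type=record.ipmn_type,
                              size_bin=size_bin, region=record.region,
                              extent=REGION_TO_EXTENT[record.region])


def subgroup_accuracy_table(correct: Sequence[bool], categories: Sequence[str],
                            order: Sequence[str] | None = None,
                            ) -> tuple[ContingencyTable, pd.DataFrame]:
    """Per-category correct/incorrect counts and accuracies for one dimension.

    Empty categories (possible when ``order`` is given explicitly) are kept in
    the summary with zero counts but dropped from the contingency table, since
    exact tests require positive row margins.
    """
    correct = np.asarray(correct, dtype=bool)
    categories = np.asarray(categories)
    if len(correct) != len(categories):
        raise ValueError("correct flags and categories must align")
    if order is None:
        order = list(pd.unique(categories))
    rows, labels = [], []
    summary = []
    for cat in order:
        m = categories == cat
        n, c = int(m.sum()), int(correct[m].sum())
        summary.append({"category": cat, "n": n, "correct": c,
                        "accuracy": c / n if n else np.nan})
        if n > 0:
            labels.append(cat)
            rows.append([c, n - c])
    table = ContingencyTable(labels=tuple(labels), counts=np.array(rows, dtype=int))
    return table, pd.DataFrame(summary)


# ---------------------------------------------------------------------------
# Exact conditional tests
# ---------------------------------------------------------------------------

def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided exact conditional test on an r x 2 table.

    Conditional on all margins, the probability of a table is the
    multivariate hypergeometric mass; the two-sided p-value sums the masses
    of all margin-fixed tables whose probability does not exceed the observed
    one (the Freeman-Halton extension; for r = 2 this is the classical
    two-sided Fisher test).  The enumeration is exact: row count vectors are
    enumerated in two halves, and the halves are matched on the first-column
    margin with a sorted-prefix sum, which keeps the 6 x 2 tables of a
    170-case cohort well under a second.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, int)
    if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
        raise ValueError("need an r x 2 table with r >= 2")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin: test undefined")
    c1 = int(cols[0])
    n = int(counts.sum())
    obs_log = float(sum(_log_binom(int(rows[i]), counts[i, 0]) for i in range(len(rows))))
    thresh = obs_log + 1e-7 * max(1.0, abs(obs_log))
    log_const = gammaln(c1 + 1) + gammaln(n - c1 + 1) - gammaln(n + 1)

    def enumerate_half(row_sizes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sums = np.zeros(1, dtype=int)
        logs = np.zeros(1)
        for R in row_sizes:
            a = np.arange(int(R) + 1)
            la = _log_binom(int(R), a)
            sums = (sums[:, None] + a[None, :]).ravel()
            logs = (logs[:, None] + la[None, :]).ravel()
            keep = sums <= c1
            sums, logs = sums[keep], logs[keep]
        return sums, logs

    half = max(1, len(rows) // 2)
    sA, lA = enumerate_half(rows[:half])
    sB, lB = enumerate_half(rows[half:])

    buckets: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for s in np.unique(sB):
        ls = np.sort(lB[sB == s])
        buckets[int(s)] = (ls, np.cumsum(np.exp(ls + log_const)))

    p = 0.0
    for s, l in zip(sA, lA):
        b = buckets.get(c1 - int(s))
        if b is None:
            continue
        ls, prefix = b
        j = int(np.searchsorted(ls, thresh - l, side="right"))
        if j > 0:
            p += float(np.exp(l) * prefix[j - 1])
    return min(p, 1.0)


# ---------------------------------------------------------------------------
# ANOVA with Tukey adjustment
# ---------------------------------------------------------------------------

def anova_tukey(values: Sequence[float], groups: Sequence[str]) -> dict:
    """One-way ANOVA F-test plus Tukey-HSD-adjusted pairwise comparisons.

    Groups with fewer than two observations are excluded with a warning.
    Returns the overall p-value, a pairwise frame (group1, group2, mean
    difference, adjusted p), and per-group means with pooled-variance
    standard errors (the estimated marginal means of the one-way model).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"groups {small} have <2 observations; excluded from ANOVA")
        keep = ~np.isin(groups, small)
        values, groups = values[keep], groups[keep]
    names = pd.unique(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups with >=2 observations")
    by_group = [values[groups == g] for g in names]
    p_overall = float(f_oneway(*by_group).pvalue)

    n_total = len(values)
    dof = n_total - len(names)
    mse = sum(((v - v.mean()) ** 2).sum() for v in by_group) / dof
    group_means = pd.DataFrame({
        "group": names,
        "n": [len(v) for v in by_group],
        "mean": [v.mean() for v in by_group],
        "sem": [np.sqrt(mse / len(v)) for v in by_group],
    })

    tk = pairwise_tukeyhsd(values, groups)
    i_idx, j_idx = tk._multicomp.pairindices
    pairwise = pd.DataFrame({
        "group1": [str(tk.groupsunique[i]) for i in i_idx],
        "group2": [str(tk.groupsunique[j]) for j in j_idx],
        "meandiff": tk.meandiffs,
        "p_adj": tk.pvalues,
    })
    return {"p_value": p_overall, "pairwise": pairwise, "group_means": group_means}


# ---------------------------------------------------------------------------
# Discrimination metrics
# ---------------------------------------------------------------------------

def roc_youden_brier(scores: Sequence[float], labels: Sequence[int]) -> MetricSet:
    """AUC, Youden-point sensitivity/specificity, Brier score, and accuracy.

    The operating point maximizes ``sensitivity + specificity - 1``; on ties
    the lowest threshold wins.  Accuracy uses the 0.5 probability cut.
    """
    from sklearn.metrics import brier_score_loss, roc_auc_score, roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    j = tpr - fpr
    # roc_curve thresholds are descending; the last argmax among ties is the
    # lowest threshold
    best = len(j) - 1 - int(np.argmax(j[::-1]))
    return MetricSet(
        auc=auc,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        youden_threshold=float(thresholds[best]),
        brier=float(brier_score_loss(labels, np.clip(scores, 0, 1))),
        accuracy=float(np.mean((scores >= 0.5).astype(int) == labels)),
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def subgroup_report(cases: Sequence[CaseRecord], correct: Sequence[bool],
                    uncertainty: Sequence[float]) -> pd.DataFrame:
    """Accuracy, exact-test p, and uncertainty summary per dimension/category.

    One tidy frame mirroring the study's subgroup table: for each
    categorization dimension, per-category n, accuracy (%), the dimension's
    exact-test p-value on correct/incorrect counts, mean uncertainty with
    s.e.m., and the dimension's ANOVA p-value on uncertainty.
    """
    correct = np.asarray(correct, dtype=bool)
    uncertainty = np.asarray(uncertainty, dtype=float)
    assign = [categorize_case(c) for c in cases]
    dims = {
        "risk": [a.risk for a in assign],
        "type": [a.ipmn_type for a in assign],
        "bd_size": [a.size_bin if a.ipmn_type == "BD" else None for a in assign],
        "md_size": [a.size_bin if a.ipmn_type == "MD" else None for a in assign],
        "region": [a.region for a in assign],
        "extent": [a.extent for a in assign],
    }
    out = []
    for dim, cats in dims.items():
        cats = np.asarray(cats, dtype=object)
        mask = np.array([c is not None for c in cats])
        if mask.sum() == 0:
            continue
        sub_correct = correct[mask]
        sub_unc = uncertainty[mask]
        sub_cats = cats[mask].astype(str)
        table, summary = subgroup_accuracy_table(sub_correct, sub_cats)
        p_fisher = fisher_exact(table) if len(table.labels) >= 2 else np.nan
        counts = pd.Series(sub_cats).value_counts()
        if (counts >= 2).sum() >= 2 and np.std(sub_unc) > 0:
            p_anova = anova_tukey(sub_unc, sub_cats)["p_value"]
        else:
            p_anova = np.nan
        for _, row in summary.iterrows():
            m = sub_cats == row["category"]
            out.append({
                "dimension": dim, "category": row["category"], "n": row["n"],
                "accuracy_pct": 100.0 * row["accuracy"],
                "fisher_p": p_fisher,
                "uncertainty_mean": float(sub_unc[m].mean()) if m.any() else np.nan,
                "uncertainty_sem": float(sub_unc[m].std(ddof=1) / np.sqrt(m.sum()))
                                   if m.sum() > 1 else np.nan,
                "anova_p": p_anova,
            })
    return pd.DataFrame(out)
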