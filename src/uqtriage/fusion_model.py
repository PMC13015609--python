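"""Two-branch classifier and decision-level fusion.

The classifier couples a bagged decision-tree ensemble on radiomic features
(47 trees, per-tree leaf class-frequency outputs) with a small dropout network
(the "DL" branch).  Their probability outputs are combined by a thresholded
decision rule with two hyperparameters:

* threshold ``t`` — when the radiomics branch's maximum class probability
  strictly exceeds ``t``, its prediction is used alone;
* weight ``k`` — otherwise the fused output is ``(1-k)*p_rad + k*p_dl``.

``(t, k)`` are chosen by grid search under stratified five-fold
cross-validation.  Evaluation uses held-out-center "trials" of one or two
whole centers each, with metrics pooled by test-set-size weighted averaging.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from ._nn import DropoutMLP

__all__ = [
    "FusionParams",
    "TrialSplit",
    "BranchModels",
    "select_features",
    "fit_branches",
    "fuse_probabilities",
    "grid_search_fusion",
    "make_trial_splits",
    "weighted_average_metrics",
    "DEFAULT_T_GRID",
    "DEFAULT_K_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_T_GRID = tuple(np.round(np.arange(0.50, 1.001, 0.05), 2))
DEFAULT_K_GRID = tuple(np.round(np.arange(0.0, 1.001, 0.1), 1))

#: Trial test-set sizes used on the study cohort.
TRIAL_TEST_SIZES = (29, 35, 35, 75)


@dataclass(frozen=True)
class FusionParams:
    """Decision-level fusion hyperparameters."""

    t: float
    k: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.t <= 1.0 and 0.0 <= self.k <= 1.0):
            raise ValueError("t and k must lie in [0, 1]")


@dataclass(frozen=True)
class TrialSplit:
    """One held-out-center evaluation split."""

    trial_id: int
    test_centers: tuple[int, ...]
    train_centers: tuple[int, ...]
    n_test: int

    def __post_init__(self) -> None:
        if set(self.test_centers) & set(self.train_centers):
            raise ValueError("test and train center sets must be disjoint")


@dataclass
class BranchModels:
    """The two fitted branches plus the feature subset they were trained on."""

    radiomics: RandomForestClassifier
    dl: DropoutMLP
    feature_idx: np.ndarray
    n_trees: int = 47
    dropout: float = 0.3

    def per_tree_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(n_cases, n_trees, n_classes) leaf class-frequency vectors."""
        Xs = np.asarray(X, dtype=float)[:, self.feature_idx]
        return np.stack([t.predict_proba(Xs) for t in self.radiomics.estimators_], axis=1)

    def radiomics_probabilities(self, X: np.ndarray) -> np.ndarray:
        return self.radiomics.predict_proba(np.asarray(X, dtype=float)[:, self.feature_idx])

    def dl_probabilities(self, X: np.ndarray,
                         rng: np.random.Generator | None = None) -> np.ndarray:
        return self.dl.predict_proba(np.asarray(X, dtype=float)[:, self.feature_idx], rng=rng)


def _rank_corr(a: np.ndarray, b: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(a, b).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def _greedy_select(X: np.ndarray, y: np.ndarray, rho_max: float,
                   order: Sequence[int]) -> list[int]:
    kept: list[int] = []
    for j in order:
        if all(abs(_rank_corr(X[:, j], X[:, i])) < rho_max for i in kept):
            kept.append(j)
    return sorted(kept)


def select_features(X: np.ndarray, y: np.ndarray, rho_max: float = 0.6,
                    n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Redundancy-filtered feature subset.

    Features are ranked once by absolute Spearman correlation with the label
    on the full training data (a stable ordering; per-fold rankings of
    near-duplicate features would elect different representatives in
    different folds and the intersection would discard the whole block).
    The greedy redundancy pass — retain a feature iff its absolute Spearman
    correlation with every already-retained feature is below ``rho_max``,
    computed on the fold's data — runs inside stratified ``n_folds``-fold
    cross-validation, and the per-fold selections are intersected, so only
    features whose retention is stable across folds survive.  Constant
    features are excluded with a logged warning.
    """
    if not 0.0 < rho_max <= 1.0:
        raise ValueError("rho_max must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) < 2:
        raise ValueError("need at least two cases")
    y_codes = pd.factorize(y)[0]

    usable = []
    for j in range(X.shape[1]):
        if np.std(X[:, j]) == 0:
            logger.warning("feature %d is constant; excluded from selection", j)
            continue
        usable.append(j)
    if not usable:
        raise ValueError("all features are constant")
    order = sorted(usable, key=lambda j: -abs(_rank_corr(X[:, j], y_codes)))

    n_folds = min(n_folds, int(np.bincount(y_codes).min()))
    if n_folds < 2:
        selected = set(_greedy_select(X, y_codes, rho_max, order))
    else:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        selected = None
        for train_idx, _ in skf.split(X, y_codes):
            fold = set(_greedy_select(X[train_idx], y_codes[train_idx],
                                      rho_max, order))
            selected = fold if selected is None else (selected & fold)
    if not selected:
        raise ValueError("feature selection removed every feature")
    return np.array(sorted(selected), dtype=int)


def fit_branches(X: np.ndarray, y: np.ndarray, feature_idx: np.ndarray | None = None,
                 n_trees: int = 47, dropout: float = 0.3, min_samples_leaf: int = 5,
                 mlp_hidden: tuple[int, ...] = (32, 16), mlp_epochs: int = 300,
                 seed: int = 0) -> BranchModels:
    """Fit both branches on one training cohort.

    The radiomics branch is a 47-tree bagged ensemble whose per-tree outputs
    are leaf class-frequency vectors (``min_samples_leaf`` keeps leaves impure
    so trees emit soft probabilities rather than hard votes).  The DL branch
    is a dropout MLP on the same selected features; dropout stays active at
    inference for Monte Carlo sampling.  Refits under the same seed are
    identical.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort must contain both classes")
    if feature_idx is None:
        feature_idx = np.arange(X.shape[1])
    feature_idx = np.asarray(feature_idx, dtype=int)
    Xs = X[:, feature_idx]
    rf = RandomForestClassifier(n_estimators=n_trees, min_samples_leaf=min_samples_leaf,
                                random_state=seed)
    rf.fit(Xs, y)
    mlp = DropoutMLP(n_features=len(feature_idx), n_classes=2, hidden=mlp_hidden,
                     dropout=dropout, seed=seed).fit(Xs, y, epochs=mlp_epochs)
    return BranchModels(radiomics=rf, dl=mlp, feature_idx=feature_idx,
                        n_trees=n_trees, dropout=dropout)


def fuse_probabilities(p_rad: np.ndarray, p_dl: np.ndarray,
                       params: FusionParams) -> np.ndarray:
    """Decision-level fusion of two class-probability vectors (or batches).

    If the radiomics branch's maximum class probability strictly exceeds
    ``t``, the radiomics vector is returned unchanged (the DL prediction is
    discarded); otherwise the output is the elementwise weighted combination
    ``(1 - k) * p_rad + k * p_dl``.
    """
    p_rad = np.asarray(p_rad, dtype=float)
    p_dl = np.asarray(p_dl, dtype=float)
    if p_rad.shape != p_dl.shape:
        raise ValueError("probability vectors must have matching shapes")
    for p in (p_rad, p_dl):
        if np.any(p < -1e-9) or np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
            raise ValueError("inputs must be probability vectors summing to 1")
    confident = p_rad.max(axis=-1) > params.t
    blended = (1.0 - params.k) * p_rad + params.k * p_dl
    return np.where(confident[..., None], p_rad, blended)


def grid_search_fusion(X: np.ndarray, y: np.ndarray,
                       t_grid: Sequence[float] = DEFAULT_T_GRID,
                       k_grid: Sequence[float] = DEFAULT_K_GRID,
                       feature_idx: np.ndarray | None = None,
                       n_folds: int = 5, seed: int = 0,
                       **fit_kwargs) -> FusionParams:
    """Pick ``(t, k)`` maximizing mean cross-validated fused accuracy.

    Both branches are refit on each training fold; fused accuracy on the
    validation fold is averaged over folds for every grid point.  Ties are
    broken toward smaller ``k`` then smaller ``t``.
    """
    if len(t_grid) == 0 or len(k_grid) == 0:
        raise ValueError("grids must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc = np.zeros((len(k_grid), len(t_grid)))
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        models = fit_branches(X[tr], y[tr], feature_idx=feature_idx,
                              seed=seed + fold, **fit_kwargs)
        p_rad = models.radiomics_probabilities(X[va])
        p_dl = models.dl_probabilities(X[va])
        for ki, k in enumerate(k_grid):
            for ti, t in enumerate(t_grid):
                fused = fuse_probabilities(p_rad, p_dl, FusionParams(t=float(t), k=float(k)))
                acc[ki, ti] += np.mean(fused.argmax(axis=1) == y[va])
    acc /= n_folds
    best_k, best_t, best = 0, 0, -np.inf
    for ki in range(len(k_grid)):          # ascending k, then ascending t:
        for ti in range(len(t_grid)):      # strict '>' implements the tie-break
            if acc[ki, ti] > best + 1e-12:
                best, best_k, best_t = acc[ki, ti], ki, ti
    return FusionParams(t=float(t_grid[best_t]), k=float(k_grid[best_k]))


def make_trial_splits(centers: Sequence[int], labels: Sequence[str] | None = None,
                      target_sizes: Sequence[int] = TRIAL_TEST_SIZES,
                      ) -> list[TrialSplit]:
    """Build held-out-center trials with test sets of 1–2 whole centers.

    Searches for unions of one or two centers whose case counts match
    ``target_sizes`` exactly (preferring unused centers; centers may repeat
    across trials, as trials are independent splits), falling back to the
    closest achievable size.  Raises if any trial would leave a class absent
    from its train or test side.
    """
    centers = np.asarray(centers)
    uniq = np.unique(centers)
    if len(uniq) < 4:
        raise ValueError("need at least 4 centers to form 4 trials")
    sizes = {int(c): int(np.sum(centers == c)) for c in uniq}
    combos: list[tuple[tuple[int, ...], int]] = [((int(c),), sizes[int(c)]) for c in uniq]
    cl = [int(c) for c in uniq]
    for i in range(len(cl)):
        for j in range(i + 1, len(cl)):
            combos.append(((cl[i], cl[j]), sizes[cl[i]] + sizes[cl[j]]))

    splits: list[TrialSplit] = []
    used: set[int] = set()
    chosen: set[tuple[int, ...]] = set()
    for trial_id, target in enumerate(target_sizes, start=1):
        def cost(item):
            cs, n = item
            return (abs(n - target), len(set(cs) & used), len(cs))
        cand = min((c for c in combos if c[0] not in chosen), key=cost)
        test_cs, n_test = cand
        chosen.add(test_cs)
        used.update(test_cs)
        train_cs = tuple(c for c in cl if c not in test_cs)
        splits.append(TrialSplit(trial_id=trial_id, test_centers=test_cs,
                                 train_centers=train_cs, n_test=n_test))

    if labels is not None:
        labels = np.asarray(labels)
        bad = []
        for s in splits:
            te = np.isin(centers, s.test_centers)
            if len(np.unique(labels[te])) < 2 or len(np.unique(labels[~te])) < 2:
                bad.append(s.trial_id)
        if bad:
            raise ValueError(f"trials {bad} lack both classes in train or test")
    return splits


def weighted_average_metrics(per_trial: Sequence[Mapping] | pd.DataFrame,
                             ns: Sequence[int]) -> dict[str, float]:
    """Pool per-trial metrics by test-set-size weighted arithmetic mean."""
    frame = pd.DataFrame(list(per_trial))
    ns = np.asarray(ns, dtype=float)
    if len(frame) != len(ns):
        raise ValueError("metrics and ns must have equal length")
    if ns.sum() <= 0:
        raise ValueError("total n must be positive")
    w = ns / ns.sum()
    return {col: float(np.dot(w, frame[col].to_numpy(dtype=float)))
            for col in frame.columns}


def save_bundle(models: BranchModels, params: FusionParams, out_dir: str | Path) -> None:
    """Serialize a fitted model bundle to a directory with a JSON manifest."""
    import joblib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    joblib.dump(models.radiomics, out / "radiomics_forest.joblib")
    joblib.dump(models.dl, out / "dl_branch.joblib")
    manifest = {
        "fusion_params": {"t": params.t, "k": params.k},
        "feature_idx": [int(i) for i in models.feature_idx],
        "n_trees": models.n_trees,
        "dropout": models.dropout,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_bundle(in_dir: str | Path) -> tuple[BranchModels, FusionParams]:
    import joblib

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    models = BranchModels(
        radiomics=joblib.load(src / "radiomics_forest.joblib"),
        dl=joblib.load(src / "dl_branch.joblib"),
        feature_idx=np.asarray(manifest["feature_idx"], dtype=int),
        n_trees=manifest["n_trees"],
        dropout=manifest["dropout"],
    )
    fp = manifest["fusion_params"]
    return models, FusionParams(t=fp["t"], k=fp["k"])
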