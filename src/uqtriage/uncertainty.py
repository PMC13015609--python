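"""Predictive-entropy uncertainty decomposition over paired branch samples.

For one case, the two branches provide a family of class-probability vectors:
``n_passes`` Monte Carlo dropout forward passes from the network and
``n_trees`` per-tree leaf-frequency vectors from the ensemble (30 x 47 = 1410
samples at the study's settings).  Every (pass, tree) pair is combined through
the trained fusion rule, giving predictive samples ``p_t``.  With
``p_hat = mean_t p_t``:

* total uncertainty       ``H(p_hat) = -sum_c p_hat_c log(p_hat_c + eps)``
* aleatoric uncertainty   ``E[H(p)] = mean_t H(p_t)`` (irreducible data
  ambiguity — each sample is itself unsure)
* epistemic uncertainty   ``I = H(p_hat) - E[H(p)]`` (mutual information
  between prediction and model posterior — the samples disagree)

all in nats, each normalized by the maximum possible entropy ``log(C)`` so
scores are comparable across class counts.  ``total = aleatoric + epistemic``
holds by construction, and ``epistemic >= 0`` by Jensen's inequality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fusion_model import BranchModels, FusionParams, fuse_probabilities

__all__ = [
    "EPSILON",
    "PredictiveSampleSet",
    "UncertaintyScores",
    "mc_forward_passes",
    "pair_branch_samples",
    "mean_probability",
    "total_entropy",
    "aleatoric_uncertainty",
    "epistemic_uncertainty",
    "normalize_uncertainty",
    "score_case",
    "score_cohort",
]

#: Numerical stability constant added inside the logarithm.
EPSILON = 1e-12


@dataclass(frozen=True)
class PredictiveSampleSet:
    """T x C matrix of per-sample class-probability vectors."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[0] < 1:
            raise ValueError("samples must be a T x C matrix with T >= 1")
        if np.any(s < -1e-9) or np.any(np.abs(s.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("every row must be a probability vector summing to 1")
        object.__setattr__(self, "samples", s)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_classes(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class UncertaintyScores:
    """Raw (nats) and log(C)-normalized uncertainty values for one case."""

    mean_prob: np.ndarray
    total: float
    aleatoric: float
    epistemic: float
    total_norm: float
    aleatoric_norm: float
    epistemic_norm: float
    epsilon: float = EPSILON

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.mean_prob))


class InconsistentInputsError(ValueError):
    pass


def mc_forward_passes(model, X: np.ndarray, n_passes: int = 30,
                      seed: int = 0) -> np.ndarray:
    """Stochastic dropout forward passes; (n_cases, n_passes, C).

    Requires a model with active dropout — a zero-dropout model would return
    ``n_passes`` identical vectors and silently report zero epistemic signal,
    so that is rejected.
    """
    if getattr(model, "dropout", 0.0) <= 0.0:
        raise ValueError("model has no stochastic (dropout) layers; "
                         "MC sampling would be degenerate")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    rng = np.random.default_rng(seed)
    passes = [model.predict_proba(X, rng=rng) for _ in range(n_passes)]
    return np.stack(passes, axis=1)


def pair_branch_samples(pass_probs: np.ndarray, tree_probs: np.ndarray,
                        params: FusionParams) -> PredictiveSampleSet:
    """Cartesian pairing of dropout passes with ensemble trees for one case.

    Each (pass, tree) pair is combined through the trained fusion rule,
    yielding ``n_passes * n_trees`` fused predictive samples.
    """
    pass_probs = np.atleast_2d(np.asarray(pass_probs, dtype=float))
    tree_probs = np.atleast_2d(np.asarray(tree_probs, dtype=float))
    if pass_probs.shape[1] != tree_probs.shape[1]:
        raise ValueError("pass and tree samples must share the class dimension")
    n_passes, C = pass_probs.shape
    n_trees = tree_probs.shape[0]
    rad = np.repeat(tree_probs[None, :, :], n_passes, axis=0)   # (P, T, C)
    dl = np.repeat(pass_probs[:, None, :], n_trees, axis=1)     # (P, T, C)
    fused = fuse_probabilities(rad.reshape(-1, C), dl.reshape(-1, C), params)
    return PredictiveSampleSet(samples=fused)


def mean_probability(samples: PredictiveSampleSet) -> np.ndarray:
    return samples.samples.mean(axis=0)


def _entropy(p: np.ndarray, epsilon: float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return -np.sum(p * np.log(p + epsilon), axis=-1)


def total_entropy(mean_prob: np.ndarray, epsilon: float = EPSILON) -> float:
    """Shannon entropy of the mean prediction, in nats."""
    return float(_entropy(mean_prob, epsilon))


def aleatoric_uncertainty(samples: PredictiveSampleSet,
                          epsilon: float = EPSILON) -> float:
    """Expected per-sample entropy across the T predictive samples, in nats."""
    return float(_entropy(samples.samples, epsilon).mean())


def epistemic_uncertainty(total: float, aleatoric: float) -> float:
    """Mutual information ``total - aleatoric``; tiny negative noise clamped."""
    diff = total - aleatoric
    if diff < -1e-9:
        raise InconsistentInputsError(
            f"epistemic uncertainty {diff} is strongly negative; "
            "total and aleatoric were not computed from the same samples")
    return max(diff, 0.0)


def normalize_uncertainty(value: float, n_classes: int) -> float:
    """Divide by the maximum possible entropy log(C)."""
    if n_classes < 2:
        raise ValueError("normalization needs at least 2 classes")
    return float(value) / float(np.log(n_classes))


def scores_from_samples(samples: PredictiveSampleSet,
                        epsilon: float = EPSILON) -> UncertaintyScores:
    """Full decomposition of one predictive sample set."""
    p_hat = mean_probability(samples)
    tot = total_entropy(p_hat, epsilon)
    ale = aleatoric_uncertainty(samples, epsilon)
    epi = epistemic_uncertainty(tot, ale)
    C = samples.n_classes
    return UncertaintyScores(
        mean_prob=p_hat, total=tot, aleatoric=ale, epistemic=epi,
        total_norm=normalize_uncertainty(tot, C),
        aleatoric_norm=normalize_uncertainty(ale, C),
        epistemic_norm=normalize_uncertainty(epi, C),
        epsilon=epsilon)


def score_case(models: BranchModels, x: np.ndarray, params: FusionParams,
               n_passes: int = 30, seed: int = 0,
               epsilon: float = EPSILON) -> UncertaintyScores:
    """End-to-end uncertainty for a single feature vector."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    tree_probs = models.per_tree_probabilities(x)[0]
    pass_probs = mc_forward_passes(models.dl, x[:, models.feature_idx],
                                   n_passes=n_passes, seed=seed)[0]
    samples = pair_branch_samples(pass_probs, tree_probs, params)
    return scores_from_samples(samples, epsilon)


def score_cohort(models: BranchModels, X: np.ndarray, params: FusionParams,
                 case_ids: list[str] | None = None, n_passes: int = 30,
                 seed: int = 0, epsilon: float = EPSILON) -> pd.DataFrame:
    """Vectorized per-case uncertainty table for a whole cohort.

    Returns a frame with columns ``case_id, pred_class, p_high, total,
    aleatoric, epistemic, total_norm, aleatoric_norm, epistemic_norm``.
    All cases share one seeded dropout-mask stream and are paired and scored
    in a single broadcast.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    tree_probs = models.per_tree_probabilities(X)            # (n, T, C)
    pass_probs = mc_forward_passes(models.dl, X[:, models.feature_idx],
                                   n_passes=n_passes, seed=seed)  # (n, P, C)
    n_trees, C = tree_probs.shape[1], tree_probs.shape[2]
    n_passes_ = pass_probs.shape[1]
    rad = np.repeat(tree_probs[:, None, :, :], n_passes_, axis=1)
    dl = np.repeat(pass_probs[:, :, None, :], n_trees, axis=2)
    fused = fuse_probabilities(rad.reshape(-1, C), dl.reshape(-1, C), params)
    fused = fused.reshape(n, n_passes_ * n_trees, C)

    p_hat = fused.mean(axis=1)
    tot = _entropy(p_hat, epsilon)
    ale = _entropy(fused, epsilon).mean(axis=1)
    epi = np.maximum(tot - ale, 0.0)
    logC = np.log(C)
    frame = pd.DataFrame({
        "case_id": case_ids if case_ids is not None else [f"case_{i:04d}" for i in range(n)],
        "pred_class": p_hat.argmax(axis=1),
        "p_high": p_hat[:, 1],
        "total": tot, "aleatoric": ale, "epistemic": epi,
        "total_norm": tot / logC, "aleatoric_norm": ale / logC,
        "epistemic_norm": epi / logC,
    })
    return frame
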