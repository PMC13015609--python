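"""Synthetic IPMN cohorts, toy lesion volumes, and raw branch outputs.

The real study cohort is 170 histopathologically confirmed IPMNs pooled from
seven centers, stratified into Low-Risk (low-grade dysplasia) and High-Risk
(high-grade dysplasia / invasive carcinoma) groups, with branch-duct (BD) and
main-duct/mixed (MD) subtypes, six anatomical regions, and type-specific size
measurements (maximum cyst diameter for BD, main pancreatic duct diameter for
MD).  This module emulates that cohort structure so every downstream stage —
fusion classifier, uncertainty decomposition, selective prediction, subgroup
statistics, attribution — is testable without any image download.

Two kinds of fixtures live here:

* stochastic generators (:func:`generate_cohort`, :func:`generate_images`,
  :func:`generate_branch_samples`) that are exactly reproducible under a seed;
* :func:`load_count_fixture`, the published per-subgroup totals and
  correct-prediction counts, embedded as plain integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "CaseRecord",
    "CountFixture",
    "REGIONS",
    "REGION_TO_EXTENT",
    "generate_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "generate_images",
    "generate_branch_samples",
    "load_count_fixture",
    "DEFAULT_CENTER_SIZES",
]

REGIONS = ("head", "body", "tail", "head+body", "body+tail", "whole")

#: Extent of pancreatic involvement is a deterministic function of region.
REGION_TO_EXTENT = {
    "head": "single",
    "body": "single",
    "tail": "single",
    "head+body": "two",
    "body+tail": "two",
    "whole": "whole",
}

#: Center sizes summing to 170 and supporting held-out-center trial test sets
#: of sizes 29, 35, 35 and 75 (unions of one or two whole centers).
DEFAULT_CENTER_SIZES = (29, 35, 17, 18, 40, 16, 15)

# Region mixture per risk group (counts from the published cohort tables).
_REGION_COUNTS = {
    "Low-Risk": {"head": 40, "body": 15, "tail": 15, "head+body": 12, "body+tail": 4, "whole": 21},
    "High-Risk": {"head": 12, "body": 3, "tail": 8, "head+body": 6, "body+tail": 8, "whole": 26},
}

# IPMN type mixture per risk group (BD / MD-or-mixed).
_TYPE_COUNTS = {
    "Low-Risk": {"BD": 74, "MD": 33},
    "High-Risk": {"BD": 19, "MD": 44},
}

# Size distributions per (type, risk): lognormal anchored at the published
# medians, with sigma matched to the published interquartile ranges.
_SIZE_MEDIAN = {("BD", "Low-Risk"): 18.2, ("BD", "High-Risk"): 25.1,
                ("MD", "Low-Risk"): 8.6, ("MD", "High-Risk"): 10.3}
_SIZE_IQR = {("BD", "Low-Risk"): (14.0, 29.0), ("BD", "High-Risk"): (15.5, 37.5),
             ("MD", "Low-Risk"): (6.8, 9.9), ("MD", "High-Risk"): (7.9, 14.1)}

# Default per-(risk, type) class-overlap difficulty: High-Risk and MD cases
# are harder, mirroring the accuracy gradient seen on the real cohort.
_DEFAULT_DIFFICULTY = {
    ("Low-Risk", "BD"): 0.45,
    ("Low-Risk", "MD"): 0.55,
    ("High-Risk", "BD"): 0.60,
    ("High-Risk", "MD"): 0.70,
}


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Parameters
    ----------
    n_cases
        Number of lesions. Default 170, the size of the study test cohort.
    n_centers
        Number of contributing centers (default 7).
    n_features
        Length of the per-case radiomic feature vector.
    n_informative
        How many leading features carry class signal ("texture block").
    class_prevalence
        Fraction of High-Risk cases; default 63/170.
    difficulty
        Either a scalar in [0, 1] applied to every case, or a mapping from
        ``(risk, type)`` to a scalar.  0 means perfectly separable classes;
        1 means no class signal at all.
    image_shape
        Voxel dimensions of the toy volumes, or ``None`` when no imaging
        branch is needed.
    seed
        Base RNG seed; two calls with identical config produce identical
        cohorts.
    """

    n_cases: int = 170
    n_centers: int = 7
    n_features: int = 20
    n_informative: int = 5
    class_prevalence: float = 63 / 170
    difficulty: float | Mapping[tuple[str, str], float] | None = None
    region_mixture: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: _REGION_COUNTS)
    type_mixture: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: _TYPE_COUNTS)
    image_shape: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < self.n_centers:
            raise ConfigurationError(
                f"n_cases ({self.n_cases}) must be >= n_centers ({self.n_centers})")
        if not 0.0 < self.class_prevalence < 1.0:
            raise ConfigurationError("class_prevalence must lie strictly in (0, 1)")
        if not 1 <= self.n_informative <= self.n_features:
            raise ConfigurationError("need 1 <= n_informative <= n_features")
        for d in self._difficulty_values():
            if not 0.0 <= d <= 1.0:
                raise ConfigurationError(f"difficulty {d} outside [0, 1]")
        for risk, mix in self.region_mixture.items():
            if set(mix) != set(REGIONS):
                raise ConfigurationError(f"region mixture for {risk} must cover {REGIONS}")
            if any(v < 0 for v in mix.values()) or sum(mix.values()) <= 0:
                raise ConfigurationError("region mixture weights must be non-negative, not all zero")

    def _difficulty_values(self) -> list[float]:
        if self.difficulty is None:
            return list(_DEFAULT_DIFFICULTY.values())
        if isinstance(self.difficulty, Mapping):
            return list(self.difficulty.values())
        return [float(self.difficulty)]

    def difficulty_for(self, risk: str, ipmn_type: str) -> float:
        if self.difficulty is None:
            return _DEFAULT_DIFFICULTY[(risk, ipmn_type)]
        if isinstance(self.difficulty, Mapping):
            return float(self.difficulty[(risk, ipmn_type)])
        return float(self.difficulty)


@dataclass(frozen=True)
class CaseRecord:
    """One synthetic lesion."""

    case_id: str
    center: int
    features: np.ndarray
    label: str          # "Low-Risk" | "High-Risk"
    ipmn_type: str      # "BD" | "MD"
    size_mm: float      # cyst diameter (BD) or MPD diameter (MD)
    region: str
    extent: str

    def __post_init__(self) -> None:
        if self.size_mm <= 0:
            raise ValueError("size_mm must be positive")
        if REGION_TO_EXTENT[self.region] != self.extent:
            raise ValueError(f"extent {self.extent!r} inconsistent with region {self.region!r}")


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    # For lognormal, median = exp(mu) and q3/q1 = exp(2 * 0.6745 * sigma).
    mu = math.log(median)
    sigma = math.log(iqr[1] / iqr[0]) / (2 * 0.674489750196082)
    return mu, sigma


def _allocate(weights: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder integer allocation of ``n`` across ``weights``."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def generate_cohort(config: SyntheticConfig) -> list[CaseRecord]:
    """Draw a reproducible synthetic cohort.

    Class labels follow ``class_prevalence`` with deterministic rounding, so
    the default configuration yields exactly 63 High-Risk of 170 cases.  The
    informative feature block shares a per-case latent: for a case with signed
    label ``s`` (+1 High-Risk) and difficulty ``d``,

        latent = s * (1 - d) + d * z,     z ~ N(0, 1)
        f_i    = latent + 0.3 * d * e_i,  e_i ~ N(0, 1) i.i.d.

    so class separation shrinks — and within-class spread grows — as
    difficulty rises; at d = 0 the informative features are exactly +/-1 and
    the classes are linearly separable.  Remaining features are N(0, 1) noise.
    Sizes are lognormal with medians/IQRs per (type, risk) matching the study
    cohort; regions and types follow the published per-risk mixtures.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    n_high = int(round(config.class_prevalence * n))
    labels = np.array(["Low-Risk"] * (n - n_high) + ["High-Risk"] * n_high)
    rng.shuffle(labels)

    # Centers: exact study-compatible sizes at the default scale, otherwise
    # proportional allocation.
    if n == 170 and config.n_centers == 7:
        center_sizes = np.array(DEFAULT_CENTER_SIZES)
    else:
        center_sizes = _allocate(np.ones(config.n_centers), n)
    centers = np.repeat(np.arange(config.n_centers), center_sizes)
    rng.shuffle(centers)

    records: list[CaseRecord] = []
    for i in range(n):
        label = str(labels[i])
        tmix = config.type_mixture[label]
        types = list(tmix)
        ipmn_type = str(rng.choice(types, p=_normalized([tmix[t] for t in types])))
        rmix = config.region_mixture[label]
        region = str(rng.choice(REGIONS, p=_normalized([rmix[r] for r in REGIONS])))

        mu, sigma = _lognormal_params(_SIZE_MEDIAN[(ipmn_type, label)],
                                      _SIZE_IQR[(ipmn_type, label)])
        size_mm = float(rng.lognormal(mu, sigma))

        d = config.difficulty_for(label, ipmn_type)
        s = 1.0 if label == "High-Risk" else -1.0
        latent = s * (1.0 - d) + d * rng.standard_normal()
        feats = np.empty(config.n_features)
        k = config.n_informative
        feats[:k] = latent + 0.3 * d * rng.standard_normal(k)
        feats[k:] = rng.standard_normal(config.n_features - k)

        records.append(CaseRecord(
            case_id=f"case_{i:04d}",
            center=int(centers[i]),
            features=feats,
            label=label,
            ipmn_type=ipmn_type,
            size_mm=size_mm,
            region=region,
            extent=REGION_TO_EXTENT[region],
        ))
    return records


def _normalized(w: Sequence[float]) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    return w / w.sum()


def cohort_to_frame(cases: Sequence[CaseRecord]) -> pd.DataFrame:
    """Tabulate a cohort: one row per case, features as columns ``f0..f{p-1}``."""
    p = len(cases[0].features)
    rows = []
    for c in cases:
        row = {"case_id": c.case_id, "center": c.center, "label": c.label,
               "ipmn_type": c.ipmn_type, "size_mm": c.size_mm,
               "region": c.region, "extent": c.extent}
        row.update({f"f{j}": c.features[j] for j in range(p)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[CaseRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    fcols = [c for c in frame.columns if c.startswith("f") and c[1:].isdigit()]
    fcols.sort(key=lambda c: int(c[1:]))
    return [CaseRecord(case_id=str(r["case_id"]), center=int(r["center"]),
                       features=np.array([r[c] for c in fcols], dtype=float),
                       label=str(r["label"]), ipmn_type=str(r["ipmn_type"]),
                       size_mm=float(r["size_mm"]), region=str(r["region"]),
                       extent=str(r["extent"]))
            for _, r in frame.iterrows()]


class ImageGenerationError(ValueError):
    pass


def generate_images(cases: Sequence[CaseRecord], config: SyntheticConfig,
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Render one toy (volume, mask) pair per case.

    Each volume contains a single ellipsoidal "cyst" on a smooth background;
    its diameter in voxels tracks ``size_mm``, and the within-lesion texture
    amplitude tracks the label — High-Risk lesions get a noisier, higher
    intensity-entropy interior, the imaging correlate the texture features
    stand in for.  The mask marks the ellipsoid.  Volumes are plain float
    arrays, serializable to NIfTI via :func:`save_images_nifti`.
    """
    if config.image_shape is None:
        raise ImageGenerationError("config.image_shape must be set to generate images")
    shape = tuple(config.image_shape)
    max_size = max(c.size_mm for c in cases)
    # voxels per mm so the largest lesion still fits with a 2-voxel margin
    scale = (min(shape) / 2 - 2) / (max_size / 2)
    if scale <= 0:
        raise ImageGenerationError(f"image_shape {shape} leaves no room for any lesion")
    out = []
    for c in cases:
        rng = np.random.default_rng((config.seed, 7, hash(c.case_id) & 0x7FFFFFFF))
        radius = c.size_mm / 2 * scale
        if radius < 1.5:      # floor keeps the smallest lesions non-empty
            radius = 1.5
        if 2 * radius + 2 > min(shape):
            raise ImageGenerationError(
                f"image_shape {shape} too small for lesion of {c.size_mm:.1f} mm")
        grid = np.indices(shape).astype(float)
        center = np.array([(s - 1) / 2 for s in shape])
        # mildly anisotropic ellipsoid
        axes = radius * np.array([1.0, 0.85, 0.7])
        dist = sum(((grid[k] - center[k]) / axes[k]) ** 2 for k in range(3))
        mask = dist <= 1.0

        vol = 0.15 + 0.05 * grid[0] / shape[0] + 0.01 * rng.standard_normal(shape)
        d = config.difficulty_for(c.label, c.ipmn_type)
        # interior model: narrow fluid signal plus a heterogeneous component
        # (solid/mucinous voxels drawn uniformly over the intensity range);
        # High-Risk lesions carry a larger heterogeneous fraction, hence a
        # strictly higher within-mask intensity-histogram entropy.  The class
        # contrast shrinks as difficulty rises.
        hetero_0 = 0.6 if c.label == "High-Risk" else 0.1
        frac = (1.0 - d) * hetero_0 + d * 0.35
        n_in = int(mask.sum())
        interior = 0.7 + 0.05 * rng.standard_normal(n_in)
        solid = rng.random(n_in) < frac
        interior[solid] = rng.uniform(0.2, 1.2, int(solid.sum()))
        vol[mask] = interior
        out.append((vol.astype(np.float32), mask.astype(np.uint8)))
    return out


def save_images_nifti(images: Sequence[tuple[np.ndarray, np.ndarray]],
                      cases: Sequence[CaseRecord], out_dir: str | Path) -> None:
    """Write ``<case_id>_vol.nii.gz`` / ``<case_id>_mask.nii.gz`` pairs."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for (vol, mask), case in zip(images, cases):
        nib.save(nib.Nifti1Image(vol, affine), out_dir / f"{case.case_id}_vol.nii.gz")
        nib.save(nib.Nifti1Image(mask, affine), out_dir / f"{case.case_id}_mask.nii.gz")


def generate_branch_samples(n_cases: int, n_trees: int, n_passes: int,
                            sharpness: float = 10.0, seed: int = 0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Raw two-branch outputs with controllable dispersion, no training needed.

    For each case a latent High-Risk probability ``q ~ Beta(2, 2)`` is drawn;
    per-tree and per-pass probabilities are then Beta(sharpness*q,
    sharpness*(1-q)) draws around it.  As ``sharpness`` grows the samples
    concentrate on ``q`` and downstream epistemic uncertainty tends to zero.

    Returns
    -------
    tree_probs : (n_cases, n_trees, 2) array
    pass_probs : (n_cases, n_passes, 2) array
    """
    if n_trees < 1 or n_passes < 1:
        raise ValueError("n_trees and n_passes must be >= 1")
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    rng = np.random.default_rng(seed)
    q = rng.beta(2.0, 2.0, size=n_cases)

    def draw(m: int) -> np.ndarray:
        a = np.clip(sharpness * q, 1e-6, None)
        b = np.clip(sharpness * (1.0 - q), 1e-6, None)
        p1 = rng.beta(a[:, None], b[:, None], size=(n_cases, m))
        return np.stack([1.0 - p1, p1], axis=-1)

    return draw(n_trees), draw(n_passes)


# ---------------------------------------------------------------------------
# Published count fixture
# ---------------------------------------------------------------------------

# (total, correct) per category.  Correct counts not printed verbatim are the
# unique integer consistent with the printed accuracy percentage and total.
_FIXTURE = {
    "risk": {"Low-Risk": (107, 87), "High-Risk": (63, 27)},
    "type": {"BD": (93, 66), "MD": (77, 48)},
    "region": {"head": (52, 36), "body": (18, 14), "tail": (23, 11),
               "head+body": (18, 12), "body+tail": (12, 5), "whole": (47, 36)},
    "extent": {"single": (93, 61), "two": (30, 17), "whole": (47, 36)},
}


@dataclass(frozen=True)
class CountFixture:
    """Per-subgroup totals and correct-prediction counts of the study cohort.

    170 cases, 114 of them correctly classified by the fusion model (67.1%
    overall accuracy); every categorization dimension partitions both numbers.
    """

    dimensions: Mapping[str, Mapping[str, tuple[int, int]]]

    @property
    def n_total(self) -> int:
        return sum(t for t, _ in self.dimensions["risk"].values())

    @property
    def n_correct(self) -> int:
        return sum(c for _, c in self.dimensions["risk"].values())

    def table(self, dimension: str) -> tuple[list[str], np.ndarray]:
        """Return (category labels, r×2 array of [correct, incorrect] counts)."""
        d = self.dimensions[dimension]
        labels = list(d)
        arr = np.array([[d[k][1], d[k][0] - d[k][1]] for k in labels], dtype=int)
        return labels, arr

    def accuracy(self, dimension: str, category: str) -> float:
        total, correct = self.dimensions[dimension][category]
        return correct / total


def load_count_fixture() -> CountFixture:
    """The embedded study contingency counts, self-validated on load."""
    fx = CountFixture(dimensions=_FIXTURE)
    for dim, cats in fx.dimensions.items():
        totals = sum(t for t, _ in cats.values())
        corrects = sum(c for _, c in cats.values())
        if totals != 170 or corrects != 114:
            raise AssertionError(f"fixture dimension {dim} inconsistent: {totals}/{corrects}")
        if any(c > t for t, c in cats.values()):
            raise AssertionError(f"fixture dimension {dim} has correct > total")
    return fx
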