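"""Keypoint-based egg pattern matching and the best-match graph.

This is the pattern-matching core: every egg is reduced to a set of local
descriptors of its maculation, eggs are compared by a symmetric dissimilarity,
and each egg is ranked against every other egg in a pool (a "batch": one
year, one region over all years, or everything).  The rank-1 neighbour is the
egg's *best match*; the proportion of best matches that fall within the
correct clutch is the headline signal statistic.

Descriptor design.  Keypoints and 128-d gradient-histogram descriptors come
from scale-space difference-of-Gaussians (SIFT, scikit-image).  Plain SIFT
descriptors are deliberately invariant to contrast and scale - which would
erase precisely the hen-specific cues a maternal signature lives in (spot
size, spot darkness, shell ground tone, pole-ward concentration, egg shape).
Each descriptor is therefore augmented with weighted appearance columns:

* log2 spot scale in mm (physical spot size),
* axial position of the keypoint along the egg's long axis,
* local tone at the keypoint and the egg's ground tone,
* per-egg summary columns (mean axial position, log2 feature count,
  median log2 scale, egg aspect ratio).

Dissimilarity between two eggs is the modified-Hausdorff distance between
their augmented descriptor sets: the mean nearest-neighbour distance in each
direction, symmetrised by the maximum.  It is zero for identical feature
sets, symmetric, and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.feature import SIFT
from skimage.transform import resize

from .imageprep import EggImage, EggMask, orient_canonical

__all__ = [
    "FeatureConfig",
    "FeatureSet",
    "MatchGraph",
    "MAX_DISSIMILARITY",
    "extract_features",
    "egg_dissimilarity",
    "build_match_graph",
    "within_clutch_match_rate",
    "feature_table",
]

#: score assigned when one or both eggs have no usable features
MAX_DISSIMILARITY = 10.0


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction and matching parameters.

    ``normalize_long_axis_px`` optionally resamples every egg so its long
    axis spans a fixed number of pixels before detection.  It is off by
    default: keypoint scales are expressed in millimetres, which already
    makes eggs photographed at different scales comparable, and resampling
    same-scale images only injects interpolation noise between eggs of the
    same hen.  ``descriptor_cap`` keeps the largest-scale features, which
    carry the major pigment marks.
    The ``w_*`` weights set how strongly each appearance column counts
    against one unit of SIFT descriptor distance (descriptors are
    unit-normalised, so distances lie in [0, 2]).
    """

    normalize_long_axis_px: int | None = None
    canonical_orientation: bool = True
    descriptor_cap: int = 200
    w_scale: float = 2.0
    w_axial: float = 0.5
    w_tone: float = 4.0
    w_ground: float = 4.0
    w_mean_axial: float = 1.0
    w_n_features: float = 0.5
    w_median_scale: float = 1.0
    w_aspect: float = 5.0


@dataclass
class FeatureSet:
    """Per-egg keypoints plus the three scalar pattern variables.

    ``largest_scale_mm`` and ``dominant_orientation_deg`` are the scale and
    orientation of the single largest feature; both are None when no feature
    was detected.
    """

    egg_id: str
    keypoints: pd.DataFrame  # row, col, scale_mm, orientation_deg
    descriptors: np.ndarray  # (n, d) augmented matrix used for matching
    n_features: int
    largest_scale_mm: float | None
    dominant_orientation_deg: float | None

    def __post_init__(self) -> None:
        if self.n_features != len(self.keypoints):
            raise ValueError("n_features must equal the keypoint count")
        if self.dominant_orientation_deg is not None and not (
                0.0 <= self.dominant_orientation_deg < 360.0):
            raise ValueError("orientation must lie in [0, 360)")

    @property
    def empty(self) -> bool:
        return self.n_features == 0


def _empty_featureset(egg_id: str) -> FeatureSet:
    return FeatureSet(
        egg_id=egg_id,
        keypoints=pd.DataFrame(columns=["row", "col", "scale_mm", "orientation_deg"]),
        descriptors=np.empty((0, 128)),
        n_features=0, largest_scale_mm=None, dominant_orientation_deg=None)


def extract_features(img: EggImage, mask: EggMask,
                     config: FeatureConfig | None = None) -> FeatureSet:
    """Detect maculation keypoints inside the egg mask and build descriptors.

    Deterministic for fixed input.  An unpigmented egg yields an empty
    FeatureSet (not an error); such eggs are excluded from match graphs.
    """
    config = config or FeatureConfig()
    if config.canonical_orientation:
        img, mask = orient_canonical(img, mask)
    gray = img.pixels if img.is_gray else None
    if gray is None:
        from .imageprep import to_grayscale
        gray = to_grayscale(img).pixels
    m = mask.mask
    mm_per_px = img.mm_per_px

    rows_any = np.where(m.any(axis=1))[0]
    cols_any = np.where(m.any(axis=0))[0]
    long_px = rows_any[-1] - rows_any[0] + 1
    if config.normalize_long_axis_px and long_px != config.normalize_long_axis_px:
        factor = config.normalize_long_axis_px / long_px
        new_shape = (max(int(round(gray.shape[0] * factor)), 8),
                     max(int(round(gray.shape[1] * factor)), 8))
        gray = np.clip(np.round(resize(gray.astype(float), new_shape,
                                       preserve_range=True, anti_aliasing=True)),
                       0, 255).astype(np.uint8)
        m = resize(m.astype(float), new_shape, preserve_range=True) > 0.5
        mm_per_px = mm_per_px / factor
        rows_any = np.where(m.any(axis=1))[0]
        cols_any = np.where(m.any(axis=0))[0]

    egg_id = img.egg_id or "egg"
    sift = SIFT()
    try:
        sift.detect_and_extract(gray)
    except RuntimeError:  # no keypoints at all
        return _empty_featureset(egg_id)

    kp = sift.keypoints
    scale_px = sift.sigmas  # absolute detection scale (sigma ~ 0.64 x blob radius)
    orient = np.degrees(sift.orientations) % 360.0
    desc = sift.descriptors
    # keypoints must sit clearly inside the shell: the rim itself produces
    # edge responses that are not maculation
    interior = ndimage.binary_erosion(m, iterations=3)
    inside = interior[kp[:, 0], kp[:, 1]]
    kp, scale_px, orient, desc = kp[inside], scale_px[inside], orient[inside], desc[inside]
    if len(kp) == 0:
        return _empty_featureset(egg_id)

    scale_mm = scale_px * mm_per_px
    length_px = max(rows_any[-1] - rows_any[0], 1)
    axial_all = (kp[:, 0] - rows_any[0]) / length_px
    n_all = len(kp)
    mean_axial = float(axial_all.mean())
    median_log_scale = float(np.median(np.log2(scale_mm + 1e-9)))
    aspect = (cols_any[-1] - cols_any[0] + 1) / (rows_any[-1] - rows_any[0] + 1)

    if n_all > config.descriptor_cap:
        keep = np.argsort(-scale_px, kind="stable")[: config.descriptor_cap]
        kp, scale_px, orient, desc = kp[keep], scale_px[keep], orient[keep], desc[keep]
        scale_mm = scale_mm[keep]

    local_tone = ndimage.uniform_filter(gray.astype(float), 5)[kp[:, 0], kp[:, 1]]
    ground_tone = float(np.median(gray[m]))
    axial = (kp[:, 0] - rows_any[0]) / length_px
    unit = desc / np.maximum(np.linalg.norm(desc, axis=1, keepdims=True), 1e-9)
    k = len(kp)
    augmented = np.column_stack([
        unit,
        config.w_scale * np.log2(scale_mm + 1e-9),
        config.w_axial * axial,
        config.w_tone * local_tone / 255.0,
        np.full(k, config.w_ground * ground_tone / 255.0),
        np.full(k, config.w_mean_axial * mean_axial),
        np.full(k, config.w_n_features * np.log2(n_all)),
        np.full(k, config.w_median_scale * median_log_scale),
        np.full(k, config.w_aspect * aspect),
    ])

    largest = int(np.argmax(scale_mm))
    keypoints = pd.DataFrame({
        "row": kp[:, 0], "col": kp[:, 1],
        "scale_mm": scale_mm, "orientation_deg": orient})
    return FeatureSet(
        egg_id=egg_id, keypoints=keypoints, descriptors=augmented,
        n_features=k,
        largest_scale_mm=float(scale_mm[largest]),
        dominant_orientation_deg=float(orient[largest]))


def egg_dissimilarity(a: FeatureSet, b: FeatureSet) -> float:
    """Symmetric non-negative pattern distance between two eggs.

    Modified-Hausdorff form: ``max`` over both directions of the mean
    nearest-neighbour distance between augmented descriptors.  Identical
    feature sets score 0; if either set is empty the defined maximal score is
    returned.
    """
    if a.empty or b.empty:
        return MAX_DISSIMILARITY
    dists = cdist(a.descriptors, b.descriptors)
    return float(max(dists.min(axis=1).mean(), dists.min(axis=0).mean()))


@dataclass
class MatchGraph:
    """Full ranked match lists for one batch of eggs.

    ``ranked[egg]`` lists every other egg in the pool by ascending
    dissimilarity (ties broken by egg id); ``best_match[egg]`` is rank 1.
    Eggs without features are recorded in ``excluded`` and appear nowhere.
    """

    batch_label: str
    egg_ids: list[str]
    dissimilarity: pd.DataFrame  # square, symmetric, zero diagonal
    ranked: dict[str, list[tuple[str, float]]]
    excluded: list[str] = field(default_factory=list)

    @property
    def best_match(self) -> dict[str, str]:
        return {e: lst[0][0] for e, lst in self.ranked.items() if lst}

    def top_k(self, egg_id: str, k: int) -> list[str]:
        lst = self.ranked[egg_id]
        if k > len(lst):
            raise ValueError(f"k={k} exceeds pool size - 1 = {len(lst)}")
        return [other for other, _ in lst[:k]]


def build_match_graph(pool: list[FeatureSet], batch_label: str = "all") -> MatchGraph:
    """Compute all pairwise dissimilarities and rank every egg's matches."""
    usable = [f for f in pool if not f.empty]
    excluded = [f.egg_id for f in pool if f.empty]
    if len(usable) < 2:
        raise ValueError("a match graph needs at least 2 eggs with features")
    ids = [f.egg_id for f in usable]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate egg ids in pool")
    n = len(usable)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = egg_dissimilarity(usable[i], usable[j])
    frame = pd.DataFrame(mat, index=ids, columns=ids)
    ranked: dict[str, list[tuple[str, float]]] = {}
    for i, egg in enumerate(ids):
        others = [(ids[j], float(mat[i, j])) for j in range(n) if j != i]
        others.sort(key=lambda t: (t[1], t[0]))
        ranked[egg] = others
    return MatchGraph(batch_label=batch_label, egg_ids=ids,
                      dissimilarity=frame, ranked=ranked, excluded=excluded)


def within_clutch_match_rate(graph: MatchGraph, clutch_of: dict[str, str]) -> float:
    """Fraction of eggs whose best match lies in their own clutch."""
    best = graph.best_match
    if not best:
        return float("nan")
    hits = sum(1 for egg, match in best.items()
               if clutch_of[egg] == clutch_of[match])
    return hits / len(best)


def feature_table(feature_sets: list[FeatureSet]) -> pd.DataFrame:
    """The three per-egg scalar pattern variables as a tidy table."""
    return pd.DataFrame(
        [{"egg_id": f.egg_id, "n_features": f.n_features,
          "largest_scale_mm": f.largest_scale_mm,
          "dominant_orientation_deg": f.dominant_orientation_deg}
         for f in feature_sets])
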