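"""Grey-level co-occurrence texture features, intensity statistics and
morphology for kidney-parenchyma ROIs.

Texture is computed in-plane (distance 1, the four 2D Chebyshev directions)
from symmetric co-occurrence matrices, under the four standard aggregation
schemes:

``2d_avg``
    one matrix per (slice, direction); the feature is averaged over all of
    them. Reported with prefix ``F_cm``.
``2d_merged``
    the four directional matrices of a slice are summed before the feature
    is computed; the per-slice values are averaged. Prefix ``F_cm_merged``.
``25d_avg``
    matrices are summed over slices per direction; the four directional
    values are averaged. Prefix ``F_cm_25d``.
``25d_merged``
    every matrix is summed into one; a single value. Prefix
    ``F_cm_25d_merged``.

Grey levels default to undiscretized rounded HU re-indexed to ``1..Ng``
(so Ng is data dependent); fixed bin size or fixed bin count discretization
is available and recommended when robustness across scanners matters.

Intensity features use population moments; cohort z-scoring uses the sample
(n-1) standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import ROI, SegmentationMask

__all__ = [
    "GreyLevelImage",
    "CooccurrenceMatrix",
    "DIRECTIONS_2D",
    "AGGREGATION_MODES",
    "GLCM_FEATURES",
    "discretize_levels",
    "build_cooccurrence",
    "glcm_correlation",
    "glcm_cluster_tendency",
    "glcm_feature_suite",
    "aggregate_texture",
    "intensity_features",
    "morphology_features",
    "extract_all_features",
    "zscore_table",
]

#: in-plane unit offsets (row, col): 0, 45, 90, 135 degrees
DIRECTIONS_2D: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))

AGGREGATION_MODES = ("2d_avg", "2d_merged", "25d_avg", "25d_merged")

_MODE_PREFIX = {
    "2d_avg": "F_cm",
    "2d_merged": "F_cm_merged",
    "25d_avg": "F_cm_25d",
    "25d_merged": "F_cm_25d_merged",
}

GLCM_FEATURES = (
    "joint.max",
    "joint.avg",
    "joint.var",
    "joint.entr",
    "asm",
    "contrast",
    "dissimilarity",
    "inv.diff",
    "corr",
    "clust.tend",
)


@dataclass
class GreyLevelImage:
    """ROI voxels quantized to integer levels 1..ng on a dense 3D grid.

    ``levels`` covers the ROI bounding box; 0 marks voxels outside the ROI.
    """

    levels: np.ndarray  # int array, 0 = outside ROI
    ng: int
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        inroi = self.levels[self.levels > 0]
        if inroi.size == 0:
            raise ValueError("grey-level image has no ROI voxels")
        if self.ng < 1 or inroi.max() > self.ng:
            raise ValueError("levels must lie in 1..ng")


@dataclass
class CooccurrenceMatrix:
    """Pair counts (or probabilities) of grey levels at a fixed offset."""

    matrix: np.ndarray  # ng x ng
    distance: int
    direction: tuple[int, int] | None  # None once directions are merged
    symmetric: bool
    normalized: bool

    @property
    def empty(self) -> bool:
        return float(self.matrix.sum()) == 0.0

    def normalize(self) -> "CooccurrenceMatrix":
        total = float(self.matrix.sum())
        if total == 0.0:
            raise ValueError("cannot normalize an empty co-occurrence matrix")
        return CooccurrenceMatrix(
            matrix=self.matrix / total,
            distance=self.distance,
            direction=self.direction,
            symmetric=self.symmetric,
            normalized=True,
        )


def discretize_levels(roi: ROI, method: str = "none", param: float | int | None = None) -> GreyLevelImage:
    """Map ROI HU values to integer grey levels on the ROI bounding box.

    method "none"
        levels = round(HU) - min(round(HU)) + 1 (no true discretization,
        matching feature extraction straight from HU).
    method "fixed_bin_size"
        level = floor((HU - min) / w) + 1 with bin width ``param`` (HU).
    method "fixed_bin_count"
        ``param`` equal-width bins over [min, max]; max maps to Ng.
    """
    values = roi.values
    if method == "none":
        r = np.rint(values).astype(np.int64)
        lev = r - r.min() + 1
    elif method == "fixed_bin_size":
        if param is None or param <= 0:
            raise ValueError("fixed_bin_size requires a positive bin width")
        lev = np.floor((values - values.min()) / float(param)).astype(np.int64) + 1
    elif method == "fixed_bin_count":
        if param is None or int(param) < 1:
            raise ValueError("fixed_bin_count requires a positive bin count")
        ng = int(param)
        lo, hi = values.min(), values.max()
        if hi == lo:
            lev = np.ones(len(values), dtype=np.int64)
        else:
            lev = np.floor((values - lo) / (hi - lo) * ng).astype(np.int64) + 1
            lev[lev > ng] = ng
    else:
        raise ValueError(f"unknown discretization method {method!r}")

    origin = roi.coordinates.min(axis=0)
    shape = roi.coordinates.max(axis=0) - origin + 1
    grid = np.zeros(tuple(shape), dtype=np.int64)
    rel = roi.coordinates - origin
    grid[rel[:, 0], rel[:, 1], rel[:, 2]] = lev
    return GreyLevelImage(levels=grid, ng=int(lev.max()), spacing=roi.spacing)


def _pair_counts(plane: np.ndarray, ng: int, direction: tuple[int, int], d: int) -> np.ndarray:
    """Counts of ordered level pairs at offset d*direction within one slice.

    Only pairs with both voxels inside the ROI (level > 0) contribute.
    Returns the forward-orientation count matrix.
    """
    dr, dc = direction[0] * d, direction[1] * d
    nr, nc = plane.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        return np.zeros((ng, ng), dtype=np.int64)
    a = plane[r0:r1, c0:c1]
    b = plane[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return np.zeros((ng, ng), dtype=np.int64)
    idx = (a[valid] - 1) * ng + (b[valid] - 1)
    return np.bincount(idx, minlength=ng * ng).reshape(ng, ng)


def build_cooccurrence(
    img: GreyLevelImage,
    slice_index: int,
    direction: tuple[int, int],
    d: int = 1,
    symmetric: bool = True,
) -> CooccurrenceMatrix:
    """Co-occurrence count matrix for one slice and one in-plane direction.

    With ``symmetric`` every forward pair is also counted in the reverse
    orientation, so the matrix equals its transpose. A slice with no valid
    pair in the direction yields an empty matrix (flagged, excluded from
    aggregation).
    """
    if tuple(direction) not in DIRECTIONS_2D and tuple(-np.asarray(direction)) not in DIRECTIONS_2D:
        raise ValueError(f"direction {direction} is not an in-plane unit offset")
    counts = _pair_counts(img.levels[slice_index], img.ng, tuple(direction), d)
    if symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(
        matrix=counts.astype(float),
        distance=d,
        direction=tuple(direction),
        symmetric=symmetric,
        normalized=False,
    )


def _require_normalized(P: CooccurrenceMatrix) -> np.ndarray:
    if not P.normalized:
        raise ValueError("feature requires a normalized co-occurrence matrix")
    m = P.matrix
    if abs(float(m.sum()) - 1.0) > 1e-9:
        raise ValueError("probabilities do not sum to 1")
    return m


def glcm_correlation(P: CooccurrenceMatrix) -> float:
    """Normalized covariance of co-occurring grey levels, in [-1, 1].

    High when neighbouring intensities fluctuate jointly, as in
    heterogeneous tissue with coherent structures. A degenerate matrix
    (zero marginal variance, e.g. a flat region) returns 1: a perfectly
    uniform region is maximally self-correlated.
    """
    m = _require_normalized(P)
    ng = m.shape[0]
    i = np.arange(1, ng + 1)
    pi = m.sum(axis=1)
    mu = float(i @ pi)
    var = float(((i - mu) ** 2) @ pi)
    if var <= 0.0:
        return 1.0
    cov = float(((i - mu)[:, None] * (i - mu)[None, :] * m).sum())
    return float(np.clip(cov / var, -1.0, 1.0))


def glcm_cluster_tendency(P: CooccurrenceMatrix) -> float:
    """Sum of (i + j - 2*mu)^2 p(i,j); groupiness of similar grey levels."""
    m = _require_normalized(P)
    ng = m.shape[0]
    i = np.arange(1, ng + 1)
    mu = float(i @ m.sum(axis=1))
    s = i[:, None] + i[None, :] - 2.0 * mu
    return float((s * s * m).sum())


def glcm_feature_suite(P: CooccurrenceMatrix) -> dict[str, float]:
    """The implemented co-occurrence feature set from one normalized matrix."""
    m = _require_normalized(P)
    ng = m.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[:, None]
    jj = i[None, :]
    absdiff = np.abs(ii - jj)
    nz = m > 0
    out = {
        "joint.max": float(m.max()),
        "joint.avg": float((ii * m).sum()),
        "joint.entr": float(-(m[nz] * np.log2(m[nz])).sum()),
        "asm": float((m * m).sum()),
        "contrast": float((absdiff**2 * m).sum()),
        "dissimilarity": float((absdiff * m).sum()),
        "inv.diff": float((m / (1.0 + absdiff)).sum()),
        "corr": glcm_correlation(P),
        "clust.tend": glcm_cluster_tendency(P),
    }
    out["joint.var"] = float(((ii - out["joint.avg"]) ** 2 * m).sum())
    return {k: out[k] for k in GLCM_FEATURES}


def _all_count_matrices(img: GreyLevelImage, d: int) -> dict[tuple[int, int], np.ndarray]:
    """Symmetric count matrices keyed by (slice index, direction index)."""
    mats = {}
    for s in range(img.levels.shape[0]):
        plane = img.levels[s]
        if not (plane > 0).any():
            continue
        for k, direction in enumerate(DIRECTIONS_2D):
            c = _pair_counts(plane, img.ng, direction, d)
            c = c + c.T
            if c.sum() > 0:
                mats[(s, k)] = c
    return mats


def _suite_from_counts(counts: np.ndarray, d: int) -> dict[str, float]:
    cm = CooccurrenceMatrix(counts.astype(float), d, None, True, False).normalize()
    return glcm_feature_suite(cm)


def aggregate_texture(
    img: GreyLevelImage,
    features: tuple[str, ...] = GLCM_FEATURES,
    mode: str = "2d_avg",
    d: int = 1,
) -> dict[str, float]:
    """Co-occurrence features under one aggregation scheme.

    Returns ``{feature_name: value}`` without the mode prefix. Empty
    matrices are excluded from merges and averages; if every matrix is
    empty each feature is NaN (recorded as missing upstream).
    """
    if mode not in AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    mats = _all_count_matrices(img, d)
    if not mats:
        return {f: float("nan") for f in features}

    if mode == "2d_avg":
        suites = [_suite_from_counts(c, d) for c in mats.values()]
    elif mode == "2d_merged":
        slices = sorted({s for s, _ in mats})
        suites = []
        for s in slices:
            merged = sum(c for (si, _), c in mats.items() if si == s)
            suites.append(_suite_from_counts(merged, d))
    elif mode == "25d_avg":
        dirs = sorted({k for _, k in mats})
        suites = []
        for k in dirs:
            merged = sum(c for (_, ki), c in mats.items() if ki == k)
            suites.append(_suite_from_counts(merged, d))
    else:  # 25d_merged
        merged = sum(mats.values())
        suites = [_suite_from_counts(merged, d)]

    return {f: float(np.mean([s[f] for s in suites])) for f in features}


def intensity_features(roi: ROI) -> dict[str, float]:
    """Global first-order statistics of the ROI grey-level histogram."""
    x = np.asarray(roi.values, dtype=float)
    if x.size == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)
    centered = x - mean
    skew = float((centered**3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float((centered**4).mean() / sd**4 - 3.0) if sd > 0 else 0.0
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return {
        "F_stat.mean": mean,
        "F_stat.var": var,
        "F_stat.skew": skew,
        "F_stat.kurt": kurt,
        "F_stat.median": float(p50),
        "F_stat.min": float(x.min()),
        "F_stat.max": float(x.max()),
        "F_stat.p10": float(p10),
        "F_stat.p90": float(p90),
        "F_stat.iqr": float(p75 - p25),
        "F_stat.range": float(x.max() - x.min()),
        "F_stat.mad": float(np.abs(centered).mean()),
        "F_stat.energy": float((x**2).sum()),
        "F_stat.rms": float(np.sqrt((x**2).mean())),
    }


def morphology_features(
    mask: SegmentationMask, spacing: tuple[float, float, float] | None = None
) -> dict[str, float]:
    """Geometric descriptors of the mask: volume, surface area, sphericity,
    centroid and principal-axis elongation/flatness.

    Surface area counts exposed voxel faces (a foreground face not shared
    with another foreground voxel contributes its physical face area).
    """
    if mask.empty:
        raise ValueError("empty mask has no morphology")
    sp = tuple(spacing) if spacing is not None else mask.spacing
    lab = mask.labels
    voxel_volume = sp[0] * sp[1] * sp[2]
    n = mask.n_foreground
    volume = n * voxel_volume

    face_areas = (sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1])
    area = 0.0
    padded = np.pad(lab, 1)
    for axis, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += float(np.abs(diff).sum()) * fa

    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area

    coords = np.argwhere(lab).astype(float) * np.asarray(sp)
    centroid = coords.mean(axis=0)
    if n > 1:
        cov = np.cov(coords, rowvar=False, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        elongation = flatness = 1.0

    return {
        "F_morph.vol": float(volume),
        "F_morph.area": float(area),
        "F_morph.sphericity": float(sphericity),
        "F_morph.elongation": elongation,
        "F_morph.flatness": flatness,
        "F_morph.centroid.z": float(centroid[0]),
        "F_morph.centroid.y": float(centroid[1]),
        "F_morph.centroid.x": float(centroid[2]),
    }


#: centroid coordinates are excluded from cohort feature tables
#: (translation-variant, carries no tissue information)
_TABLE_EXCLUDE = ("F_morph.centroid.z", "F_morph.centroid.y", "F_morph.centroid.x")


def extract_all_features(
    roi: ROI,
    mask: SegmentationMask | None = None,
    discretization: str = "none",
    disc_param: float | None = None,
    modes: tuple[str, ...] = AGGREGATION_MODES,
    d: int = 1,
) -> dict[str, float]:
    """All named features of one patient ROI: co-occurrence texture under
    the requested aggregation modes, intensity statistics and (when the
    mask is given) morphology."""
    img = discretize_levels(roi, discretization, disc_param)
    out: dict[str, float] = {}
    for mode in modes:
        prefix = _MODE_PREFIX[mode]
        vals = aggregate_texture(img, GLCM_FEATURES, mode, d)
        out.update({f"{prefix}.{name}": v for name, v in vals.items()})
    out.update(intensity_features(roi))
    if mask is not None:
        morph = morphology_features(mask)
        out.update({k: v for k, v in morph.items() if k not in _TABLE_EXCLUDE})
    return out


def zscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column across patients (sample SD, n-1).

    Constant columns are dropped with a warning; an all-constant table is
    an error.
    """
    if len(table) < 2:
        raise ValueError("z-scoring requires at least two patients")
    num = table.select_dtypes(include=[np.number])
    sd = num.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if len(constant) == len(num.columns):
        raise ValueError("all feature columns are constant")
    if constant:
        warnings.warn(f"dropping constant feature columns: {constant}", stacklevel=2)
    keep = [c for c in num.columns if c not in constant]
    return (num[keep] - num[keep].mean()) / sd[keep]
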