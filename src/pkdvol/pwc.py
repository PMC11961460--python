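"""Automated total-cyst-volume segmentation by progressive weighted curve.

Cysts are segmented from the gray-level distribution inside the
radiologist-delineated kidneys. The progressive weighted curve (PWC) over
the kidney histogram is

    PWC(k) = sum_{i=0..k} w_i x_i / sum_{i=0..k} w_i ,

the count-weighted mean of the gray values up to level ``k`` (``w_i`` =
histogram count of level ``i``, ``x_i`` the gray value). Its inflection
points are the candidate segmentation thresholds. Each candidate is scored
from the connected objects it produces — slice-wise circularity, internal
intensity SD and mean border gradient — and the best-scoring threshold
yields the cyst mask; total cyst volume (TCV) is the mask volume.

On T2-weighted sequences cyst fluid is hyperintense, so by default cysts
are voxels *above* the chosen threshold (``polarity="bright"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import perimeter as _skperimeter
from skimage.filters import threshold_otsu

from .volume import IntensityVolume, voxel_volume_ml

__all__ = [
    "GrayHistogram",
    "PWCCurve",
    "ObjectFeatures",
    "CandidateThreshold",
    "SegmentationConfig",
    "SegmentationResult",
    "build_histogram",
    "compute_pwc",
    "find_candidate_thresholds",
    "apply_threshold",
    "object_features",
    "score_thresholds",
    "segment_cysts",
    "compute_tcv",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity in 3-D


@dataclass
class GrayHistogram:
    """Histogram of masked gray values over equal-width bins.

    ``counts[i]`` (= w_i) is the number of masked voxels in bin ``i`` and
    ``levels[i]`` (= x_i) the bin-centre gray value.
    """

    counts: np.ndarray
    levels: np.ndarray
    bin_edges: np.ndarray
    constant_image: bool = False

    def __post_init__(self):
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def n_voxels(self) -> int:
        return int(self.counts.sum())


@dataclass
class PWCCurve:
    """Progressive weighted curve PWC(k) sampled at the histogram levels."""

    values: np.ndarray
    levels: np.ndarray
    #: first k with a nonzero cumulative count
    defined_from: int = 0


@dataclass
class ObjectFeatures:
    """Shape/intensity features of one thresholded object."""

    circularity: float
    internal_sd: float
    border_gradient: float
    n_voxels: int
    mean_intensity: float


@dataclass
class CandidateThreshold:
    """One candidate gray level with its object features and quality score."""

    level: float
    level_index: int
    score: float = float("nan")
    objects: list[ObjectFeatures] = field(default_factory=list)
    rejected: str | None = None  # reason, if the contrast gate excluded it


@dataclass
class SegmentationConfig:
    """Tunable parameters of the PWC segmentation.

    ``min_cnr`` is a Rose-criterion contrast gate: a candidate threshold is
    only admissible if its objects are at least ``min_cnr`` noise SDs
    brighter than the remaining kidney tissue; this is what rejects
    thresholds that merely split the parenchyma noise in cyst-free kidneys.
    """

    bins: int = 256
    polarity: str = "bright"  # cysts above ("bright") or below ("dark") threshold
    smoothing_sigma: float = 1.0  # in bins, applied to the PWC before differencing
    min_object_voxels: int = 5
    score_weights: tuple[float, float, float] = (1.0, 2.0, 1.0)  # circ, gradient, low-SD
    min_cnr: float = 3.0
    #: cysts never occupy the whole organ; a candidate must leave at least
    #: this fraction of the kidney as non-cyst tissue
    min_background_fraction: float = 0.10
    inflection_tol: float = 1e-6  # x curve range

    def __post_init__(self):
        if self.bins < 2:
            raise ValueError("need at least 2 gray-level bins")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")
        if any(w < 0 for w in self.score_weights) or not any(self.score_weights):
            raise ValueError("score weights must be non-negative and not all zero")


@dataclass
class SegmentationResult:
    cyst_mask: np.ndarray
    chosen_level: float | None
    chosen_index: int | None
    candidates: list[CandidateThreshold]
    tcv_ml: float
    used_fallback: bool = False
    no_valid_candidate: bool = False


def build_histogram(volume: IntensityVolume, mask, n_levels: int = 256) -> GrayHistogram:
    """Histogram of masked intensities over ``n_levels`` equal-width bins.

    Bins span the masked intensity range, so the binning (and everything
    downstream) is invariant under affine intensity rescaling. A constant
    image yields a single nonzero bin and is flagged.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = np.asarray(mask) > 0
    if mask.shape != volume.grid.shape:
        raise ValueError("mask and volume shapes differ")
    vals = np.asarray(volume.grid, dtype=float)[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        edges = np.linspace(lo - 0.5, lo + 0.5, n_levels + 1)
        counts = np.zeros(n_levels, dtype=np.int64)
        counts[0] = vals.size
        centers = 0.5 * (edges[:-1] + edges[1:])
        return GrayHistogram(counts, centers, edges, constant_image=True)
    counts, edges = np.histogram(vals, bins=n_levels, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return GrayHistogram(counts.astype(np.int64), centers, edges)


def compute_pwc(hist: GrayHistogram) -> PWCCurve:
    """The progressive weighted curve of a gray-level histogram.

    PWC(k) is the count-weighted mean of the gray values of bins 0..k. An
    all-zero prefix (no voxels yet) is backfilled with the first defined
    value, so the curve is total over the bin range.
    """
    w = np.asarray(hist.counts, dtype=float)
    if w.sum() == 0:
        raise ValueError("histogram has no counts")
    x = np.asarray(hist.levels, dtype=float)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * x)
    defined = cw > 0
    first = int(np.argmax(defined))
    values = np.empty_like(cw)
    values[defined] = cwx[defined] / cw[defined]
    values[:first] = values[first]
    return PWCCurve(values=values, levels=x, defined_from=first)


def find_candidate_thresholds(
    curve: PWCCurve, smoothing_sigma: float = 1.0, tol: float = 1e-6
) -> list[int]:
    """Bin indices where the (smoothed) PWC has an inflection point.

    The curve is smoothed with a Gaussian of ``smoothing_sigma`` bins and
    inflections are sign changes of the central second difference;
    curvatures below ``tol`` times the curve range are treated as zero, so
    flat or strictly linear curves return no candidates.
    """
    v = np.asarray(curve.values, dtype=float)
    if v.size < 5:
        return []
    if smoothing_sigma > 0:
        v = ndimage.gaussian_filter1d(v, smoothing_sigma, mode="nearest")
    d2 = v[2:] - 2.0 * v[1:-1] + v[:-2]  # second difference at index i+1
    vrange = float(v.max() - v.min())
    if vrange == 0:
        return []
    sign = np.zeros_like(d2, dtype=int)
    sign[d2 > tol * vrange] = 1
    sign[d2 < -tol * vrange] = -1
    idx_nonzero = np.nonzero(sign)[0]
    out = []
    for a, b in zip(idx_nonzero[:-1], idx_nonzero[1:]):
        if sign[a] != sign[b]:
            out.append(int((a + b) // 2) + 1)  # +1: d2[i] sits at curve index i+1
    return sorted(set(out))


def apply_threshold(
    volume: IntensityVolume,
    mask,
    level: float,
    polarity: str = "bright",
    min_object_voxels: int = 5,
):
    """Threshold inside the mask and label connected objects.

    Returns ``(labels, n_objects)`` where foreground voxels are those
    strictly brighter (``polarity="bright"``) or darker than ``level``,
    partitioned into 26-connected components with components smaller than
    ``min_object_voxels`` removed.
    """
    mask = np.asarray(mask) > 0
    grid = np.asarray(volume.grid)
    fg = mask & (grid > level if polarity == "bright" else grid < level)
    labels, n = ndimage.label(fg, structure=_STRUCT26)
    if n and min_object_voxels > 1:
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < min_object_voxels)[0]
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
            labels, n = ndimage.label(labels > 0, structure=_STRUCT26)
    return labels, int(n)


_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity in-slice


def _slice_circularity(obj: np.ndarray) -> float:
    """Area-weighted 4*pi*A/P^2 over axial (z) slice components.

    Each slice's cross-section may consist of several disjoint lobes (a
    cluster of spheres cut off-axis); circularity is evaluated per
    connected 2-D component and area-weighted, so a round lobe is not
    penalized for sharing a slice with another. Clipped to [0, 1].
    """
    areas, circs = [], []
    for k in range(obj.shape[2]):
        sl = obj[:, :, k]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=_STRUCT8)
        for lab in range(1, n + 1):
            comp = labels == lab
            a = int(comp.sum())
            p = _skperimeter(comp)
            c = 1.0 if p == 0 else min(1.0, 4.0 * np.pi * a / (p * p))
            areas.append(a)
            circs.append(c)
    return float(np.average(circs, weights=areas))


def _features_from_bbox(sub: np.ndarray, subg: np.ndarray) -> ObjectFeatures:
    """Features of one object given its (padded) bounding-box crop."""
    n = int(sub.sum())
    vals = subg[sub]
    if n == 1:
        circ, sd = 1.0, 0.0
    else:
        circ = _slice_circularity(sub)
        sd = float(vals.std())
    border = sub & ~ndimage.binary_erosion(sub)
    gx, gy, gz = np.gradient(subg)
    gmag = np.sqrt(gx**2 + gy**2 + gz**2)
    grad = float(gmag[border].mean()) if border.any() else 0.0
    return ObjectFeatures(
        circularity=circ,
        internal_sd=sd,
        border_gradient=grad,
        n_voxels=n,
        mean_intensity=float(vals.mean()),
    )


def _pad_bbox(bbox, shape, pad=2):
    return tuple(
        slice(max(0, s.start - pad), min(dim, s.stop + pad))
        for s, dim in zip(bbox, shape)
    )


def _label_features(labels: np.ndarray, n: int, grid: np.ndarray) -> list[ObjectFeatures]:
    """Features of every labeled object, evaluated on bounding-box crops."""
    out = []
    for lab, bbox in enumerate(ndimage.find_objects(labels, max_label=n), start=1):
        if bbox is None:  # pragma: no cover
            continue
        sl = _pad_bbox(bbox, labels.shape)
        out.append(_features_from_bbox(labels[sl] == lab, grid[sl].astype(float)))
    return out


def object_features(obj, volume: IntensityVolume) -> ObjectFeatures:
    """Shape and intensity features of one binary object.

    circularity: 4*pi*area/perimeter^2 per connected axial-slice component,
    area-weighted (1 for a single voxel); internal_sd: SD of member-voxel
    gray values; border_gradient: mean intensity-gradient magnitude (gray
    levels/voxel) over the object's boundary voxels. The gradient is
    evaluated on a bounding-box crop padded by 2 voxels, so it reflects the
    local edge, not far-field structure.
    """
    obj = np.asarray(obj) > 0
    if not obj.any():
        raise ValueError("empty object")
    grid = np.asarray(volume.grid, dtype=float)
    bbox = ndimage.find_objects(obj.astype(np.int8))[0]
    sl = _pad_bbox(bbox, obj.shape)
    return _features_from_bbox(obj[sl], grid[sl])


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, 0.5, dtype=float)
    return (values - lo) / (hi - lo)


def score_thresholds(
    candidate_objects: list[list[ObjectFeatures]],
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Quality score in [0, 1] for each candidate threshold.

    Features are min-max normalized over the pooled objects of *all*
    candidates (so scores are comparable across thresholds); each object's
    quality is the weighted mean of normalized circularity, normalized
    border gradient and one-minus-normalized internal SD — compact,
    sharp-edged, homogeneous objects (cysts) score high. A threshold's
    score is the object-volume-weighted mean quality; a candidate with no
    objects scores 0.
    """
    all_objs = [o for objs in candidate_objects for o in objs]
    scores = np.zeros(len(candidate_objects), dtype=float)
    if not all_objs:
        return scores
    circ = _minmax(np.array([o.circularity for o in all_objs]))
    grad = _minmax(np.array([o.border_gradient for o in all_objs]))
    sd = _minmax(np.array([o.internal_sd for o in all_objs]))
    wsum = float(sum(weights))
    quality = (weights[0] * circ + weights[1] * grad + weights[2] * (1.0 - sd)) / wsum
    pos = 0
    for i, objs in enumerate(candidate_objects):
        k = len(objs)
        if k == 0:
            continue
        q = quality[pos : pos + k]
        vol = np.array([o.n_voxels for o in objs], dtype=float)
        scores[i] = float(np.average(q, weights=vol))
        pos += k
    return scores


def _robust_sd(v: np.ndarray) -> float:
    """SD estimate via the median absolute deviation (normal-consistent)."""
    med = np.median(v)
    return float(1.4826 * np.median(np.abs(v - med)))


def _candidate_admissible(
    labels: np.ndarray, mask: np.ndarray, grid: np.ndarray, config: SegmentationConfig
) -> str | None:
    """Contrast gate; returns a rejection reason or None if admissible."""
    fg = labels > 0
    bg = mask & ~fg
    n_mask = int(mask.sum())
    if not fg.any():
        return "no objects"
    if int(bg.sum()) < config.min_background_fraction * n_mask:
        return "foreground covers the whole kidney"
    mu_fg = float(grid[fg].mean())
    mu_bg = float(grid[bg].mean())
    diff = mu_fg - mu_bg if config.polarity == "bright" else mu_bg - mu_fg
    if diff <= 0:
        return "no contrast"
    # two-sided Rose criterion: the separation must exceed min_cnr times
    # the internal spread of BOTH putative classes, otherwise the
    # threshold is merely splitting one population's noise. The spread is
    # the MAD-based robust SD so a minority of partial-volume shell voxels
    # inside a class cannot inflate it.
    spread = max(_robust_sd(grid[fg]), _robust_sd(grid[bg]))
    if spread == 0:
        return None
    if diff / spread < config.min_cnr:
        return f"contrast-to-noise {diff / spread:.2f} below {config.min_cnr}"
    return None


def segment_cysts(
    volume: IntensityVolume, mask, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Segment cysts inside the kidney mask by scored PWC thresholding.

    Pipeline: histogram -> PWC -> inflection candidates -> per-candidate
    object labeling, contrast gate and feature scoring -> best-scoring
    threshold (ties to the lower gray level). If the curve has no
    inflection points, falls back to the single maximum-between-class-
    variance (Otsu) threshold and flags it. If no candidate passes the
    contrast gate the kidney is reported cyst-free (empty mask).
    """
    config = config or SegmentationConfig()
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty kidney mask")
    grid = np.asarray(volume.grid, dtype=float)

    hist = build_histogram(volume, mask, config.bins)
    curve = compute_pwc(hist)
    cand_idx = find_candidate_thresholds(
        curve, config.smoothing_sigma, config.inflection_tol
    )

    used_fallback = False
    if not cand_idx and not hist.constant_image:
        level = float(threshold_otsu(grid[mask], nbins=config.bins))
        # snap to the nearest bin centre so reporting stays on the gray grid
        idx = int(np.clip(np.searchsorted(hist.levels, level), 0, len(hist.levels) - 1))
        cand_idx = [idx]
        used_fallback = True

    candidates: list[CandidateThreshold] = []
    per_cand_objects: list[list[ObjectFeatures]] = []
    masks: list[np.ndarray] = []
    for idx in cand_idx:
        level = float(hist.levels[idx])
        cand = CandidateThreshold(level=level, level_index=idx)
        labels, n = apply_threshold(
            volume, mask, level, config.polarity, config.min_object_voxels
        )
        # features are computed for every candidate — the min-max feature
        # normalization must see the full candidate set, while the contrast
        # gate only controls which candidates are eligible to win
        cand.objects = _label_features(labels, n, grid)
        cand.rejected = _candidate_admissible(labels, mask, grid, config)
        per_cand_objects.append(cand.objects)
        masks.append(labels > 0)
        candidates.append(cand)

    scores = score_thresholds(per_cand_objects, config.score_weights)
    for cand, s in zip(candidates, scores):
        cand.score = float(s) if cand.rejected is None else 0.0

    admissible = [i for i, c in enumerate(candidates) if c.rejected is None]
    if not admissible:
        empty = np.zeros_like(mask)
        return SegmentationResult(
            cyst_mask=empty,
            chosen_level=None,
            chosen_index=None,
            candidates=candidates,
            tcv_ml=0.0,
            used_fallback=used_fallback,
            no_valid_candidate=True,
        )
    # highest score wins; ties broken toward the lower gray level
    best = min(admissible, key=lambda i: (-candidates[i].score, candidates[i].level))
    cyst_mask = masks[best]
    return SegmentationResult(
        cyst_mask=cyst_mask,
        chosen_level=candidates[best].level,
        chosen_index=candidates[best].level_index,
        candidates=candidates,
        tcv_ml=compute_tcv(cyst_mask, volume.spacing),
        used_fallback=used_fallback,
    )


def compute_tcv(cyst_mask, spacing) -> float:
    """Total cyst volume in mL: voxel count times voxel volume."""
    return float(np.count_nonzero(np.asarray(cyst_mask)) * voxel_volume_ml(spacing))
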