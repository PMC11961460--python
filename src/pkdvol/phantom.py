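"""Synthetic 3-D kidney MRI phantoms with known ground truth.

Generates T2-weighted-like abdominal volumes: two ellipsoidal kidneys of
moderate parenchymal intensity containing hyperintense spherical cysts on a
dark background, degraded by partial-volume blur and noise, together with
ground-truth kidney and cyst masks. Because the true total kidney volume
(TKV) and total cyst volume (TCV) are known by construction, the phantoms
let the segmentation and volumetrics stages be validated quantitatively
without patient data.

The ``pattern`` field mimics the atypical presentations seen in Class 2
ADPKD: ``unilateral`` (cysts in one kidney only), ``lopsided`` (most cyst
volume on one side), ``asymmetric`` (unequal kidney sizes and cyst loads),
``bilateral_atrophy`` (small kidneys, few small cysts) and a
``typical_bilateral`` control.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "PhantomTruth", "PhantomError", "generate_phantom", "truth_volumes"]

PATTERNS = (
    "typical_bilateral",
    "unilateral",
    "lopsided",
    "asymmetric",
    "bilateral_atrophy",
)


class PhantomError(RuntimeError):
    """Phantom generation failed (e.g. a cyst could not be placed)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic kidney volume.

    Geometry is in millimetres; the grid axes are (x, y, z) with z the
    slice (axial) direction. Defaults emulate a 2 mm isotropic T2-weighted
    acquisition of two adult kidneys (~110 mm pole-to-pole) carrying a
    moderate polycystic load; cysts are hyperintense relative to
    parenchyma, as fluid is on T2 weighting.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    #: semiaxes (x, y, z) of each kidney ellipsoid, mm (enlarged, as in ADPKD)
    kidney_semiaxes: tuple[float, float, float] = (32.0, 36.0, 60.0)
    pattern: str = "typical_bilateral"
    #: cysts per kidney (before pattern-specific reallocation)
    n_cysts: int = 10
    cyst_radius_range: tuple[float, float] = (6.0, 14.0)
    parenchyma_intensity_mean_sd: tuple[float, float] = (100.0, 4.0)
    cyst_intensity_mean_sd: tuple[float, float] = (200.0, 8.0)
    background_intensity_mean_sd: tuple[float, float] = (40.0, 2.0)
    #: partial-volume blur of the ideal piecewise-constant image, mm
    blur_sigma: float = 2.0
    #: per-voxel noise SD in gray levels (contrast/noise >= 3 at defaults)
    noise_sd: float = 12.0
    noise_model: str = "gaussian"  # or "rician"
    n_gray_levels: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.cyst_intensity_mean_sd[0] <= self.parenchyma_intensity_mean_sd[0]:
            raise ValueError("cysts must be hyperintense relative to parenchyma (T2 convention)")
        if self.cyst_radius_range[0] > self.cyst_radius_range[1]:
            raise ValueError("cyst_radius_range must be (lo, hi)")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume.

    ``kidney_mask`` labels voxels 1 (left kidney) / 2 (right kidney);
    ``cyst_mask`` is the pre-blur cyst geometry, a subset of the kidneys.
    Volumes are in mL.
    """

    kidney_mask: np.ndarray
    cyst_mask: np.ndarray
    true_tkv: float
    true_tcv: float
    spec: PhantomSpec = field(repr=False, default=None)


def truth_volumes(truth: PhantomTruth, spacing) -> tuple[float, float]:
    """Recompute (true_tkv, true_tcv) in mL from the masks and spacing."""
    if truth.kidney_mask.shape != truth.cyst_mask.shape:
        raise ValueError("kidney and cyst masks must share a grid")
    voxel_ml = float(np.prod(spacing)) / 1000.0
    return (
        float(np.count_nonzero(truth.kidney_mask) * voxel_ml),
        float(np.count_nonzero(truth.cyst_mask) * voxel_ml),
    )


def _kidney_layout(spec: PhantomSpec):
    """Centres (mm), per-kidney semiaxes and cyst allocation for a pattern."""
    nx, ny, nz = spec.grid_shape
    sx, sy, sz = spec.voxel_spacing
    cx, cy, cz = nx * sx / 2.0, ny * sy / 2.0, nz * sz / 2.0
    ax, ay, az = spec.kidney_semiaxes
    gap = ax + 0.18 * nx * sx / 2.0  # lateral offset from midline
    centers = [(cx - gap, cy, cz), (cx + gap, cy, cz)]
    semi = [np.array([ax, ay, az]), np.array([ax, ay, az])]
    n = spec.n_cysts
    rlo, rhi = spec.cyst_radius_range
    radii_rng = [(rlo, rhi), (rlo, rhi)]
    if spec.pattern == "typical_bilateral":
        counts = [n, n]
    elif spec.pattern == "unilateral":
        counts = [n, 0]
    elif spec.pattern == "lopsided":
        # dominant kidney gets full count of large cysts; the other a few
        # small ones, so >=70% of cyst volume sits on one side
        counts = [n, max(1, n // 3)]
        radii_rng = [(max(rlo, 0.45 * rhi), rhi), (rlo, min(rhi, 0.45 * rhi))]
    elif spec.pattern == "asymmetric":
        semi = [np.array([1.1 * ax, 1.1 * ay, az]), np.array([ax, ay, az]) * 0.75]
        counts = [n, max(1, n // 2)]
    elif spec.pattern == "bilateral_atrophy":
        semi = [np.array([ax, ay, az]) * 0.6, np.array([ax, ay, az]) * 0.6]
        counts = [max(0, n // 3), max(0, n // 3)]
        radii_rng = [(0.6 * rlo, 0.3 * rhi), (0.6 * rlo, 0.3 * rhi)]
    else:  # pragma: no cover
        raise ValueError(spec.pattern)
    return centers, semi, counts, radii_rng


def _place_cysts(rng, center, semi, count, radius_range, placed, max_tries=500):
    """Sample non-overlapping cyst (centre, radius) pairs inside one kidney.

    Radii are drawn up front and placed largest-first, which makes dense
    packings feasible without changing the radius distribution.
    """
    rlo, rhi = radius_range
    radii = np.sort(rng.uniform(rlo, rhi, size=count))[::-1]
    new = []
    for j, r in enumerate(radii):
        margin = semi - r
        if np.any(margin <= 0):
            raise PhantomError(
                f"cyst {len(placed) + j}: radius {r:.1f} mm cannot fit inside "
                f"kidney semiaxes {tuple(semi)}"
            )
        for attempt in range(max_tries):
            # uniform in the unit ball, scaled to the shrunken ellipsoid so
            # the whole sphere fits inside the kidney
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            rad = rng.uniform() ** (1.0 / 3.0)
            c = np.asarray(center) + u * rad * margin
            if all(np.linalg.norm(c - pc) > r + pr for pc, pr in placed + new):
                new.append((c, r))
                break
        else:
            raise PhantomError(
                f"could not place cyst {len(placed) + len(new)} "
                f"(radius {r:.1f} mm) after {max_tries} tries"
            )
    return new


def generate_phantom(spec: PhantomSpec):
    """Generate one phantom.

    Returns
    -------
    (volume, truth) : (IntensityVolume, PhantomTruth)
        ``volume.grid`` holds gray levels quantized to
        ``spec.n_gray_levels`` discrete values; ``truth`` carries the
        kidney/cyst masks and the true volumes in mL. Deterministic for a
        fixed seed.
    """
    from .volume import IntensityVolume

    rng = np.random.default_rng(spec.seed)
    centers, semi, counts, radii_rng = _kidney_layout(spec)
    extent = [n * s for n, s in zip(spec.grid_shape, spec.voxel_spacing)]
    for c, a in zip(centers, semi):
        if any(ci - ai < 0 or ci + ai > ei for ci, ai, ei in zip(c, a, extent)):
            raise PhantomError(
                f"kidney at {tuple(round(x, 1) for x in c)} mm with semiaxes "
                f"{tuple(a)} does not fit inside the {tuple(extent)} mm grid"
            )

    coords = [
        np.arange(n) * s + s / 2.0
        for n, s in zip(spec.grid_shape, spec.voxel_spacing)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")

    kidney_mask = np.zeros(spec.grid_shape, dtype=np.uint8)
    for label, (c, a) in enumerate(zip(centers, semi), start=1):
        ell = ((X - c[0]) / a[0]) ** 2 + ((Y - c[1]) / a[1]) ** 2 + ((Z - c[2]) / a[2]) ** 2
        kidney_mask[ell <= 1.0] = label

    placed: list[tuple[np.ndarray, float]] = []
    for c, a, cnt, rr in zip(centers, semi, counts, radii_rng):
        placed += _place_cysts(rng, c, a, cnt, rr, placed)

    pmean, psd = spec.parenchyma_intensity_mean_sd
    cmean, csd = spec.cyst_intensity_mean_sd
    bmean, bsd = spec.background_intensity_mean_sd
    img = np.full(spec.grid_shape, bmean + rng.normal(0.0, bsd), dtype=float)
    img[kidney_mask > 0] = pmean + rng.normal(0.0, psd)

    cyst_mask = np.zeros(spec.grid_shape, dtype=bool)
    for c, r in placed:
        # fill within a bounding box only, for speed
        lo = [max(0, int((c[i] - r) / spec.voxel_spacing[i]) - 1) for i in range(3)]
        hi = [
            min(spec.grid_shape[i], int((c[i] + r) / spec.voxel_spacing[i]) + 2)
            for i in range(3)
        ]
        sl = tuple(slice(l, h) for l, h in zip(lo, hi))
        d2 = (X[sl] - c[0]) ** 2 + (Y[sl] - c[1]) ** 2 + (Z[sl] - c[2]) ** 2
        inside = d2 <= r * r
        cyst_mask[sl] |= inside
        img[sl][inside] = cmean + rng.normal(0.0, csd)
    cyst_mask &= kidney_mask > 0  # cysts are kidney tissue by construction

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(
            img, sigma=[spec.blur_sigma / s for s in spec.voxel_spacing]
        )
    if spec.noise_sd > 0:
        if spec.noise_model == "gaussian":
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        elif spec.noise_model == "rician":
            # magnitude of a complex signal with i.i.d. Gaussian channels
            re = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            im = rng.normal(0.0, spec.noise_sd, size=img.shape)
            img = np.hypot(re, im)
        else:
            raise ValueError(f"unknown noise model {spec.noise_model!r}")

    # quantize to discrete gray levels (histogram machinery works on levels)
    lo, hi = float(img.min()), float(img.max())
    k = spec.n_gray_levels - 1
    grid = np.rint((img - lo) / max(hi - lo, np.finfo(float).tiny) * k).astype(np.int32)

    voxel_ml = float(np.prod(spec.voxel_spacing)) / 1000.0
    truth = PhantomTruth(
        kidney_mask=kidney_mask,
        cyst_mask=cyst_mask,
        true_tkv=float(np.count_nonzero(kidney_mask) * voxel_ml),
        true_tcv=float(np.count_nonzero(cyst_mask) * voxel_ml),
        spec=spec,
    )
    return IntensityVolume(grid=grid, spacing=spec.voxel_spacing), truth


def write_phantom(out_dir, volume, truth: PhantomTruth) -> dict:
    """Write volume/kidney-mask/cyst-mask NIfTIs plus a JSON truth sidecar."""
    from .io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(out / "phantom.nii.gz", volume.grid.astype(np.float32), volume.spacing)
    write_volume(out / "kidney_mask.nii.gz", truth.kidney_mask.astype(np.uint8), volume.spacing)
    write_volume(out / "cyst_mask.nii.gz", truth.cyst_mask.astype(np.uint8), volume.spacing)
    sidecar = {
        "true_tkv_ml": truth.true_tkv,
        "true_tcv_ml": truth.true_tcv,
        "seed": truth.spec.seed if truth.spec else None,
        "spec": asdict(truth.spec) if truth.spec else None,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar
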