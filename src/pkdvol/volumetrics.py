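"""Per-subject kidney volumetrics and Mayo imaging classification.

Quantities: total kidney volume (TKV, mL), height-adjusted TKV (htTKV,
mL/m), total cyst volume (TCV), residual tissue volume RTV = TKV - TCV (the
vital, non-cystic tissue), the cyst-load ratios, nephromegaly (TKV >
750 mL), and the Mayo Clinic Imaging Classification: Class 1 subclasses
1A-1E by the estimated kidney growth rate implied by htTKV and age, Class 2
subclasses 2A/2B by the atypical presentation pattern.

The Class 1 model assumes exponential kidney growth from a 150 mL/m
baseline: htTKV = 150 * (1 + r)^age. Subclass cut points on the annual rate
r are 1.5 / 3 / 4.5 / 6 %; these constants come from the published Mayo
classification and are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import mayo2_subclass
from .volume import voxel_volume_ml

__all__ = [
    "VolumetricsResult",
    "compute_tkv",
    "height_adjust",
    "derive_volumetrics",
    "flag_nephromegaly",
    "mayo1_growth_rate",
    "classify_mayo1",
    "classify_mayo",
    "NEPHROMEGALY_TKV_ML",
    "MAYO1_BASELINE_HTTKV",
    "MAYO1_RATE_BOUNDS",
]

#: nephromegaly cutoff: TKV strictly greater than 750 mL
NEPHROMEGALY_TKV_ML = 750.0
#: htTKV (mL/m) assumed at age 0 in the Class 1 growth model
MAYO1_BASELINE_HTTKV = 150.0
#: upper annual growth-rate bound of classes 1A..1D (1E is above the last)
MAYO1_RATE_BOUNDS = (0.015, 0.03, 0.045, 0.06)

_BOUND_EPS = 1e-9  # tolerance so exact boundary rates fall to the lower class


@dataclass
class VolumetricsResult:
    """All derived volumetric quantities for one subject.

    ``tkv``/``tcv``/``rtv`` are in mL (or consistently in mL/m if the
    inputs were height-adjusted); ratios are unitless and ``tcv_percent``
    is 100*tcv/tkv.
    """

    tkv: float
    tcv: float
    rtv: float
    tcv_percent: float
    rtv_over_tcv: float
    rtv_over_tkv: float
    tcv_over_tkv: float
    nephromegaly: bool | None = None
    mayo_class: str | None = None
    httkv: float | None = None

    def as_dict(self) -> dict:
        return {
            "tkv_ml": self.tkv,
            "tcv_ml": self.tcv,
            "rtv_ml": self.rtv,
            "tcv_percent": self.tcv_percent,
            "rtv_over_tcv": self.rtv_over_tcv,
            "rtv_over_tkv": self.rtv_over_tkv,
            "tcv_over_tkv": self.tcv_over_tkv,
            "nephromegaly": self.nephromegaly,
            "mayo_class": self.mayo_class,
            "httkv_ml_per_m": self.httkv,
        }


def compute_tkv(kidney_mask, spacing) -> tuple[float, dict[int, float]]:
    """Total kidney volume in mL plus the per-label (per-kidney) volumes.

    ``kidney_mask`` is a label map (e.g. 1 = left kidney, 2 = right); any
    nonzero label counts toward the total.
    """
    mask = np.asarray(kidney_mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("empty kidney mask")
    vml = voxel_volume_ml(spacing)
    per_kidney = {int(l): float(np.count_nonzero(mask == l) * vml) for l in labels}
    return float(sum(per_kidney.values())), per_kidney


def height_adjust(volume_ml: float, height_m: float) -> float:
    """Height-adjusted volume (mL/m): volume divided by height in metres."""
    if height_m <= 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return volume_ml / height_m


def flag_nephromegaly(tkv_ml: float) -> bool:
    """True iff TKV strictly exceeds 750 mL."""
    if tkv_ml < 0:
        raise ValueError("TKV cannot be negative")
    return tkv_ml > NEPHROMEGALY_TKV_ML


def derive_volumetrics(tkv: float, tcv: float) -> VolumetricsResult:
    """RTV and the cyst-load ratios from (TKV, TCV).

    RTV = TKV - TCV exactly; rtv_over_tkv + tcv_over_tkv = 1. Rejects
    tcv > tkv, which signals inconsistent masks.
    """
    if tkv <= 0:
        raise ValueError(f"TKV must be positive, got {tkv}")
    if not 0 <= tcv <= tkv:
        raise ValueError(f"TCV must lie in [0, TKV]; got tcv={tcv}, tkv={tkv}")
    rtv = tkv - tcv
    return VolumetricsResult(
        tkv=tkv,
        tcv=tcv,
        rtv=rtv,
        tcv_percent=100.0 * tcv / tkv,
        rtv_over_tcv=(rtv / tcv) if tcv > 0 else float("inf"),
        rtv_over_tkv=rtv / tkv,
        tcv_over_tkv=tcv / tkv,
        nephromegaly=flag_nephromegaly(tkv),
    )


def mayo1_growth_rate(
    httkv: float, age_years: float, baseline: float = MAYO1_BASELINE_HTTKV
) -> float:
    """Annual growth rate r solving httkv = baseline * (1 + r)^age."""
    if age_years <= 0:
        raise ValueError("age must be positive")
    if httkv <= 0:
        raise ValueError("htTKV must be positive")
    return float((httkv / baseline) ** (1.0 / age_years) - 1.0)


def classify_mayo1(
    httkv: float,
    age_years: float,
    baseline: float = MAYO1_BASELINE_HTTKV,
    bounds: tuple[float, ...] = MAYO1_RATE_BOUNDS,
) -> str:
    """Mayo Class 1 subclass (1A-1E) from htTKV (mL/m) and age.

    The estimated annual growth rate r (exponential model from the
    ``baseline`` htTKV) is compared against ``bounds``; rates exactly on a
    boundary fall to the lower class. htTKV below the baseline implies a
    negative rate and is clamped to 1A with a warning.
    """
    if httkv < baseline:
        warnings.warn(
            f"htTKV {httkv:.1f} below the {baseline:.0f} mL/m baseline; clamped to 1A",
            stacklevel=2,
        )
        return "1A"
    r = mayo1_growth_rate(httkv, age_years, baseline)
    names = ("1A", "1B", "1C", "1D", "1E")
    for name, hi in zip(names, bounds):
        if r <= hi + _BOUND_EPS:
            return name
    return names[-1]


def classify_mayo(
    pattern: str | None, httkv: float | None = None, age_years: float | None = None
) -> str:
    """Full Mayo imaging class.

    An atypical ``pattern`` annotation takes precedence and yields 2A/2B;
    otherwise the Class 1 subclass is computed from (httkv, age).
    """
    if pattern is not None:
        return mayo2_subclass(pattern)
    if httkv is None or age_years is None:
        raise ValueError("need either an atypical pattern or (httkv, age)")
    return classify_mayo1(httkv, age_years)
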