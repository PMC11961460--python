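"""Shared I/O: NIfTI volumes, cohort CSVs and run configuration."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import REQUIRED_COLUMNS, _SCHEMA
from .volume import IntensityVolume

__all__ = ["RunConfig", "read_volume", "write_volume", "read_mask", "read_cohort_csv", "load_config"]

log = logging.getLogger("pkdvol")


@dataclass
class RunConfig:
    """Run-wide knobs, settable from a key = value config file and CLI flags.

    All volumes are mL, heights m and eGFR mL/min/1.73 m2 — no unit
    autodetection.
    """

    bins: int = 256
    polarity: str = "bright"
    smoothing_sigma: float = 1.0
    min_object_voxels: int = 5
    score_weights: tuple[float, float, float] = (1.0, 2.0, 1.0)
    progressor_cutoff: float = 1.9
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if any(w < 0 for w in self.score_weights) or not any(self.score_weights):
            raise ValueError("score weights must be non-negative, not all zero")


def load_config(path) -> RunConfig:
    """Parse a plain ``key = value`` config file into a :class:`RunConfig`."""
    values: dict = {}
    field_types = {f.name: f.type for f in fields(RunConfig)}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in field_types:
                warnings.warn(f"{path}:{lineno}: unknown config key {key!r} ignored")
                continue
            if key == "score_weights":
                values[key] = tuple(float(v) for v in val.split(","))
            elif key in ("bins", "min_object_voxels", "seed"):
                values[key] = int(val)
            elif key in ("smoothing_sigma", "progressor_cutoff"):
                values[key] = float(val)
            else:
                values[key] = val
    return RunConfig(**values)


def read_volume(path) -> IntensityVolume:
    """Read a 3-D NIfTI volume; spacing taken from the header zooms (mm)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return IntensityVolume(grid=data, spacing=spacing)


def write_volume(path, grid, spacing) -> None:
    """Write a 3-D array as NIfTI with a diagonal affine from the spacing."""
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError("expected a 3-D volume")
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(grid, affine), str(path))


def read_mask(path, like: IntensityVolume | None = None) -> np.ndarray:
    """Read a NIfTI label map, optionally checking grid agreement."""
    vol = read_volume(path)
    if like is not None:
        if vol.grid.shape != like.grid.shape:
            raise ValueError(
                f"mask grid {vol.grid.shape} does not match volume {like.grid.shape}"
            )
        if not np.allclose(vol.spacing, like.spacing):
            raise ValueError("mask voxel spacing does not match the volume")
    return np.asarray(vol.grid).astype(np.int32)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV with the packaged-fixture schema.

    Unknown columns produce a warning but are kept; missing required
    columns or invalid values are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        warnings.warn(f"cohort CSV has unknown columns (kept): {extra}")
        log.warning("unknown cohort columns: %s", extra)
    for col, typ in _SCHEMA.items():
        if typ is bool:
            if df[col].dtype != bool:
                df[col] = (
                    df[col].astype(str).str.strip().str.lower().map(
                        {"true": True, "false": False, "1": True, "0": False,
                         "yes": True, "no": False}
                    )
                )
                if df[col].isna().any():
                    raise ValueError(f"column {col!r}: unparseable boolean values")
                df[col] = df[col].astype(bool)
        elif typ is float:
            df[col] = df[col].astype(float)
    for col in ("serum_creatinine", "egfr", "httkv"):
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0, "patient_id"].tolist()
            raise ValueError(f"column {col!r} must be positive (patients {bad})")
    return df
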