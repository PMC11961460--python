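"""In-memory container for a 3-D gray-level volume with voxel spacing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IntensityVolume", "voxel_volume_ml"]


@dataclass
class IntensityVolume:
    """A 3-D intensity grid with physical voxel spacing in mm per axis."""

    grid: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got {self.grid.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def voxel_volume_ml(spacing) -> float:
    """Volume of one voxel in mL (spacing in mm)."""
    return float(np.prod(spacing)) / 1000.0
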