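"""In-memory containers for CT volumes and binary voxel masks.

Axis convention: arrays are indexed (x, y, z) with z the slice axis.
All estimators operate in voxel index space; the physical spacing (mm)
is carried as metadata and only used where explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageVolume:
    """A 3D scalar grid in Hounsfield Units with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if any(n < 1 for n in self.values.shape):
            raise ValueError(f"shape components must be >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class VoxelMask:
    """A 3D binary grid with spacing; foreground marks the voxel set."""

    foreground: np.ndarray
    spacing: tuple[float, float, float]
    n_foreground: int = field(init=False)

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground, dtype=bool)
        if self.foreground.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.foreground.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        self.n_foreground = int(self.foreground.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.foreground.shape

    def is_empty(self) -> bool:
        return self.n_foreground == 0
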