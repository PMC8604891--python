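"""Voxel containers shared by every stage: dose grids and binary structure masks.

A :class:`DoseGrid` is a plain 3D array of physical dose in Gy on a regular
grid with per-axis voxel spacing in millimetres.  A :class:`StructureMask` is
a named boolean volume on the *same* grid; no resampling happens anywhere in
this package — masks must match their dose grid voxel for voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, EmptyStructureError

__all__ = ["DoseGrid", "StructureMask", "voxel_volume_cc"]


def voxel_volume_cc(spacing_mm) -> float:
    """Volume of one voxel in cubic centimetres."""
    s = np.asarray(spacing_mm, dtype=float)
    return float(np.prod(s)) / 1000.0


@dataclass
class DoseGrid:
    """3D dose distribution in Gy.

    Parameters
    ----------
    values:
        3D float array, finite and non-negative everywhere.
    spacing_mm:
        Voxel edge lengths per axis in mm, strictly positive.
    origin_mm:
        Physical coordinate of the voxel (0, 0, 0) corner.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cc(self) -> float:
        return voxel_volume_cc(self.spacing_mm)


@dataclass
class StructureMask:
    """Named binary volume aligned to a dose grid."""

    name: str
    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask voxels must be a 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * voxel_volume_cc(self.spacing_mm)

    def require_aligned(self, dose: DoseGrid) -> None:
        if self.shape != dose.shape:
            raise AlignmentError(
                f"mask {self.name!r} shape {self.shape} does not match "
                f"dose grid shape {dose.shape}"
            )

    def require_nonempty(self) -> None:
        if not self.voxels.any():
            raise EmptyStructureError(f"structure {self.name!r} has no voxels")
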