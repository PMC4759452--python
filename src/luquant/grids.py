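"""Voxel grid container shared by phantoms, projectors and reconstructions.

A :class:`VoxelGrid` is a 3-D scalar field on an isotropic or anisotropic
regular grid.  Units of the values depend on the role of the grid: activity
concentration maps are in MBq/ml, attenuation maps in cm^-1 (at the 208 keV
Lu-177 photopeak), masks are dimensionless occupancy fractions in [0, 1].

The world coordinate origin sits at the geometric centre of the grid and the
third axis is the scanner (rotation) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]


def _as_voxel_mm(voxel_mm) -> tuple[float, float, float]:
    if np.isscalar(voxel_mm):
        voxel_mm = (float(voxel_mm),) * 3
    voxel_mm = tuple(float(v) for v in voxel_mm)
    if len(voxel_mm) != 3 or any(v <= 0 for v in voxel_mm):
        raise ValueError(f"voxel_mm must be 3 positive lengths, got {voxel_mm!r}")
    return voxel_mm


@dataclass
class VoxelGrid:
    """3-D scalar field with voxel size bookkeeping.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Per-voxel scalar values; must be finite.
    voxel_mm : float or 3-tuple of float
        Voxel edge lengths in mm (default 4.8 mm isotropic, the acquisition
        matrix of the emulated protocol).
    """

    values: np.ndarray
    voxel_mm: tuple[float, float, float] = (4.8, 4.8, 4.8)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VoxelGrid values must be finite")
        self.voxel_mm = _as_voxel_mm(self.voxel_mm)

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (= cm^3)."""
        vx, vy, vz = self.voxel_mm
        return vx * vy * vz / 1000.0

    def congruent(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_mm, other.voxel_mm)

    def require_congruent(self, other: "VoxelGrid", what: str = "grid"):
        if not self.congruent(other):
            raise ValueError(
                f"incongruent {what}: {self.shape}@{self.voxel_mm} vs "
                f"{other.shape}@{other.voxel_mm}"
            )

    def coords_mm(self):
        """World coordinates (mm) of voxel centres along each axis."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(self.shape, self.voxel_mm)
        )

    # -- convenience --------------------------------------------------------
    def copy(self, values: np.ndarray | None = None) -> "VoxelGrid":
        return VoxelGrid(self.values.copy() if values is None else values, self.voxel_mm)

    def total_activity_MBq(self) -> float:
        """Sum(values) * voxel volume; meaningful for concentration grids."""
        return float(self.values.sum() * self.voxel_volume_ml)
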