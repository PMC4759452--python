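"""Volumetric-sensitivity calibration and concentration recovery.

The volumetric sensitivity S_vol converts reconstructed image values into
activity concentration.  It is measured once per compensation combination
from the calibration-bottle reconstruction:

    S_vol = (R_bottle / V_bottle) / C_true

with R the reconstructed values summed over the bottle VOI, V the VOI volume
and C_true the known filling concentration (0.45 MBq/ml).  The concentration
recovery coefficient of an insert is then

    cRC = (R_insert / (V_insert * S_vol)) / C_insert ,

i.e. estimated over true concentration.  R is implemented as the VOI value
*total* with the explicit division by V, the only reading under which the
quotient is a concentration.

Quantification VOIs are binary centre-inclusion masks built from the nominal
sphere geometry, emulating human delineation on the CT boundary; the
partial-volume losses this admits are part of what the recovery coefficient
measures (no partial-volume correction is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import VoxelGrid
from .phantoms import InsertSpec
from .recon import ActivityImage

__all__ = ["VOIStatistics", "SensitivityFactor", "voi_statistics",
           "compute_sensitivity", "concentration_recovery", "delineate_insert_voi",
           "delineate_cylinder_voi"]


@dataclass(frozen=True)
class VOIStatistics:
    total_counts: float
    volume_ml: float

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise ValueError("VOI volume must be positive")
        if self.total_counts < 0:
            raise ValueError("VOI total must be non-negative")

    @property
    def mean_counts_per_ml(self) -> float:
        return self.total_counts / self.volume_ml


@dataclass(frozen=True)
class SensitivityFactor:
    """Reconstructed value per ml per (MBq/ml) of true concentration, tagged
    with the compensation combination it was derived under."""

    S_vol: float
    compensation: str
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.S_vol <= 0:
            raise ValueError("S_vol must be positive")


def _image_values(image) -> tuple[np.ndarray, VoxelGrid]:
    if isinstance(image, ActivityImage):
        return image.values, image.grid
    if isinstance(image, VoxelGrid):
        return image.values, image
    raise TypeError(f"expected ActivityImage or VoxelGrid, got {type(image)!r}")


def voi_statistics(image, mask: VoxelGrid) -> VOIStatistics:
    """Total reconstructed value and volume over a (fractional) VOI mask."""
    values, grid = _image_values(image)
    grid.require_congruent(mask, "VOI mask")
    msum = float(mask.values.sum())
    if msum == 0:
        raise ValueError("empty VOI mask")
    total = float((values * mask.values).sum())
    return VOIStatistics(total_counts=total, volume_ml=msum * mask.voxel_volume_ml)


def compute_sensitivity(calibration_image: ActivityImage, bottle_mask: VoxelGrid,
                        C_true_MBq_ml: float = 0.45) -> SensitivityFactor:
    """Volumetric sensitivity from the calibration-bottle reconstruction."""
    if C_true_MBq_ml <= 0:
        raise ValueError("true concentration must be positive")
    stats = voi_statistics(calibration_image, bottle_mask)
    if stats.total_counts <= 0:
        raise ValueError("no reconstructed counts in the calibration VOI")
    comp = calibration_image.compensation if isinstance(calibration_image, ActivityImage) else None
    return SensitivityFactor(
        S_vol=stats.mean_counts_per_ml / C_true_MBq_ml,
        compensation=comp or "unknown",
        provenance={"C_true_MBq_ml": C_true_MBq_ml,
                    "V_bottle_ml": stats.volume_ml,
                    "R_bottle": stats.total_counts},
    )


def concentration_recovery(image: ActivityImage, voi_mask: VoxelGrid,
                           S_vol: SensitivityFactor, C_insert_MBq_ml: float) -> float:
    """cRC = (R / (V * S_vol)) / C_insert for one insert VOI.

    The image and the sensitivity factor must come from the same compensation
    combination; mixing them would silently bias the recovery estimate.
    """
    if C_insert_MBq_ml <= 0:
        raise ValueError("true insert concentration must be positive")
    if isinstance(image, ActivityImage) and image.compensation is not None:
        if image.compensation != S_vol.compensation:
            raise ValueError(
                f"compensation mismatch: image is {image.compensation!r} but "
                f"S_vol was calibrated under {S_vol.compensation!r}"
            )
    stats = voi_statistics(image, voi_mask)
    estimated_concentration = stats.mean_counts_per_ml / S_vol.S_vol
    return estimated_concentration / C_insert_MBq_ml


def delineate_insert_voi(insert: InsertSpec, grid_like: VoxelGrid) -> VoxelGrid:
    """Binary CT-style VOI: voxels whose centres lie inside the nominal sphere.

    A sub-voxel sphere degenerates to the single voxel containing the centre
    (with a warning), as a human delineating on CT would still mark it.
    """
    cx, cy, cz = grid_like.coords_mm()
    center = np.asarray(insert.center_mm, dtype=float)
    lo = (cx[0], cy[0], cz[0])
    hi = (cx[-1], cy[-1], cz[-1])
    half = np.asarray(grid_like.voxel_mm) / 2.0
    if np.any(center < np.asarray(lo) - half) or np.any(center > np.asarray(hi) + half):
        raise ValueError(f"insert {insert.label} centre {tuple(center)} outside the grid")

    gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
    r2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
    mask = (r2 <= insert.radius_mm**2).astype(float)
    if mask.sum() == 0:
        warnings.warn(
            f"insert {insert.label} ({insert.volume_ml} ml) is sub-voxel; "
            "VOI degenerates to the voxel containing its centre",
            stacklevel=2,
        )
        idx = np.unravel_index(np.argmin(r2), r2.shape)
        mask[idx] = 1.0
    return VoxelGrid(mask, grid_like.voxel_mm)


def delineate_cylinder_voi(center_mm, radius_mm: float, height_mm: float,
                           grid_like: VoxelGrid) -> VoxelGrid:
    """Binary centre-inclusion VOI of an axis-aligned cylinder (bottle VOI)."""
    cx, cy, cz = grid_like.coords_mm()
    gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
    c = np.asarray(center_mm, dtype=float)
    mask = (((gx - c[0]) ** 2 + (gy - c[1]) ** 2 <= radius_mm**2)
            & (np.abs(gz - c[2]) <= height_mm / 2.0)).astype(float)
    if mask.sum() == 0:
        raise ValueError("cylinder VOI contains no voxel centres")
    return VoxelGrid(mask, grid_like.voxel_mm)
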