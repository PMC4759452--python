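"""Digital phantoms: the tumour-insert torso and the calibration bottle.

Two voxelized phantoms stand in for the physical ones:

* a torso with nine spherical "tumour" inserts (0.4-104.4 cm^3) at 30:1
  insert-to-background concentration, a mildly active (1.7:1) left lung, a
  cold right lung, both lungs at 0.3 g/cm^3 density, and 806 MBq total
  activity;
* a 525 cm^3 bottle at 0.45 MBq/cm^3 centred in a water-filled cylinder, used
  to calibrate the volumetric sensitivity of the system.

Phantom construction is fully deterministic: region masks are fractional
occupancy grids obtained by sub-voxel supersampling, and the background
concentration is solved in closed form so the configured concentration ratios
and total activity hold exactly on the voxelized grid.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import MU_WATER_208KEV_PER_CM
from .grids import VoxelGrid

__all__ = [
    "InsertSpec",
    "DigitalPhantom",
    "TorsoConfig",
    "CalibrationConfig",
    "TABLE_INSERTS",
    "sphere_radius_from_volume",
    "rasterize_sphere",
    "rasterize_ellipsoid",
    "rasterize_cylinder",
    "build_torso_phantom",
    "build_calibration_phantom",
]


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def sphere_radius_from_volume(volume_ml: float) -> float:
    """Radius (cm) of a sphere of the given volume (ml = cm^3)."""
    if volume_ml <= 0:
        raise ValueError(f"volume must be positive, got {volume_ml}")
    return (3.0 * volume_ml / (4.0 * np.pi)) ** (1.0 / 3.0)


def _supersample_offsets(supersample: int, voxel_mm):
    """Sub-voxel centre offsets (mm) of a supersample^3 lattice."""
    s = int(supersample)
    frac = (np.arange(s) + 0.5) / s - 0.5
    ox, oy, oz = np.meshgrid(
        frac * voxel_mm[0], frac * voxel_mm[1], frac * voxel_mm[2], indexing="ij"
    )
    return np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)  # (s^3, 3)


def _fractional_mask(grid: VoxelGrid, inside_fn, bbox_lo_mm, bbox_hi_mm, supersample: int):
    """Generic fractional rasterizer.

    ``inside_fn(points_mm) -> bool array`` decides membership of sub-voxel
    sample points; only voxels intersecting the bounding box are sampled.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    nx, ny, nz = grid.shape
    cx, cy, cz = grid.coords_mm()
    mask = np.zeros(grid.shape, dtype=np.float64)

    half = np.asarray(grid.voxel_mm) / 2.0
    ix = np.where((cx >= bbox_lo_mm[0] - half[0]) & (cx <= bbox_hi_mm[0] + half[0]))[0]
    iy = np.where((cy >= bbox_lo_mm[1] - half[1]) & (cy <= bbox_hi_mm[1] + half[1]))[0]
    iz = np.where((cz >= bbox_lo_mm[2] - half[2]) & (cz <= bbox_hi_mm[2] + half[2]))[0]
    if len(ix) == 0 or len(iy) == 0 or len(iz) == 0:
        return VoxelGrid(mask, grid.voxel_mm), True

    gx, gy, gz = np.meshgrid(cx[ix], cy[iy], cz[iz], indexing="ij")
    centres = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)  # (M, 3)
    offs = _supersample_offsets(supersample, grid.voxel_mm)           # (s^3, 3)
    pts = centres[:, None, :] + offs[None, :, :]
    frac = inside_fn(pts.reshape(-1, 3)).reshape(len(centres), -1).mean(axis=1)
    sub = mask[np.ix_(ix, iy, iz)]
    sub[...] = frac.reshape(len(ix), len(iy), len(iz))
    mask[np.ix_(ix, iy, iz)] = sub
    return VoxelGrid(mask, grid.voxel_mm), bool(frac.sum() == 0.0)


def rasterize_sphere(center_mm, radius_mm: float, grid: VoxelGrid, supersample: int = 3) -> VoxelGrid:
    """Fractional-occupancy mask of a sphere.

    Occupancy per voxel is the fraction of a supersample^3 sub-voxel lattice
    falling inside the sphere.  Spheres smaller than a few voxels are sampled
    with a proportionally finer lattice (spacing <~ radius/10) so the mask
    volume converges for the sub-voxel inserts too.  A sphere entirely
    outside the grid yields an all-zero mask and a warning.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    center = np.asarray(center_mm, dtype=float)
    if radius_mm == 0.0:
        return VoxelGrid(np.zeros(grid.shape), grid.voxel_mm)
    needed = int(np.ceil(10.0 * max(grid.voxel_mm) / radius_mm))
    supersample = max(int(supersample), min(25, needed))

    def inside(p):
        return ((p - center) ** 2).sum(axis=1) <= radius_mm**2

    lo, hi = center - radius_mm, center + radius_mm
    mask, empty = _fractional_mask(grid, inside, lo, hi, supersample)
    if empty:
        warnings.warn(
            f"sphere at {center_mm} (r={radius_mm} mm) lies outside the grid",
            stacklevel=2,
        )
    return mask


def rasterize_ellipsoid(center_mm, semi_axes_mm, grid: VoxelGrid, supersample: int = 3) -> VoxelGrid:
    center = np.asarray(center_mm, dtype=float)
    axes = np.asarray(semi_axes_mm, dtype=float)
    if np.any(axes <= 0):
        raise ValueError("semi-axes must be positive")

    def inside(p):
        return (((p - center) / axes) ** 2).sum(axis=1) <= 1.0

    mask, _ = _fractional_mask(grid, inside, center - axes, center + axes, supersample)
    return mask


def rasterize_cylinder(center_mm, radius_mm: float, height_mm: float, grid: VoxelGrid,
                       supersample: int = 3) -> VoxelGrid:
    """Fractional mask of a z-axis-aligned circular cylinder."""
    if radius_mm <= 0 or height_mm <= 0:
        raise ValueError("radius and height must be positive")
    center = np.asarray(center_mm, dtype=float)

    def inside(p):
        d = p - center
        return (d[:, 0] ** 2 + d[:, 1] ** 2 <= radius_mm**2) & (
            np.abs(d[:, 2]) <= height_mm / 2.0
        )

    lo = center - [radius_mm, radius_mm, height_mm / 2.0]
    hi = center + [radius_mm, radius_mm, height_mm / 2.0]
    mask, _ = _fractional_mask(grid, inside, lo, hi, supersample)
    return mask


# ---------------------------------------------------------------------------
# phantom specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InsertSpec:
    """Nominal specification of one spherical tumour insert."""

    label: str
    volume_ml: float
    activity_MBq: float
    center_mm: tuple[float, float, float]

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise ValueError(f"{self.label}: volume must be positive")
        if self.activity_MBq < 0:
            raise ValueError(f"{self.label}: activity must be >= 0")

    @property
    def concentration_MBq_ml(self) -> float:
        """Nominal concentration, exactly activity/volume."""
        return self.activity_MBq / self.volume_ml

    @property
    def radius_mm(self) -> float:
        return sphere_radius_from_volume(self.volume_ml) * 10.0


def _ring_xy(k: int, n: int = 7, a_mm: float = 90.0, b_mm: float = 70.0):
    phi = 2.0 * np.pi * k / n
    return (a_mm * np.cos(phi), b_mm * np.sin(phi))


#: Nine-insert table: volumes (cm^3) and activities (MBq); default centres put
#: Q2/Q3 next to the left/right lungs under the sternum and the remaining
#: seven on an elliptical ring in the abdomen.
TABLE_INSERTS: tuple[InsertSpec, ...] = (
    InsertSpec("Q1", 104.4, 105.2, (*_ring_xy(0), -80.0)),
    InsertSpec("Q2", 30.3, 31.2, (60.0, -80.0, 40.0)),
    InsertSpec("Q3", 30.3, 30.4, (-60.0, -80.0, 40.0)),
    InsertSpec("Q4", 26.1, 27.2, (*_ring_xy(1), -80.0)),
    InsertSpec("Q5", 10.8, 11.9, (*_ring_xy(2), -80.0)),
    InsertSpec("Q6", 5.5, 5.8, (*_ring_xy(3), -80.0)),
    InsertSpec("Q7", 2.6, 2.7, (*_ring_xy(4), -80.0)),
    InsertSpec("Q8", 1.2, 1.2, (*_ring_xy(5), -80.0)),
    InsertSpec("Q9", 0.4, 0.5, (*_ring_xy(6), -80.0)),
)


@dataclass
class DigitalPhantom:
    """Paired activity/attenuation voxel grids with labelled region masks."""

    activity: VoxelGrid          # MBq/ml
    mu: VoxelGrid                # cm^-1 at 208 keV
    masks: dict                  # name -> fractional VoxelGrid in [0, 1]
    inserts: list = field(default_factory=list)
    background_concentration_MBq_ml: float = 0.0
    insert_concentration_MBq_ml: float = 0.0

    def __post_init__(self):
        self.activity.require_congruent(self.mu, "activity/mu")
        if np.any(self.activity.values < 0):
            raise ValueError("activity must be non-negative")
        for name, m in self.masks.items():
            self.activity.require_congruent(m, f"mask '{name}'")
            if m.values.min() < 0 or m.values.max() > 1 + 1e-9:
                raise ValueError(f"mask '{name}' outside [0, 1]")

    @property
    def voxel_mm(self):
        return self.activity.voxel_mm

    def total_activity_MBq(self) -> float:
        return self.activity.total_activity_MBq()


@dataclass
class TorsoConfig:
    """Geometry and activity configuration of the torso phantom.

    The torso body is an elliptical water cylinder (the physical phantom's
    dimensions are not part of the emulated specification, so they are
    configuration); the two lungs are ellipsoids at 0.3 g/cm^3.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    voxel_mm: float = 4.8
    body_semi_axes_cm: tuple[float, float] = (19.0, 13.0)
    lung_right_center_mm: tuple[float, float, float] = (-70.0, 0.0, 80.0)
    lung_right_semi_mm: tuple[float, float, float] = (60.0, 70.0, 64.5)   # ~1134 cm^3
    lung_left_center_mm: tuple[float, float, float] = (70.0, 0.0, 80.0)
    lung_left_semi_mm: tuple[float, float, float] = (55.0, 70.0, 56.2)    # ~907 cm^3
    inserts: tuple[InsertSpec, ...] = TABLE_INSERTS
    total_activity_MBq: float = 806.0
    insert_to_background_ratio: float = 30.0
    left_lung_to_background_ratio: float = 1.7
    lung_density_g_ml: float = 0.3
    mu_water_per_cm: float = MU_WATER_208KEV_PER_CM
    supersample: int = 3


@dataclass
class CalibrationConfig:
    """Calibration bottle inside a water cylinder."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_mm: float = 4.8
    body_radius_mm: float = 108.0
    body_height_mm: float = 200.0
    bottle_diameter_mm: float = 66.0
    bottle_height_mm: float = 153.0
    bottle_concentration_MBq_ml: float = 0.45
    mu_water_per_cm: float = MU_WATER_208KEV_PER_CM
    supersample: int = 3

    @property
    def bottle_volume_ml(self) -> float:
        r_cm = self.bottle_diameter_mm / 20.0
        return float(np.pi * r_cm**2 * self.bottle_height_mm / 10.0)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _check_insert_overlap(inserts):
    for i, a in enumerate(inserts):
        for b in inserts[i + 1:]:
            d = np.linalg.norm(np.subtract(a.center_mm, b.center_mm))
            if d < a.radius_mm + b.radius_mm:
                raise ValueError(
                    f"inserts {a.label} and {b.label} overlap "
                    f"(centre distance {d:.1f} mm < radii sum "
                    f"{a.radius_mm + b.radius_mm:.1f} mm)"
                )


def build_torso_phantom(config: TorsoConfig | None = None) -> DigitalPhantom:
    """Voxelize the nine-insert torso phantom.

    The background concentration c_b is solved from the activity balance

        A_total = c_b * Vvox * (S_bg + r_lung * S_lungL + r_ins * sum_i S_i)

    with S_* the fractional-mask voxel sums, so the configured concentration
    ratios (inserts 30x, active left lung 1.7x background) and the total
    activity (806 MBq) hold exactly on the grid.  All inserts share one
    concentration, as when filled from a single stock solution.
    """
    cfg = config or TorsoConfig()
    ref = VoxelGrid(np.zeros(cfg.grid_shape), cfg.voxel_mm)
    _check_insert_overlap(cfg.inserts)

    ax_mm = (cfg.body_semi_axes_cm[0] * 10.0, cfg.body_semi_axes_cm[1] * 10.0)
    cx, cy, cz = ref.coords_mm()
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    body_xy = ((gx / ax_mm[0]) ** 2 + (gy / ax_mm[1]) ** 2 <= 1.0).astype(float)
    body = VoxelGrid(np.repeat(body_xy[:, :, None], ref.shape[2], axis=2), cfg.voxel_mm)

    lung_r = rasterize_ellipsoid(cfg.lung_right_center_mm, cfg.lung_right_semi_mm, ref,
                                 cfg.supersample)
    lung_l = rasterize_ellipsoid(cfg.lung_left_center_mm, cfg.lung_left_semi_mm, ref,
                                 cfg.supersample)

    masks: dict = {"body": body, "lung_right": lung_r, "lung_left": lung_l}
    insert_sum = np.zeros(ref.shape)
    for ins in cfg.inserts:
        m = rasterize_sphere(ins.center_mm, ins.radius_mm, ref, cfg.supersample)
        masks[ins.label] = m
        insert_sum += m.values

    bg = np.clip(
        body.values - lung_r.values - lung_l.values - insert_sum, 0.0, 1.0
    )
    masks["background"] = VoxelGrid(bg, cfg.voxel_mm)

    vvol = ref.voxel_volume_ml
    denom = vvol * (
        bg.sum()
        + cfg.left_lung_to_background_ratio * lung_l.values.sum()
        + cfg.insert_to_background_ratio * insert_sum.sum()
    )
    c_bg = cfg.total_activity_MBq / denom

    activity = c_bg * (
        bg
        + cfg.left_lung_to_background_ratio * lung_l.values
        + cfg.insert_to_background_ratio * insert_sum
    )

    mu = cfg.mu_water_per_cm * (
        body.values - (1.0 - cfg.lung_density_g_ml) * (lung_r.values + lung_l.values)
    )

    return DigitalPhantom(
        activity=VoxelGrid(activity, cfg.voxel_mm),
        mu=VoxelGrid(np.clip(mu, 0.0, None), cfg.voxel_mm),
        masks=masks,
        inserts=list(cfg.inserts),
        background_concentration_MBq_ml=float(c_bg),
        insert_concentration_MBq_ml=float(c_bg * cfg.insert_to_background_ratio),
    )


def build_calibration_phantom(config: CalibrationConfig | None = None) -> DigitalPhantom:
    """Voxelize the uniform-concentration calibration bottle in its water bath."""
    cfg = config or CalibrationConfig()
    if (cfg.bottle_diameter_mm / 2.0 > cfg.body_radius_mm
            or cfg.bottle_height_mm > cfg.body_height_mm):
        raise ValueError("calibration bottle does not fit inside the body cylinder")
    ref = VoxelGrid(np.zeros(cfg.grid_shape), cfg.voxel_mm)

    body = rasterize_cylinder((0, 0, 0), cfg.body_radius_mm, cfg.body_height_mm, ref,
                              cfg.supersample)
    bottle = rasterize_cylinder((0, 0, 0), cfg.bottle_diameter_mm / 2.0,
                                cfg.bottle_height_mm, ref, cfg.supersample)

    activity = cfg.bottle_concentration_MBq_ml * bottle.values
    mu = cfg.mu_water_per_cm * body.values

    return DigitalPhantom(
        activity=VoxelGrid(activity, cfg.voxel_mm),
        mu=VoxelGrid(mu, cfg.voxel_mm),
        masks={"body": body, "bottle": bottle},
        inserts=[],
        background_concentration_MBq_ml=0.0,
        insert_concentration_MBq_ml=cfg.bottle_concentration_MBq_ml,
    )
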