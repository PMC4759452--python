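"""Acquisition, system-model and reconstruction configuration.

All physical constants that the pipeline depends on but that are properties
of the camera rather than of the algorithms live here, with explicit units in
the attribute names:

* the acquisition protocol (views, dwell, matrix, energy window, orbit),
* the distance-dependent collimator/detector Gaussian response (MELP),
* the bilinear HU -> linear-attenuation-coefficient conversion at 208 keV,
* Monte-Carlo scatter-estimation controls,
* the OSEM iteration schedule and compensation combination.

Defaults emulate a Lu-177 therapy-followup protocol: 64 projections of 20 s on
a 128 x 128 matrix with 4.8 mm pixels, 20 % window at the 208 keV photopeak,
medium-energy parallel-hole collimation and a non-circular orbit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ProtocolConfig",
    "PSFModel",
    "MuConversion",
    "ScatterConfig",
    "ReconConfig",
    "RunConfig",
    "elliptical_orbit_radii_cm",
    "MU_WATER_208KEV_PER_CM",
    "LU177_MEAN_ELECTRON_KEV",
]

#: Linear attenuation coefficient of water at 208 keV (cm^-1).  A physical
#: constant of the model, overridable through :class:`MuConversion`.
MU_WATER_208KEV_PER_CM = 0.137

#: Mean electron (beta + conversion/Auger) energy emitted per Lu-177 decay, keV.
#: Used for the electron self-dose; ICRP-style tabulated value.
LU177_MEAN_ELECTRON_KEV = 147.9


def elliptical_orbit_radii_cm(
    n_views: int,
    semi_axis_x_cm: float,
    semi_axis_y_cm: float,
    margin_cm: float = 2.0,
    start_deg: float = 0.0,
) -> np.ndarray:
    """Per-view detector-to-axis distances for a non-circular orbit.

    The detector face follows the support function of the patient/phantom
    ellipse (semi-axes ``a``, ``b``) plus a safety margin, emulating a
    body-contouring step-and-shoot orbit.
    """
    theta = np.deg2rad(start_deg + np.arange(n_views) * 360.0 / n_views)
    support = np.sqrt(
        (semi_axis_x_cm * np.cos(theta)) ** 2 + (semi_axis_y_cm * np.sin(theta)) ** 2
    )
    return support + margin_cm


@dataclass
class ProtocolConfig:
    """SPECT acquisition protocol constants."""

    n_views: int = 64
    dwell_s: float = 20.0
    matrix: int = 128
    pixel_mm: float = 4.8
    photopeak_keV: float = 208.0
    window_fraction: float = 0.20
    orbit_radii_cm: np.ndarray | None = None
    #: planar system sensitivity, counts/s per MBq in air; cancels through the
    #: volumetric-sensitivity calibration and only sets the noise level.
    sensitivity_cps_per_MBq: float = 10.0
    start_angle_deg: float = 0.0

    def __post_init__(self):
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        for name in ("dwell_s", "pixel_mm", "photopeak_keV", "window_fraction",
                     "sensitivity_cps_per_MBq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.orbit_radii_cm is not None:
            self.orbit_radii_cm = np.asarray(self.orbit_radii_cm, dtype=float)
            if len(self.orbit_radii_cm) != self.n_views:
                raise ValueError("orbit_radii_cm must have one entry per view")
            if np.any(self.orbit_radii_cm <= 0):
                raise ValueError("orbit radii must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return self.start_angle_deg + np.arange(self.n_views) * 360.0 / self.n_views

    @property
    def energy_window_keV(self) -> tuple[float, float]:
        half = 0.5 * self.window_fraction * self.photopeak_keV
        return (self.photopeak_keV - half, self.photopeak_keV + half)

    def radii(self, default_cm: float = 25.0) -> np.ndarray:
        if self.orbit_radii_cm is None:
            return np.full(self.n_views, float(default_cm))
        return self.orbit_radii_cm


@dataclass
class PSFModel:
    """Distance-dependent Gaussian collimator-detector response.

    FWHM(d) = fwhm0_mm + slope_mm_per_cm * d, with d the source-to-collimator
    distance in cm.  Defaults are a medium-energy low-penetration (MELP)
    parallel-hole assumption: 4 mm at the face, growing 0.5 mm per cm.
    """

    fwhm0_mm: float = 4.0
    slope_mm_per_cm: float = 0.5

    def __post_init__(self):
        if self.fwhm0_mm < 0 or self.slope_mm_per_cm < 0:
            raise ValueError("PSF parameters must be non-negative")


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def psf_sigma_mm(distance_cm, psf: PSFModel):
    """Gaussian sigma (mm) at a given source-to-collimator distance (cm)."""
    distance_cm = np.asarray(distance_cm, dtype=float)
    if np.any(distance_cm < 0):
        raise ValueError("distance must be non-negative")
    out = (psf.fwhm0_mm + psf.slope_mm_per_cm * distance_cm) * _FWHM_TO_SIGMA
    return out if out.ndim else float(out)


@dataclass
class MuConversion:
    """Bilinear HU -> mu (cm^-1) conversion at the 208 keV photopeak.

    Below the breakpoint the map interpolates between air (mu(-1000) = 0) and
    water (mu(0) = mu_water); above it a shallower bone-like slope applies.
    The two segments join continuously at the breakpoint.
    """

    mu_water_per_cm: float = MU_WATER_208KEV_PER_CM
    hu_breakpoint: float = 0.0
    slope_above_per_cm_per_kHU: float | None = None  # default: half the water slope

    def __post_init__(self):
        if self.mu_water_per_cm <= 0:
            raise ValueError("mu_water_per_cm must be positive")
        if self.slope_above_per_cm_per_kHU is None:
            self.slope_above_per_cm_per_kHU = 0.5 * self.mu_water_per_cm


@dataclass
class ScatterConfig:
    """Monte-Carlo scatter estimation controls (forced detection)."""

    n_photons: int = 100_000
    downsample_factor: int = 2
    max_orders: int = 1
    rng_seed: int = 0
    depth_bins: int = 4

    def __post_init__(self):
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.max_orders < 1:
            raise ValueError("max_orders must be >= 1")


_COMPENSATIONS = ("A", "AR", "ARS")


@dataclass
class ReconConfig:
    """OSEM schedule and compensation combination.

    compensation: "A" (attenuation), "AR" (+ collimator-detector response) or
    "ARS" (+ Monte-Carlo scatter).  The scatter estimate is refreshed at the
    start of the iterations listed in ``scatter_update_iterations`` (1-based)
    and frozen afterwards; it enters the forward model only.
    """

    n_iterations: int = 15
    n_subsets: int = 16
    compensation: str = "ARS"
    scatter_update_iterations: tuple[int, ...] = (1, 2)
    scatter_config: ScatterConfig | None = None
    epsilon: float = 1e-10  # small-denominator guard in the multiplicative update

    def __post_init__(self):
        if self.compensation not in _COMPENSATIONS:
            raise ValueError(f"compensation must be one of {_COMPENSATIONS}")
        if self.n_iterations < 1 or self.n_subsets < 1:
            raise ValueError("n_iterations and n_subsets must be >= 1")
        if self.compensation == "ARS" and self.scatter_config is None:
            self.scatter_config = ScatterConfig()


@dataclass
class RunConfig:
    """Full-pipeline configuration (simulate -> calibrate -> reconstruct ->
    quantify), serializable to/from YAML losslessly."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    psf: PSFModel = field(default_factory=PSFModel)
    mu_conversion: MuConversion = field(default_factory=MuConversion)
    recon: ReconConfig = field(default_factory=ReconConfig)
    scatter: ScatterConfig = field(default_factory=ScatterConfig)
    seeds: dict = field(default_factory=lambda: {"acquisition": 1, "scatter": 2})
    output_dir: str = "luquant_out"

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        radii = d["protocol"]["orbit_radii_cm"]
        if radii is not None:
            d["protocol"]["orbit_radii_cm"] = [float(r) for r in radii]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = ScatterConfig(**d.pop("scatter", {}))
        recon_d = dict(d.pop("recon", {}))
        if recon_d.get("scatter_config") is not None:
            recon_d["scatter_config"] = ScatterConfig(**recon_d["scatter_config"])
        if "scatter_update_iterations" in recon_d:
            recon_d["scatter_update_iterations"] = tuple(recon_d["scatter_update_iterations"])
        return cls(
            protocol=ProtocolConfig(**d.pop("protocol", {})),
            psf=PSFModel(**d.pop("psf", {})),
            mu_conversion=MuConversion(**d.pop("mu_conversion", {})),
            recon=ReconConfig(**recon_d),
            scatter=sc,
            **d,
        )

    def save_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
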