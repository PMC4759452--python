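"""Ordered-subset EM reconstruction with A / AR / ARS compensation.

The multiplicative update per subset is

    x  <-  x * P_sub^T [ y / (P_sub x + s + eps) ] / P_sub^T 1

where P always models attenuation, additionally the distance-dependent
Gaussian collimator-detector response when the compensation combination is
AR or ARS, and s is the Monte-Carlo scatter estimate (ARS only).  Following
the emulated reconstruction engine, the scatter estimate is recomputed only
at the start of the first two full iterations and frozen afterwards, and it
enters the forward model term only (never the backprojection).  No
post-filtering is applied.

The module exposes both the functional `osem_reconstruct` and a
statsmodels-style pairing: :class:`SPECTReconstruction` (the model, built
from projections + attenuation map) whose ``fit()`` returns a
:class:`ReconstructionResult` carrying the image, data-fit diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .config import ProtocolConfig, PSFModel, ReconConfig, ScatterConfig
from .grids import VoxelGrid
from .projector import Projector
from .scatter import estimate_scatter
from .simulate import ProjectionSet

__all__ = ["make_subsets", "osem_reconstruct", "ActivityImage",
           "SPECTReconstruction", "ReconstructionResult"]


def make_subsets(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """Partition view indices into ordered OSEM subsets.

    Subset k holds views {k, k + n_subsets, ...}, i.e. maximally angularly
    separated views; subsets are processed in bit-reversed (van der Corput)
    order so successive subsets are far apart in angle.
    """
    if n_views % n_subsets:
        raise ValueError(f"{n_views} views not divisible into {n_subsets} subsets")

    def radical_inverse(k: int) -> float:
        inv, f = 0.0, 0.5
        while k:
            inv += f * (k & 1)
            k >>= 1
            f /= 2.0
        return inv

    order = np.argsort([radical_inverse(k) for k in range(n_subsets)], kind="stable")
    return [np.arange(k, n_views, n_subsets) for k in order]


@dataclass
class ActivityImage:
    """Reconstructed volume plus provenance (compensation, schedule, seeds)."""

    grid: VoxelGrid
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.grid.values < 0) or not np.all(np.isfinite(self.grid.values)):
            raise ValueError("reconstructed image must be non-negative and finite")

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def compensation(self) -> str | None:
        return self.provenance.get("compensation")


def osem_reconstruct(projections: ProjectionSet, mu: VoxelGrid,
                     protocol: ProtocolConfig, psf: PSFModel | None,
                     config: ReconConfig,
                     scatter_projections: np.ndarray | None = None,
                     track_loglikelihood: bool = False,
                     projector: Projector | None = None,
                     initial_image: np.ndarray | None = None) -> ActivityImage:
    """Run OSEM and return the reconstructed :class:`ActivityImage`.

    Parameters
    ----------
    scatter_projections : ndarray, optional
        Fixed scatter term in expected-counts units (matched-model mode);
        bypasses the Monte-Carlo engine.
    projector : Projector, optional
        Pre-built projector whose transmission/PSF caches are reused across
        reconstructions of the same geometry.
    """
    comp = config.compensation
    if projections.n_views != protocol.n_views:
        raise ValueError("projection set and protocol disagree on n_views")
    proj = projector or Projector(mu, protocol, psf if comp in ("AR", "ARS") else None)
    if proj.mu is None:
        raise ValueError("attenuation map required (all combinations include A)")
    if comp in ("AR", "ARS") and proj.psf is None:
        raise ValueError(f"compensation {comp} requires a PSF model")
    if comp == "A" and proj.psf is not None:
        raise ValueError("compensation A must use a PSF-free projector")

    y = np.asarray(projections.counts, dtype=np.float64)
    subsets = make_subsets(protocol.n_views, config.n_subsets)
    eps = config.epsilon

    # The reconstruction works in counts scale: the image is "reconstructed
    # counts per voxel" under the unit-scale projector, and the volumetric
    # sensitivity calibration later converts it to concentration (so camera
    # sensitivity and dwell cancel, as in a physical calibration).
    # Voxels that any subset barely sees (outside the rotated field of view,
    # where only wrap-around-level sensitivity leaks in) are frozen at zero
    # for the whole reconstruction; updating them would amplify without
    # bound.  The support is the intersection over subsets so no voxel is
    # zeroed mid-iteration.
    sens_all = [proj.sensitivity(views) for views in subsets]
    support = np.logical_and.reduce([s > 1e-2 * s.max() for s in sens_all])

    # Detector pixels fed only by frozen rim voxels can never be explained
    # by the model; a few stray (scatter/noise) counts there would otherwise
    # blow up the multiplicative ratio.  Exclude them from the data and,
    # consistently, from the sensitivity normalisation.
    fov = support.astype(np.float64)
    data_mask = np.stack([
        proj.forward(fov, v) > 1e-4 * proj.forward(fov, v).max()
        for v in range(protocol.n_views)
    ]).astype(np.float64)
    y = y * data_mask
    sens = [sum(proj.back(data_mask[v], v) for v in views) for views in subsets]

    n_vox = int(np.prod(mu.shape))
    if initial_image is None:
        x = np.full(mu.shape, y.sum() / n_vox)
    else:
        x = np.asarray(initial_image, dtype=np.float64).copy()
        if x.shape != mu.shape or np.any(x < 0):
            raise ValueError("initial_image must be a non-negative volume on the mu grid")
    x[~support] = 0.0

    s_counts = np.zeros_like(y)  # scatter term, expected-counts units
    if comp == "ARS" and scatter_projections is not None:
        s_counts = np.asarray(scatter_projections, dtype=np.float64)

    loglike: list[float] = []
    t0 = time.perf_counter()
    for it in range(1, config.n_iterations + 1):
        if (comp == "ARS" and scatter_projections is None
                and it in config.scatter_update_iterations):
            sc_cfg = config.scatter_config or ScatterConfig()
            sc_cfg = ScatterConfig(
                n_photons=sc_cfg.n_photons,
                downsample_factor=sc_cfg.downsample_factor,
                max_orders=sc_cfg.max_orders,
                rng_seed=sc_cfg.rng_seed + (it - 1),
                depth_bins=sc_cfg.depth_bins,
            )
            # x is linear in the data, so the scatter estimate computed from
            # it is automatically on the same counts scale as P x
            s_counts = estimate_scatter(VoxelGrid(x, mu.voxel_mm), mu, protocol,
                                        sc_cfg, psf=psf)

        for k, views in enumerate(subsets):
            acc = np.zeros_like(x)
            for v in views:
                fp = np.clip(proj.forward(x, v), 0.0, None)
                # The ratio is capped: a pixel holding a few counts the
                # current model cannot produce at all (stray scatter outside
                # the object once the air voxels have multiplicatively
                # collapsed) would otherwise inject an unbounded correction
                # through the far tails of the response kernel.  Well-fit
                # pixels sit far below the cap, so the converged image is
                # unaffected.
                ratio = np.minimum(
                    data_mask[v] * y[v] / (fp + s_counts[v] + eps), 1e3
                )
                acc += proj.back(ratio, v)
            upd = np.ones_like(x)
            # clip the tiny negative ringing of the band-limited blur so the
            # multiplicative update preserves non-negativity
            upd[support] = (np.clip(acc[support], 0.0, None)
                            / np.maximum(sens[k][support], 1e-12))
            x *= upd

        if track_loglikelihood:
            m = np.clip(proj.forward_views(x), 0.0, None) + s_counts
            loglike.append(float((y * np.log(m + 1e-300) - m).sum()))

    return ActivityImage(
        grid=VoxelGrid(np.clip(x, 0.0, None), mu.voxel_mm),
        provenance={
            "compensation": comp,
            "n_iterations": config.n_iterations,
            "n_subsets": config.n_subsets,
            "scatter_update_iterations": list(config.scatter_update_iterations),
            "matched_scatter": scatter_projections is not None,
            "data_seed": projections.rng_seed,
            "loglikelihood": loglike,
            "runtime_s": time.perf_counter() - t0,
        },
    )


# ---------------------------------------------------------------------------
# model / results presentation
# ---------------------------------------------------------------------------

class SPECTReconstruction:
    """OSEM reconstruction model: projection data + physics -> activity image.

    Examples
    --------
    >>> model = SPECTReconstruction(proj_set, mu, protocol, psf,
    ...                             ReconConfig(compensation="AR"))
    >>> res = model.fit()
    >>> res.image.values.shape
    (96, 96, 64)
    """

    def __init__(self, projections: ProjectionSet, mu: VoxelGrid,
                 protocol: ProtocolConfig, psf: PSFModel | None = None,
                 config: ReconConfig | None = None,
                 scatter_projections: np.ndarray | None = None,
                 projector: Projector | None = None):
        self.projections = projections
        self.mu = mu
        self.protocol = protocol
        self.psf = psf
        self.config = config or ReconConfig()
        self.scatter_projections = scatter_projections
        self.projector = projector

    def fit(self, track_loglikelihood: bool = False) -> "ReconstructionResult":
        image = osem_reconstruct(
            self.projections, self.mu, self.protocol, self.psf, self.config,
            scatter_projections=self.scatter_projections,
            track_loglikelihood=track_loglikelihood,
            projector=self.projector,
        )
        return ReconstructionResult(model=self, image=image)


@dataclass
class ReconstructionResult:
    model: SPECTReconstruction
    image: ActivityImage

    @property
    def loglikelihood_path(self) -> list[float]:
        return self.image.provenance.get("loglikelihood", [])

    def total_reconstructed(self) -> float:
        return float(self.image.values.sum())

    def summary(self) -> str:
        p = self.image.provenance
        lines = [
            "OSEM reconstruction result",
            "--------------------------",
            f"compensation        : {p['compensation']}",
            f"iterations x subsets: {p['n_iterations']} x {p['n_subsets']}",
            f"image shape         : {self.image.grid.shape}",
            f"voxel size (mm)     : {self.image.grid.voxel_mm}",
            f"total image value   : {self.total_reconstructed():.4g}",
            f"measured counts     : {self.model.projections.total_counts:.4g}",
            f"runtime (s)         : {p['runtime_s']:.1f}",
        ]
        if self.loglikelihood_path:
            lines.append(f"final log-likelihood: {self.loglikelihood_path[-1]:.6g}")
        return "\n".join(lines)
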