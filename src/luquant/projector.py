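"""Parallel-beam system model: attenuation + distance-dependent Gaussian PSF.

The forward model follows the rotation-based projector convention: for each
view the volume is resampled onto a frame whose +y axis points at the
detector, every voxel is weighted by its transmission exp(-integral mu dl)
to the collimator face (half-voxel offset, i.e. attenuation to the voxel
centre), every constant-depth plane is convolved with a Gaussian whose FWHM
grows linearly with plane-to-collimator distance, and planes are summed onto
the detector.

Two implementation choices make the back-projector an *exact* numerical
adjoint of the forward projector, which ordered-subset EM requires for stable
quantitation:

* in-plane rotation is a sparse matrix of bilinear-interpolation weights, and
  back-rotation applies its transpose;
* the per-plane blur is a circular convolution evaluated in frequency space
  with an analytically sampled Gaussian response, which is a symmetric
  operator (kernel real and even) with unit DC gain, so it conserves counts
  exactly and is its own adjoint.

Projection pixels are returned in MBq-equivalents: the attenuated, blurred
sum of (concentration x voxel volume) along each ray.  Expected detector
counts are ``dwell_s * sensitivity_cps_per_MBq`` times this.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .config import MuConversion, PSFModel, ProtocolConfig, psf_sigma_mm
from .grids import VoxelGrid

__all__ = ["hu_to_mu", "Projector", "forward_project", "back_project", "psf_sigma_mm"]


# ---------------------------------------------------------------------------
# HU -> mu
# ---------------------------------------------------------------------------

def hu_to_mu(hu, conv: MuConversion | None = None):
    """Bilinear, continuous HU -> linear attenuation coefficient (cm^-1).

    Anchored at air (mu(-1000 HU) = 0) and water (mu(0 HU) = mu_water);
    above the breakpoint a configurable bone-like slope applies.  Output is
    clamped at zero.
    """
    conv = conv or MuConversion()
    hu = np.asarray(hu, dtype=float)
    below = conv.mu_water_per_cm * (1.0 + hu / 1000.0)
    mu_at_break = conv.mu_water_per_cm * (1.0 + conv.hu_breakpoint / 1000.0)
    above = mu_at_break + conv.slope_above_per_cm_per_kHU * (hu - conv.hu_breakpoint) / 1000.0
    out = np.where(hu <= conv.hu_breakpoint, below, above)
    out = np.clip(out, 0.0, None)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# rotation operators
# ---------------------------------------------------------------------------

def _rotation_matrix(nx: int, ny: int, angle_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear resampling matrix for an in-plane rotation.

    Row p = ix*ny + iy of the output frame gathers from up to four input
    voxels; samples falling outside the grid contribute zero (the object is
    assumed inside the field of view).
    """
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    xc, yc = (nx - 1) / 2.0, (ny - 1) / 2.0
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx, dy = ix - xc, iy - yc
    xs = (c * dx - s * dy + xc).ravel()
    ys = (s * dx + c * dy + yc).ravel()

    x0 = np.floor(xs).astype(np.int64)
    y0 = np.floor(ys).astype(np.int64)
    wx = xs - x0
    wy = ys - y0

    rows, cols, vals = [], [], []
    row_idx = np.arange(nx * ny)
    for ox, weight_x in ((0, 1.0 - wx), (1, wx)):
        for oy, weight_y in ((0, 1.0 - wy), (1, wy)):
            xi, yi = x0 + ox, y0 + oy
            w = weight_x * weight_y
            ok = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny) & (w > 0)
            rows.append(row_idx[ok])
            cols.append((xi * ny + yi)[ok])
            vals.append(w[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    )
    return mat.tocsr()


class _RotationSet:
    """Lazily built per-view rotation matrices and their transposes."""

    def __init__(self, nx: int, ny: int, angles_deg):
        self.nx, self.ny = nx, ny
        self.angles_deg = np.asarray(angles_deg, dtype=float)
        self._fwd: dict[int, sparse.csr_matrix] = {}
        self._adj: dict[int, sparse.csr_matrix] = {}

    def forward(self, v: int) -> sparse.csr_matrix:
        if v not in self._fwd:
            self._fwd[v] = _rotation_matrix(self.nx, self.ny, self.angles_deg[v])
        return self._fwd[v]

    def adjoint(self, v: int) -> sparse.csr_matrix:
        if v not in self._adj:
            self._adj[v] = self.forward(v).T.tocsr()
        return self._adj[v]


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------

class Projector:
    """Matched forward/back-projection pair for one acquisition geometry.

    Parameters
    ----------
    mu : VoxelGrid or None
        Attenuation map (cm^-1).  None disables attenuation.
    protocol : ProtocolConfig
        Supplies view angles and per-view orbit radii.
    psf : PSFModel or None
        Distance-dependent Gaussian response.  None disables blurring.
    grid_like : VoxelGrid, optional
        Grid geometry when ``mu`` is None.

    Per-view transmission volumes and frequency-domain PSF kernels are cached
    on first use, so repeated projections (OSEM) pay the geometry cost once.
    """

    def __init__(self, mu: VoxelGrid | None, protocol: ProtocolConfig,
                 psf: PSFModel | None = None, grid_like: VoxelGrid | None = None,
                 rotations: _RotationSet | None = None):
        ref = mu if mu is not None else grid_like
        if ref is None:
            raise ValueError("need mu or grid_like to define the grid")
        self.shape = ref.shape
        self.voxel_mm = ref.voxel_mm
        self.mu = mu
        self.psf = psf
        self.protocol = protocol
        nx, ny, nz = self.shape
        self.angles_deg = protocol.angles_deg
        self.radii_cm = protocol.radii()
        self.rot = rotations or _RotationSet(nx, ny, self.angles_deg)
        self._T: dict[int, np.ndarray] = {}
        self._K: dict[int, np.ndarray] = {}
        self._fx2 = np.fft.fftfreq(nx)[:, None, None] ** 2
        self._fz2 = np.fft.rfftfreq(nz)[None, None, :] ** 2

    # -- helpers ------------------------------------------------------------
    @property
    def detector_shape(self) -> tuple[int, int]:
        return (self.shape[0], self.shape[2])

    @property
    def n_views(self) -> int:
        return len(self.angles_deg)

    def _rotate(self, vol: np.ndarray, v: int) -> np.ndarray:
        nx, ny, nz = self.shape
        return (self.rot.forward(v) @ vol.reshape(nx * ny, nz)).reshape(nx, ny, nz)

    def _rotate_adjoint(self, vol: np.ndarray, v: int) -> np.ndarray:
        nx, ny, nz = self.shape
        return (self.rot.adjoint(v) @ vol.reshape(nx * ny, nz)).reshape(nx, ny, nz)

    def _transmission(self, v: int) -> np.ndarray:
        if v not in self._T:
            mu_rot = self._rotate(np.ascontiguousarray(self.mu.values, dtype=np.float64), v)
            dl_cm = self.voxel_mm[1] / 10.0
            # cumulative attenuation from each voxel centre to the +y exit
            tail = np.cumsum(mu_rot[:, ::-1, :], axis=1)[:, ::-1, :]
            tau = dl_cm * (tail - 0.5 * mu_rot)
            self._T[v] = np.exp(-tau)
        return self._T[v]

    def plane_distances_cm(self, v: int) -> np.ndarray:
        """Distance of each constant-y plane to the collimator face (cm)."""
        ny = self.shape[1]
        y_world_cm = (np.arange(ny) - (ny - 1) / 2.0) * self.voxel_mm[1] / 10.0
        return np.clip(self.radii_cm[v] - y_world_cm, 0.0, None)

    def _kernel(self, v: int) -> np.ndarray:
        """Frequency response of the per-plane Gaussian blur, (nx, ny, nz//2+1)."""
        if v not in self._K:
            sigma_mm = psf_sigma_mm(self.plane_distances_cm(v), self.psf)
            sx = np.asarray(sigma_mm) / self.voxel_mm[0]
            sz = np.asarray(sigma_mm) / self.voxel_mm[2]
            expo = (sx[None, :, None] ** 2) * self._fx2 + (sz[None, :, None] ** 2) * self._fz2
            self._K[v] = np.exp(-2.0 * np.pi**2 * expo)
        return self._K[v]

    # -- forward / adjoint --------------------------------------------------
    def forward(self, activity: np.ndarray, v: int) -> np.ndarray:
        """Project one view; returns (nx, nz) pixels in MBq-equivalents."""
        nx, ny, nz = self.shape
        if activity.shape != self.shape:
            raise ValueError(f"activity shape {activity.shape} != grid {self.shape}")
        xr = self._rotate(np.asarray(activity, dtype=np.float64), v)
        if self.mu is not None:
            xr = xr * self._transmission(v)
        if self.psf is not None:
            F = np.fft.rfftn(xr, axes=(0, 2))
            proj = np.fft.irfft2((F * self._kernel(v)).sum(axis=1), s=(nx, nz))
        else:
            proj = xr.sum(axis=1)
        vvol = self.voxel_mm[0] * self.voxel_mm[1] * self.voxel_mm[2] / 1000.0
        return proj * vvol

    def back(self, projection: np.ndarray, v: int) -> np.ndarray:
        """Exact adjoint of :meth:`forward` for the same flags."""
        nx, ny, nz = self.shape
        if projection.shape != self.detector_shape:
            raise ValueError(
                f"projection shape {projection.shape} != detector {self.detector_shape}"
            )
        g = np.asarray(projection, dtype=np.float64)
        if self.psf is not None:
            G = np.fft.rfft2(g)
            F = G[:, None, :] * self._kernel(v)
            vol = np.fft.irfftn(F, s=(nx, nz), axes=(0, 2))
        else:
            vol = np.broadcast_to(g[:, None, :], self.shape).copy()
        if self.mu is not None:
            vol = vol * self._transmission(v)
        vvol = self.voxel_mm[0] * self.voxel_mm[1] * self.voxel_mm[2] / 1000.0
        return self._rotate_adjoint(vol, v) * vvol

    def forward_views(self, activity: np.ndarray, views=None) -> np.ndarray:
        views = range(self.n_views) if views is None else views
        return np.stack([self.forward(activity, v) for v in views])

    def sensitivity(self, views) -> np.ndarray:
        """Backprojection of unit projections over the given views (OSEM
        normalisation image); strictly positive inside the field of view."""
        ones = np.ones(self.detector_shape)
        out = np.zeros(self.shape)
        for v in views:
            out += self.back(ones, v)
        return out


# ---------------------------------------------------------------------------
# functional wrappers (one-shot API)
# ---------------------------------------------------------------------------

def forward_project(activity: VoxelGrid, mu: VoxelGrid | None, view_index: int,
                    protocol: ProtocolConfig, psf: PSFModel | None = None,
                    include_attenuation: bool = True, include_psf: bool = True) -> np.ndarray:
    if mu is not None:
        activity.require_congruent(mu, "activity/mu")
    proj = Projector(
        mu if include_attenuation and mu is not None else None,
        protocol,
        psf if include_psf else None,
        grid_like=activity,
    )
    return proj.forward(activity.values, view_index)


def back_project(projection: np.ndarray, mu: VoxelGrid | None, view_index: int,
                 protocol: ProtocolConfig, psf: PSFModel | None = None,
                 include_attenuation: bool = True, include_psf: bool = True,
                 grid_like: VoxelGrid | None = None) -> np.ndarray:
    proj = Projector(
        mu if include_attenuation and mu is not None else None,
        protocol,
        psf if include_psf else None,
        grid_like=grid_like if grid_like is not None else mu,
    )
    return proj.back(projection, view_index)
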