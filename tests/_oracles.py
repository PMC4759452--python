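"""Independent oracles used by the test suite.

These deliberately avoid the package's projector/scatter code paths: the
projector oracle is a per-voxel ray march along the detector axis, and the
scatter oracle is a dense analytic-geometry Monte Carlo (no forced detection,
no grids) for a point source centred in a water cylinder.
"""

from __future__ import annotations

import numpy as np

MU_WATER = 0.137
E0 = 208.0


def ray_march_axis0_view(activity, mu, voxel_mm, attenuate=True):
    """Brute-force parallel projection along +y (axis 1) with half-voxel
    attenuation convention; loops voxel by voxel."""
    nx, ny, nz = activity.shape
    dl_cm = voxel_mm / 10.0
    vvol = (voxel_mm ** 3) / 1000.0
    proj = np.zeros((nx, nz))
    for ix in range(nx):
        for iz in range(nz):
            total = 0.0
            for iy in range(ny):
                tau = 0.0
                if attenuate:
                    tau = 0.5 * mu[ix, iy, iz]
                    for j in range(iy + 1, ny):
                        tau += mu[ix, j, iz]
                    tau *= dl_cm
                total += activity[ix, iy, iz] * np.exp(-tau) * vvol
            proj[ix, iz] = total
    return proj


def _kn_shape(E, cost):
    k = E / 511.0
    r = 1.0 / (1.0 + k * (1.0 - cost))
    return r * r * (r + 1.0 / r - (1.0 - cost * cost))


def _sample_kn(rng, n, E=E0):
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        cost = rng.uniform(-1, 1, todo.size)
        u = rng.uniform(0, 2.0, todo.size)
        ok = u < _kn_shape(E, cost)
        out[todo[ok]] = cost[ok]
        todo = todo[~ok]
    return out


def _cylinder_exit(p, d, radius_cm, half_height_cm):
    """Distance from interior points p along unit directions d to the surface
    of a z-axis cylinder (analytic)."""
    px, py, pz = p[:, 0], p[:, 1], p[:, 2]
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    a = dx**2 + dy**2
    b = px * dx + py * dy
    c = px**2 + py**2 - radius_cm**2
    t_rad = np.full(len(p), np.inf)
    pos = a > 1e-12
    disc = np.sqrt(np.clip(b[pos] ** 2 - a[pos] * c[pos], 0.0, None))
    t_rad[pos] = (-b[pos] + disc) / a[pos]
    t_ax = np.full(len(p), np.inf)
    up = dz > 1e-12
    dn = dz < -1e-12
    t_ax[up] = (half_height_cm - pz[up]) / dz[up]
    t_ax[dn] = (-half_height_cm - pz[dn]) / dz[dn]
    return np.minimum(t_rad, t_ax)


def dense_mc_scatter_to_primary(n_photons, rng, radius_cm=10.0,
                                half_height_cm=10.0, mu=MU_WATER,
                                cone_deg=12.0, window=(187.2, 228.8)):
    """Scatter-to-primary ratio for a point source at the centre of a water
    cylinder, by acceptance-rejection detection into a cone around the +y
    axis.  First-order scatter only; no forced detection, no voxel grids.
    """
    d = rng.normal(size=(n_photons, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    origin = np.zeros((n_photons, 3))
    t_exit = _cylinder_exit(origin, d, radius_cm, half_height_cm)
    s = rng.exponential(1.0 / mu, n_photons)
    interacts = s < t_exit

    cos_cone = np.cos(np.deg2rad(cone_deg))
    axis = np.array([0.0, 1.0, 0.0])

    # primaries: no interaction and direction inside the acceptance cone
    primary = (~interacts) & (d @ axis >= cos_cone)
    n_primary = int(primary.sum())

    # single scatter
    p_int = origin[interacts] + s[interacts, None] * d[interacts]
    d_in = d[interacts]
    cost = _sample_kn(rng, len(p_int))
    phi = rng.uniform(0, 2 * np.pi, len(p_int))
    sint = np.sqrt(np.clip(1 - cost**2, 0, None))
    ref = np.where(np.abs(d_in[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(d_in, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d_in, e1)
    d_out = (cost[:, None] * d_in
             + sint[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2))
    E_out = E0 / (1.0 + (E0 / 511.0) * (1.0 - cost))
    in_cone = d_out @ axis >= cos_cone
    in_window = (E_out >= window[0]) & (E_out <= window[1])
    t2 = _cylinder_exit(p_int, d_out, radius_cm, half_height_cm)
    escapes = rng.exponential(1.0 / mu, len(p_int)) >= t2
    n_scatter = int((in_cone & in_window & escapes).sum())

    if n_primary == 0:
        raise RuntimeError("no primary photons detected; increase n_photons")
    return n_scatter / n_primary
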