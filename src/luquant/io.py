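"""File formats: NIfTI volumes and Interfile-style projection sets.

Volumes (activity, attenuation, masks, reconstructions) round-trip through
NIfTI-1 via nibabel with the voxel size carried in the affine.  Projection
sets use the nuclear-medicine convention of a small self-describing text
header next to a raw little-endian float32 binary (``.hdr`` + ``.img``), plus
an NPZ convenience form.
"""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np

from .grids import VoxelGrid
from .simulate import ProjectionSet

__all__ = ["write_volume", "read_volume", "write_projections", "read_projections",
           "write_projections_npz", "read_projections_npz"]


def write_volume(path, grid: VoxelGrid):
    """Write a VoxelGrid as NIfTI-1 (float32 data, voxel size in the affine)."""
    affine = np.diag([*grid.voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine)
    img.header.set_zooms(grid.voxel_mm)
    nib.save(img, os.fspath(path))


def read_volume(path) -> VoxelGrid:
    try:
        img = nib.load(os.fspath(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # nibabel raises several distinct parse errors
        raise IOError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise IOError(f"{path!r}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return VoxelGrid(data, tuple(float(z) for z in zooms))


# ---------------------------------------------------------------------------
# Interfile-style projection data
# ---------------------------------------------------------------------------

_HDR_MAGIC = "!INTERFILE-STYLE PROJECTIONS :="


def write_projections(path_base, proj: ProjectionSet):
    """Write ``<base>.hdr`` (text header) + ``<base>.img`` (raw LE float32)."""
    base = os.fspath(path_base)
    counts = np.ascontiguousarray(proj.counts, dtype="<f4")
    nv, nu, nzd = counts.shape
    lines = [
        _HDR_MAGIC,
        f"number of projections := {nv}",
        f"matrix size [1] := {nu}",
        f"matrix size [2] := {nzd}",
        f"scaling factor (mm/pixel) := {proj.pixel_mm}",
        f"image duration (sec) := {proj.dwell_s}",
        "number format := float",
        "number of bytes per pixel := 4",
        "imagedata byte order := LITTLEENDIAN",
        f"rng seed := {proj.rng_seed if proj.rng_seed is not None else 'none'}",
        "projection angles (deg) := " + " ".join(f"{a:.6f}" for a in proj.angles_deg),
        "orbit radii (cm) := " + " ".join(f"{r:.6f}" for r in proj.radii_cm),
        f"name of data file := {os.path.basename(base)}.img",
        "!END OF INTERFILE :=",
    ]
    with open(base + ".hdr", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    counts.tofile(base + ".img")


def read_projections(path_base) -> ProjectionSet:
    base = os.fspath(path_base)
    if base.endswith(".hdr"):
        base = base[:-4]
    fields = {}
    with open(base + ".hdr") as fh:
        first = fh.readline().strip()
        if first != _HDR_MAGIC:
            raise IOError(f"{base}.hdr: not an Interfile-style projection header "
                          f"(first line {first!r})")
        for line in fh:
            if ":=" not in line:
                continue
            key, _, val = line.partition(":=")
            fields[key.strip().lstrip("!")] = val.strip()

    try:
        nv = int(fields["number of projections"])
        nu = int(fields["matrix size [1]"])
        nzd = int(fields["matrix size [2]"])
        pixel_mm = float(fields["scaling factor (mm/pixel)"])
        dwell = float(fields["image duration (sec)"])
        angles = np.array(fields["projection angles (deg)"].split(), dtype=float)
        radii = np.array(fields["orbit radii (cm)"].split(), dtype=float)
    except (KeyError, ValueError) as exc:
        raise IOError(f"{base}.hdr: malformed header field: {exc}") from exc
    if fields.get("imagedata byte order", "LITTLEENDIAN") != "LITTLEENDIAN":
        raise IOError(f"{base}.hdr: unsupported byte order "
                      f"{fields['imagedata byte order']!r}")

    raw = np.fromfile(base + ".img", dtype="<f4")
    if raw.size != nv * nu * nzd:
        raise IOError(
            f"{base}.img: data size {raw.size} does not match header "
            f"{nv}x{nu}x{nzd} = {nv * nu * nzd}"
        )
    seed_s = fields.get("rng seed", "none")
    return ProjectionSet(
        counts=raw.reshape(nv, nu, nzd).astype(np.float64),
        angles_deg=angles,
        radii_cm=radii,
        dwell_s=dwell,
        pixel_mm=pixel_mm,
        rng_seed=None if seed_s == "none" else int(seed_s),
    )


def write_projections_npz(path, proj: ProjectionSet):
    np.savez_compressed(
        os.fspath(path),
        counts=proj.counts, angles_deg=proj.angles_deg, radii_cm=proj.radii_cm,
        dwell_s=proj.dwell_s, pixel_mm=proj.pixel_mm,
        rng_seed=-1 if proj.rng_seed is None else proj.rng_seed,
        meta=json.dumps(proj.meta),
    )


def read_projections_npz(path) -> ProjectionSet:
    with np.load(os.fspath(path), allow_pickle=False) as z:
        seed = int(z["rng_seed"])
        return ProjectionSet(
            counts=z["counts"], angles_deg=z["angles_deg"], radii_cm=z["radii_cm"],
            dwell_s=float(z["dwell_s"]), pixel_mm=float(z["pixel_mm"]),
            rng_seed=None if seed < 0 else seed,
            meta=json.loads(str(z["meta"])),
        )
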