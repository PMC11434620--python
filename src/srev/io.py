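"""Plain-text and TIFF I/O for walks, chains, curves and domain tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .excluded_volume import BeadChain, bond_lengths
from .genome import GenomicMap
from .params import GenerationParams
from .polymer import PowerLawFit, ScalingCurve
from .density import RadialProfile
from .tomogram import DensityVolume, DomainRecord
from .walk import RawWalk

__all__ = [
    "write_walk_xyz", "read_walk_xyz",
    "write_chain", "read_chain",
    "write_curve", "write_fit", "write_profile",
    "write_domains",
    "write_volume_tiff", "read_volume_tiff",
]

_STEP_NAMES = {0: "jump", 1: "return"}
_STEP_CODES = {"jump": 0, "return": 1}


# ---------------------------------------------------------------------------
# RawWalk: extended XYZ + JSON parameter sidecar
# ---------------------------------------------------------------------------

def write_walk_xyz(walk: RawWalk, path) -> None:
    """Extended XYZ (x y z step_type step_length_units per vertex).

    The first vertex has no incoming step and is written as ``origin 0``.
    A ``<path>.json`` sidecar holds the generation parameters.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{walk.n_beads}\n")
        fh.write("srev RawWalk: x y z step_type step_length_units\n")
        fh.write("{:.6f} {:.6f} {:.6f} origin 0\n".format(*walk.vertices[0]))
        for v, t, u in zip(walk.vertices[1:], walk.step_types,
                           walk.step_lengths):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} "
                     f"{_STEP_NAMES[int(t)]} {u:.9f}\n")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(walk.params.to_dict(), fh, indent=1)


def read_walk_xyz(path) -> RawWalk:
    path = Path(path)
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        verts = np.empty((n, 3))
        types = np.empty(n - 1, dtype=np.int8)
        lens = np.empty(n - 1)
        for i in range(n):
            x, y, z, t, u = fh.readline().split()
            verts[i] = (float(x), float(y), float(z))
            if i > 0:
                types[i - 1] = _STEP_CODES[t]
                lens[i - 1] = float(u)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        params = GenerationParams.from_dict(json.load(fh))
    return RawWalk(vertices=verts, step_types=types, step_lengths=lens,
                   params=params)


# ---------------------------------------------------------------------------
# BeadChain: extended XYZ + TSV bond table
# ---------------------------------------------------------------------------

def write_chain(chain: BeadChain, path, gmap: GenomicMap | None = None) -> None:
    """Bead coordinates as extended XYZ plus a ``<path>.bonds.tsv`` table.

    The bond table holds (i, j, rest_length_nm, length_nm) and, when a
    genomic map is supplied, the linker_bp column; a JSON sidecar records
    the bead radius, relaxed flag and generation parameters.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{chain.n_beads}\n")
        fh.write("srev BeadChain: x y z bead_index origin_vertex\n")
        for i, p in enumerate(chain.positions):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {i} "
                     f"{int(chain.origin_vertex[i])}\n")
    table = {
        "i": np.arange(chain.n_beads - 1),
        "j": np.arange(1, chain.n_beads),
        "rest_length_nm": chain.bond_rest_lengths,
        "length_nm": bond_lengths(chain),
    }
    if gmap is not None:
        table["linker_bp"] = gmap.linker_bp
    pd.DataFrame(table).to_csv(path.with_suffix(path.suffix + ".bonds.tsv"),
                               sep="\t", index=False)
    meta = {"bead_radius": chain.bead_radius, "relaxed": chain.relaxed,
            "params": chain.params.to_dict() if chain.params else None}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_chain(path) -> BeadChain:
    path = Path(path)
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        pos = np.empty((n, 3))
        origin = np.empty(n, dtype=np.int64)
        for i in range(n):
            x, y, z, _, ov = fh.readline().split()
            pos[i] = (float(x), float(y), float(z))
            origin[i] = int(ov)
    bonds = pd.read_csv(path.with_suffix(path.suffix + ".bonds.tsv"), sep="\t")
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    params = (GenerationParams.from_dict(meta["params"])
              if meta.get("params") else None)
    return BeadChain(positions=pos,
                     bead_radius=meta["bead_radius"],
                     bond_rest_lengths=bonds["rest_length_nm"].to_numpy(),
                     origin_vertex=origin, params=params,
                     relaxed=meta["relaxed"])


# ---------------------------------------------------------------------------
# curves, profiles, fits, domain tables
# ---------------------------------------------------------------------------

def write_curve(curve: ScalingCurve, path) -> None:
    pd.DataFrame({"n_bp": curve.n_bp, "value": curve.values,
                  "count": curve.counts}).to_csv(path, sep="\t", index=False)


def write_fit(fit: PowerLawFit, path) -> None:
    with open(path, "w") as fh:
        json.dump({"exponent": fit.exponent, "intercept": fit.intercept,
                   "r_squared": fit.r_squared, "n_range": list(fit.n_range),
                   "n_bins": fit.n_bins}, fh, indent=1)


def write_profile(profile: RadialProfile, path) -> None:
    pd.DataFrame({"r_nm": profile.r, "g": profile.g,
                  "G_nm3": profile.G}).to_csv(path, sep="\t", index=False)


def write_domains(records: list[DomainRecord], path) -> None:
    rows = [{"center": ",".join(str(c) for c in r.center_px),
             "radius_px": r.radius_px, "radius_nm": r.radius_nm,
             "criterion": r.stop_criterion, "local_D": r.local_D,
             "mode": r.mode} for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# density volumes
# ---------------------------------------------------------------------------

def write_volume_tiff(volume: DensityVolume, path) -> None:
    """One TIFF page per z-slice; physical metadata in the description."""
    stack = np.moveaxis(volume.data, 2, 0).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={
        "voxel_size_nm": volume.voxel_size,
        "origin_nm": list(map(float, volume.origin)),
        "deposition_sigma_nm": volume.deposition_sigma,
    })


def read_volume_tiff(path) -> DensityVolume:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    data = np.moveaxis(stack, 0, 2).astype(float)
    return DensityVolume(data=data,
                         voxel_size=float(meta.get("voxel_size_nm", 1.0)),
                         origin=np.asarray(meta.get("origin_nm", [0, 0, 0]),
                                           dtype=float),
                         deposition_sigma=float(
                             meta.get("deposition_sigma_nm", 0.0)))
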