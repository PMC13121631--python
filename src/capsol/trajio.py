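"""Trajectory and table IO.

Extended-XYZ is the canonical trajectory dialect: the comment line carries a
``Lattice="L 0 0 0 L 0 0 0 L"`` cubic cell, the per-frame iteration index and
temperature, and the per-site columns are atom-type label, Cartesian
coordinates, molecule index and molecule species — enough to reconstruct the
molecular topology on read.  PDB (with a CRYST1 cubic cell) is supported
read-only through gemmi for interoperability.  All writes are atomic
(temp-then-rename).
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from typing import Iterable

import gemmi
import numpy as np
import pandas as pd

from .forcefield import Configuration, Trajectory
from .structure import RDFResult, VolumetricMap


class TrajectoryFormatError(ValueError):
    """A trajectory file is unparsable, truncated, or missing box metadata."""


def _atomic_write(path: str, write_fn) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            write_fn(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_xyz(traj: Trajectory | Configuration, path: str) -> None:
    """Write frames as extended XYZ with cubic lattice metadata."""
    if isinstance(traj, Configuration):
        traj = Trajectory(frames=[traj], iteration_index=[0])

    def emit(fh) -> None:
        for frame, it in zip(traj.frames, traj.iteration_index):
            L = frame.box_length
            fh.write(f"{frame.n_sites}\n")
            fh.write(
                f'Lattice="{L:.8f} 0 0 0 {L:.8f} 0 0 0 {L:.8f}" '
                'Properties=species:S:1:pos:R:3:mol:I:1:resname:S:1 '
                f"iteration={it} temperature={frame.temperature:.4f}\n"
            )
            for lab, (x, y, z), m in zip(
                frame.site_labels, frame.coords, frame.mol_index
            ):
                fh.write(
                    f"{lab} {x:.10f} {y:.10f} {z:.10f} "
                    f"{int(m)} {frame.species[int(m)]}\n"
                )

    _atomic_write(path, emit)


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_KV_RE = re.compile(r"(\w+)=([^\s\"]+)")


def _read_xyz(path: str) -> Trajectory:
    frames: list[Configuration] = []
    iters: list[int] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    k = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as err:
            raise TrajectoryFormatError(
                f"frame {k}: expected an atom count at line {pos + 1}"
            ) from err
        if pos + 1 + n >= len(lines) + 1 and pos + 1 + n > len(lines):
            raise TrajectoryFormatError(f"frame {k}: truncated ({n} sites expected)")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        m_lat = _LATTICE_RE.search(comment)
        if not m_lat:
            raise TrajectoryFormatError(f"frame {k}: no Lattice box metadata")
        lat = [float(v) for v in m_lat.group(1).split()]
        if len(lat) != 9 or not (
            lat[0] == lat[4] == lat[8] and all(abs(lat[i]) < 1e-9 for i in (1, 2, 3, 5, 6, 7))
        ):
            raise TrajectoryFormatError(f"frame {k}: only cubic lattices supported")
        kv = dict(_KV_RE.findall(comment))
        iteration = int(kv.get("iteration", k))
        temperature = float(kv.get("temperature", 298.15))

        body = lines[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise TrajectoryFormatError(f"frame {k}: truncated ({n} sites expected)")
        labels, coords, mols, resnames = [], [], [], []
        for ln, row in enumerate(body):
            parts = row.split()
            if len(parts) < 6:
                raise TrajectoryFormatError(
                    f"frame {k}: malformed site line {pos + 3 + ln}"
                )
            labels.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            mols.append(int(parts[4]))
            resnames.append(parts[5])
        mols = np.asarray(mols, dtype=np.intp)
        species, mol_start = _species_from_site_mols(mols, resnames, k)
        frames.append(
            Configuration(
                box_length=lat[0], temperature=temperature, species=species,
                site_labels=np.array(labels), coords=np.array(coords),
                mol_start=mol_start,
            )
        )
        iters.append(iteration)
        pos += 2 + n
        k += 1
    if not frames:
        raise TrajectoryFormatError("no frames found")
    return _validated(frames, iters)


def _species_from_site_mols(
    mols: np.ndarray, resnames: list[str], frame_no: int
) -> tuple[list[str], np.ndarray]:
    if np.any(np.diff(mols) < 0):
        raise TrajectoryFormatError(
            f"frame {frame_no}: molecule indices must be non-decreasing"
        )
    boundaries = np.flatnonzero(np.diff(mols)) + 1
    starts = np.concatenate([[0], boundaries, [mols.size]]).astype(np.intp)
    species = [resnames[s] for s in starts[:-1]]
    return species, starts


def _read_pdb(path: str) -> Trajectory:
    st = gemmi.read_structure(path)
    cell = st.cell
    if not (
        abs(cell.a - cell.b) < 1e-6 and abs(cell.a - cell.c) < 1e-6
        and abs(cell.alpha - 90) < 1e-6 and abs(cell.beta - 90) < 1e-6
        and abs(cell.gamma - 90) < 1e-6 and cell.a > 1e-6
    ):
        raise TrajectoryFormatError("PDB lacks a cubic CRYST1 cell")
    frames = []
    for model in st:
        molecules = []
        for chain in model:
            for res in chain:
                labels = [atom.name for atom in res]
                coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
                molecules.append((res.name, labels, coords))
        if not molecules:
            raise TrajectoryFormatError("PDB model contains no atoms")
        frames.append(
            Configuration.from_molecules(cell.a, 298.15, molecules)
        )
    if not frames:
        raise TrajectoryFormatError("PDB contains no models")
    return _validated(frames, list(range(len(frames))))


def _validated(frames: list[Configuration], iters: list[int]) -> Trajectory:
    ref = frames[0]
    for k, fr in enumerate(frames[1:], start=1):
        if fr.species != ref.species or abs(fr.box_length - ref.box_length) > 1e-9:
            raise TrajectoryFormatError(
                f"frame {k}: composition or box differs from frame 0"
            )
    return Trajectory(frames=frames, iteration_index=iters)


def read_trajectory(path: str, format: str | None = None) -> Trajectory:
    """Read an extended-XYZ or PDB trajectory; format inferred from suffix."""
    fmt = format or ("pdb" if path.lower().endswith(".pdb") else "xyz")
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# analysis tables and grids
# ---------------------------------------------------------------------------

def write_rdf_csv(rdf: RDFResult, path: str) -> None:
    """r, g and the running coordination integral as CSV."""
    r = rdf.r_mid
    n_cum = np.cumsum(
        4.0 * np.pi * rdf.rho_beta * r ** 2 * rdf.g * rdf.bin_width
    )
    df = pd.DataFrame({"r": r, "g": rdf.g, "N_cumulative": n_cum})
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False))


def write_energy_csv(dist, path: str) -> None:
    df = pd.DataFrame({"E_bin_center": dist.bin_centers, "count": dist.counts})
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False))


def write_dx(vmap: VolumetricMap, path: str) -> None:
    """OpenDX scalar grid, readable by standard visualisation tools."""
    n = vmap.density.shape[0]
    origin = -vmap.extent + 0.5 * vmap.voxel

    def emit(fh) -> None:
        fh.write(f"object 1 class gridpositions counts {n} {n} {n}\n")
        fh.write(f"origin {origin:.6f} {origin:.6f} {origin:.6f}\n")
        fh.write(f"delta {vmap.voxel:.6f} 0 0\n")
        fh.write(f"delta 0 {vmap.voxel:.6f} 0\n")
        fh.write(f"delta 0 0 {vmap.voxel:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {n} {n} {n}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {n ** 3} data follows\n"
        )
        flat = vmap.density.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.8e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')

    _atomic_write(path, emit)


def write_manifest(path: str, **entries) -> None:
    """Machine-readable run manifest (inputs, seeds, settings, versions)."""
    from . import __version__

    doc = {"capsol_version": __version__, **entries}
    _atomic_write(path, lambda fh: json.dump(doc, fh, indent=2, default=str))
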