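"""Readers and writers: trajectories, grouping files, grids, tables, fixtures.

Extended-XYZ is the canonical interchange format (human readable, carries the
periodic cell on the comment line); PDB is supported read-only for
multi-MODEL structure files with a CRYST1 record.  Volumetric water-occupancy
grids are written as Gaussian cube or OpenDX.  The packaged reference tables
(experimental/simulated radii, diffusion coefficients and hydration numbers)
are shipped as CSV and guarded by checksums so silent edits are caught.

All readers reject malformed records with the offending line number rather
than guessing.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SystemMap, Trajectory, TrajectoryFrame

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_system_map",
    "write_system_map",
    "write_grid",
    "read_grid",
    "load_fixture",
    "write_table",
]

_BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class FormatError(ValueError):
    """A file did not conform to its declared format."""


# ---------------------------------------------------------------------------
# extended XYZ


def _parse_extxyz_comment(comment: str, lineno: int) -> tuple[np.ndarray, float | None]:
    """Extract box lengths (and optional time, ps) from an extended-XYZ comment.

    Accepts either ``Lattice="ax ay az bx by bz cx cy cz"`` (must be diagonal,
    i.e. orthorhombic) or a plain ``box a b c`` token triple.  A ``Time=``
    or ``time=`` key is read if present.
    """
    time = None
    m = re.search(r'[Tt]ime=([-+0-9.eE]+)', comment)
    if m:
        time = float(m.group(1))
    m = re.search(r'Lattice="([^"]+)"', comment)
    if m:
        vals = [float(x) for x in m.group(1).split()]
        if len(vals) != 9:
            raise FormatError(f"line {lineno}: Lattice needs 9 components, got {len(vals)}")
        cell = np.array(vals).reshape(3, 3)
        off = cell - np.diag(np.diag(cell))
        if np.any(np.abs(off) > 1e-8):
            raise FormatError(
                f"line {lineno}: non-orthorhombic Lattice is unsupported"
            )
        return np.diag(cell).astype(float), time
    m = re.search(r'box\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)', comment)
    if m:
        return np.array([float(m.group(i)) for i in (1, 2, 3)]), time
    raise FormatError(f'line {lineno}: no box record (Lattice="..." or "box a b c") in comment')


def _read_extxyz(path: Path, frame_interval: float | None) -> Trajectory:
    frames: list[TrajectoryFrame] = []
    names: list[str] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_total = len(lines)
    while i < n_total:
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 + n_atoms >= n_total + 0 and i + 1 >= n_total:
            raise FormatError(f"{path}: line {i + 1}: truncated frame header")
        box, time = _parse_extxyz_comment(lines[i + 1], i + 2)
        coords = np.empty((n_atoms, 3))
        frame_names = []
        for j in range(n_atoms):
            k = i + 2 + j
            if k >= n_total:
                raise FormatError(f"{path}: line {k + 1}: truncated frame (expected {n_atoms} atoms)")
            parts = lines[k].split()
            if len(parts) < 4:
                raise FormatError(f"{path}: line {k + 1}: expected 'name x y z', got {lines[k]!r}")
            frame_names.append(parts[0])
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise FormatError(f"{path}: line {k + 1}: unparseable coordinates")
        if names is None:
            names = frame_names
        elif len(frame_names) != len(names):
            raise FormatError(f"{path}: line {i + 1}: atom count changed between frames")
        if time is None:
            dt = frame_interval if frame_interval is not None else 10.0
            time = len(frames) * dt
        frames.append(TrajectoryFrame(time=time, box_lengths=box, coords=coords))
        i += 2 + n_atoms
    if not frames:
        raise FormatError(f"{path}: no frames found")
    if frame_interval is None:
        if len(frames) > 1:
            frame_interval = frames[1].time - frames[0].time
        else:
            frame_interval = 10.0
    return Trajectory(frames, frame_interval=frame_interval)


def write_trajectory(traj: Trajectory, path: str | Path, names: list[str] | None = None) -> None:
    """Write a trajectory as extended XYZ (Lattice + Time on the comment line)."""
    path = Path(path)
    n = traj.n_atoms
    if names is None:
        names = ["X"] * n
    with open(path, "w") as fh:
        for f in traj.frames:
            a, b, c = f.box_lengths
            fh.write(f"{n}\n")
            fh.write(
                f'Lattice="{a:.6f} 0 0 0 {b:.6f} 0 0 0 {c:.6f}" '
                f"Properties=species:S:1:pos:R:3 Time={f.time:.6f}\n"
            )
            for nm, (x, y, z) in zip(names, f.coords):
                fh.write(f"{nm} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# PDB (read-only)


def _read_pdb(path: Path, frame_interval: float | None) -> Trajectory:
    box = None
    frames: list[np.ndarray] = []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "CRYST1":
                try:
                    a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                    alpha, beta, gamma = (
                        float(line[33:40]),
                        float(line[40:47]),
                        float(line[47:54]),
                    )
                except ValueError:
                    raise FormatError(f"{path}: line {lineno}: unparseable CRYST1 record")
                if not (abs(alpha - 90) < 1e-6 and abs(beta - 90) < 1e-6 and abs(gamma - 90) < 1e-6):
                    raise FormatError(
                        f"{path}: line {lineno}: triclinic cells are unsupported"
                    )
                box = np.array([a, b, c])
            elif rec == "MODEL":
                if current:
                    frames.append(np.array(current))
                current = []
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = []
                try:
                    current.append(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    )
                except ValueError:
                    raise FormatError(f"{path}: line {lineno}: unparseable coordinates")
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(np.array(current))
                    current = None
    if current:
        frames.append(np.array(current))
    if box is None:
        raise FormatError(f"{path}: missing CRYST1 box record")
    if not frames:
        raise FormatError(f"{path}: no coordinates found")
    n = frames[0].shape[0]
    for k, f in enumerate(frames):
        if f.shape[0] != n:
            raise FormatError(f"{path}: model {k + 1} has {f.shape[0]} atoms, expected {n}")
    dt = frame_interval if frame_interval is not None else 10.0
    return Trajectory(
        [TrajectoryFrame(time=k * dt, box_lengths=box.copy(), coords=f) for k, f in enumerate(frames)],
        frame_interval=dt,
    )


def read_trajectory(
    path: str | Path, format_hint: str | None = None, frame_interval: float | None = None
) -> Trajectory:
    """Read a trajectory from extended-XYZ (``xyz``/``extxyz``) or PDB.

    ``format_hint`` overrides suffix detection; ``frame_interval`` (ps)
    overrides / supplies the frame spacing when time stamps are absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt in ("xyz", "extxyz"):
        return _read_extxyz(path, frame_interval)
    if fmt == "pdb":
        return _read_pdb(path, frame_interval)
    raise FormatError(f"unsupported trajectory format {fmt!r} (use extxyz or pdb)")


# ---------------------------------------------------------------------------
# grouping files


def read_system_map(path: str | Path) -> SystemMap:
    """Read a grouping file: one ``SOLUTE``/plain line of 0-based atom indices
    per solute copy, one ``WATER_O`` line, optional ``MASSES`` line (amu).

    Example::

        SOLUTE 0 1 2
        SOLUTE 3 4 5
        WATER_O 6 7 8 9
        MASSES 12.0 16.0 1.0 ...
    """
    path = Path(path)
    groups: list[list[int]] = []
    water: list[int] = []
    masses: list[float] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0].upper()
            try:
                if tag == "WATER_O":
                    water = [int(x) for x in parts[1:]]
                elif tag == "MASSES":
                    masses = [float(x) for x in parts[1:]]
                elif tag == "SOLUTE":
                    groups.append([int(x) for x in parts[1:]])
                else:
                    groups.append([int(x) for x in parts])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: unparseable index list")
    if not groups:
        raise FormatError(f"{path}: no solute groups found")
    n_atoms = 1 + max(
        [max(g) for g in groups if g] + ([max(water)] if water else [0])
    )
    if masses is None:
        masses = [1.0] * n_atoms
    return SystemMap(
        solute_groups=[np.array(g) for g in groups],
        water_oxygen_indices=np.array(water, dtype=np.intp),
        masses=np.array(masses),
    )


def write_system_map(system_map: SystemMap, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# glycodiff grouping file (0-based atom indices)\n")
        for g in system_map.solute_groups:
            fh.write("SOLUTE " + " ".join(str(i) for i in g) + "\n")
        fh.write("WATER_O " + " ".join(str(i) for i in system_map.water_oxygen_indices) + "\n")
        fh.write("MASSES " + " ".join(f"{m:g}" for m in system_map.masses) + "\n")


# ---------------------------------------------------------------------------
# volumetric grids


def write_grid(grid, path: str | Path, format: str = "cube") -> None:
    """Write an occupancy grid (see :class:`glycodiff.solvation.OccupancyGrid`)
    as Gaussian cube or OpenDX.

    Cube files store the origin/spacing in Bohr per the format convention;
    values are voxel densities.  OpenDX output goes through gridDataFormats.
    """
    path = Path(path)
    fmt = format.lower()
    dims = grid.values.shape
    if any(d <= 0 for d in dims):
        raise ValueError("grid dims must be > 0")
    if fmt == "cube":
        ox, oy, oz = np.asarray(grid.origin) * _BOHR_PER_ANGSTROM
        s = grid.spacing * _BOHR_PER_ANGSTROM
        with open(path, "w") as fh:
            fh.write("glycodiff water-occupancy grid\n")
            fh.write("density per voxel (A^-3)\n")
            # one dummy atom: cube requires >= 1 atom record
            fh.write(f"{1:5d}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
            fh.write(f"{dims[0]:5d}{s:12.6f}{0.0:12.6f}{0.0:12.6f}\n")
            fh.write(f"{dims[1]:5d}{0.0:12.6f}{s:12.6f}{0.0:12.6f}\n")
            fh.write(f"{dims[2]:5d}{0.0:12.6f}{0.0:12.6f}{s:12.6f}\n")
            fh.write(f"{1:5d}{0.0:12.6f}{ox:12.6f}{oy:12.6f}{oz:12.6f}\n")
            flat = grid.values.reshape(dims[0] * dims[1], dims[2])
            for row in flat:
                for start in range(0, dims[2], 6):
                    chunk = row[start : start + 6]
                    fh.write("".join(f"{v:13.5E}" for v in chunk) + "\n")
    elif fmt in ("dx", "opendx"):
        from gridData import Grid

        g = Grid(
            grid.values,
            origin=np.asarray(grid.origin, dtype=float),
            delta=[grid.spacing] * 3,
        )
        g.export(str(path), file_format="dx")
    else:
        raise ValueError(f"unsupported grid format {format!r} (use 'cube' or 'dx')")


def read_grid(path: str | Path):
    """Read back a grid written by :func:`write_grid` (cube or dx).

    Returns an object with ``origin``, ``spacing`` and ``values`` attributes.
    """
    from .solvation import OccupancyGrid

    path = Path(path)
    if path.suffix == ".cube":
        with open(path) as fh:
            lines = fh.readlines()
        natoms = int(lines[2].split()[0])
        origin = np.array([float(x) for x in lines[2].split()[1:4]]) / _BOHR_PER_ANGSTROM
        nx = int(lines[3].split()[0])
        ny = int(lines[4].split()[0])
        nz = int(lines[5].split()[0])
        spacing = float(lines[3].split()[1]) / _BOHR_PER_ANGSTROM
        data: list[float] = []
        for line in lines[6 + natoms:]:
            data.extend(float(x) for x in line.split())
        values = np.array(data).reshape(nx, ny, nz)
        return OccupancyGrid(origin=origin, spacing=spacing, values=values)
    if path.suffix == ".dx":
        from gridData import Grid

        g = Grid(str(path))
        return OccupancyGrid(
            origin=np.asarray(g.origin, dtype=float),
            spacing=float(g.delta[0]),
            values=np.asarray(g.grid),
        )
    raise ValueError(f"unsupported grid file {path.name!r}")


# ---------------------------------------------------------------------------
# packaged fixture tables

_FIXTURE_FILES = {
    "radii": "radii.csv",
    "diffusion": "diffusion.csv",
    "hydration": "hydration.csv",
    "polar_atoms": "polar_atoms.csv",
}

_FIXTURE_SHA256 = {
    "diffusion": "457b77a48036236986a529a88c313a62fad339b748f5e3aa83bacab8a5b60dc1",
    "hydration": "a02c381a81eebec2e8e52788585ec40864440c6df12d43daa80a8deda0b1f9ee",
    "polar_atoms": "91ee44ff2ee745f2349ebfb05794d94cf44d505a3ea5017ae702efc8e444ae61",
    "radii": "1ad03db1e9996770921a151e050d516aa3286450af45ad77977bbf2884eb2124",
}

_FIXTURE_NROWS = {"radii": 18, "diffusion": 18, "hydration": 10, "polar_atoms": 18}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table as a DataFrame indexed by carbohydrate.

    ``name`` is one of ``radii`` (R_H / R_g, Angstrom), ``diffusion``
    (D, 1e-9 m^2/s), ``hydration`` (n_H, N_W, N_PA and ratios) or
    ``polar_atoms`` (polar-group bookkeeping).  Files are checksummed;
    a mismatch raises rather than silently serving edited values.
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}")
    ref = resources.files("glycodiff.data") / _FIXTURE_FILES[name]
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(
            f"fixture {name!r} failed its checksum ({digest[:12]}...); "
            "the packaged table has been modified"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), comment="#")
    df = df.set_index("name")
    if len(df) != _FIXTURE_NROWS[name]:
        raise RuntimeError(f"fixture {name!r} has {len(df)} rows, expected {_FIXTURE_NROWS[name]}")
    if not df.index.is_unique:
        raise RuntimeError(f"fixture {name!r} has duplicate carbohydrate names")
    return df


def write_table(df: pd.DataFrame, path: str | Path, header_meta: dict | None = None) -> None:
    """Write a results table as TSV with ``#``-comment provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g")
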