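"""Domain types, unit conventions and periodic-box geometry.

Internal units are Angstrom (length), picosecond (time), amu (mass) and
Kelvin (temperature).  Diffusion coefficients cross the API boundary in
units of 1e-9 m^2/s, the scale on which experimental (DOSY NMR) and
simulated values for small solutes are conventionally reported.  The
conversion is exact: 1 A^2/ps = 1e-8 m^2/s = 10 x 1e-9 m^2/s.

Only orthorhombic (rectangular) periodic cells are supported; the systems
this package targets use cubic cells.  Triclinic input is rejected
explicitly rather than silently mangled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KB",
    "N_AVOGADRO",
    "A2_PER_PS_TO_1E9_M2_S",
    "TrajectoryFrame",
    "Trajectory",
    "SystemMap",
    "SolventModel",
    "WATER_EXPERIMENTAL",
    "TIP5P",
    "OPC",
    "minimum_image_displacement",
    "unwrap_trajectory",
    "wrap_trajectory",
    "center_of_mass",
    "geometric_center",
    "concentration_mM",
]

#: Boltzmann constant, J/K (SI exact).
KB = 1.380649e-23
#: Avogadro constant, 1/mol (SI exact).
N_AVOGADRO = 6.02214076e23
#: Multiply a diffusion coefficient in A^2/ps by this to get 1e-9 m^2/s.
A2_PER_PS_TO_1E9_M2_S = 10.0


@dataclass(frozen=True)
class SolventModel:
    """A solvent described by its shear viscosity and temperature.

    Parameters
    ----------
    name:
        Label, e.g. ``"water"`` or ``"TIP5P"``.
    viscosity:
        Shear viscosity in kg m^-1 s^-1 (Pa s).
    temperature:
        Absolute temperature in K.
    """

    name: str
    viscosity: float
    temperature: float

    def __post_init__(self) -> None:
        if not (self.viscosity > 0):
            raise ValueError(f"viscosity must be > 0, got {self.viscosity}")
        if not (self.temperature > 0):
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


#: Experimental pure water at 298 K.
WATER_EXPERIMENTAL = SolventModel("water", viscosity=0.00089, temperature=298.0)
#: TIP5P water model at 298 K.
TIP5P = SolventModel("TIP5P", viscosity=0.0007, temperature=298.0)
#: OPC water model at 298 K.
OPC = SolventModel("OPC", viscosity=0.00079, temperature=298.0)

SOLVENTS = {s.name: s for s in (WATER_EXPERIMENTAL, TIP5P, OPC)}


@dataclass
class TrajectoryFrame:
    """One snapshot: coordinates plus the orthorhombic cell that holds them.

    ``box_lengths`` are the three edge lengths of the rectangular periodic
    cell in Angstrom; ``coords`` is an ``(n_atoms, 3)`` array in Angstrom;
    ``time`` is the simulation time stamp in picoseconds.
    """

    time: float
    box_lengths: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.box_lengths = np.asarray(self.box_lengths, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n_atoms, 3), got {self.coords.shape}")
        if not np.all(self.box_lengths > 0):
            raise ValueError(f"box lengths must be > 0, got {self.box_lengths}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def volume(self) -> float:
        """Cell volume in A^3."""
        return float(np.prod(self.box_lengths))


@dataclass
class Trajectory:
    """An ordered sequence of frames with a common atom count.

    ``frame_interval`` is the spacing between saved frames in picoseconds
    (the reference protocol saves every 10 ps).
    """

    frames: list[TrajectoryFrame]
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        if not (self.frame_interval > 0):
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        n = self.frames[0].n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, expected {n} (constant atom count)"
                )
        times = np.array([f.time for f in self.frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked into an (n_frames, n_atoms, 3) array."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class SystemMap:
    """Assignment of atom indices to solute copies and solvent oxygens.

    ``solute_groups`` holds one set of 0-based atom indices per solute copy
    (pairwise disjoint); ``water_oxygen_indices`` holds the oxygen atom of
    every solvent molecule; ``masses`` is a per-atom array in amu.
    """

    solute_groups: list[np.ndarray]
    water_oxygen_indices: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.solute_groups = [
            np.asarray(sorted(g), dtype=np.intp) for g in self.solute_groups
        ]
        self.water_oxygen_indices = np.asarray(
            sorted(self.water_oxygen_indices), dtype=np.intp
        )
        self.masses = np.asarray(self.masses, dtype=float)
        if not np.all(self.masses > 0):
            raise ValueError("all masses must be > 0")
        n = self.masses.shape[0]
        seen: set[int] = set()
        for gi, g in enumerate(self.solute_groups):
            if g.size == 0:
                raise ValueError(f"solute group {gi} is empty")
            if g.min() < 0 or g.max() >= n:
                raise ValueError(f"solute group {gi} has indices outside [0, {n})")
            gset = set(g.tolist())
            if seen & gset:
                raise ValueError(f"solute group {gi} overlaps another group")
            seen |= gset
        wset = set(self.water_oxygen_indices.tolist())
        if wset & seen:
            raise ValueError("water oxygen indices overlap solute groups")
        if self.water_oxygen_indices.size and (
            self.water_oxygen_indices.min() < 0 or self.water_oxygen_indices.max() >= n
        ):
            raise ValueError(f"water oxygen indices outside [0, {n})")

    @property
    def n_solutes(self) -> int:
        return len(self.solute_groups)

    @property
    def n_atoms(self) -> int:
        return self.masses.shape[0]


def minimum_image_displacement(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    box: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Displacement ``a - b`` mapped to the nearest periodic image.

    Works on single 3-vectors or on broadcastable arrays of 3-vectors.
    Each component of the result lies in ``[-box/2, box/2)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if not np.all(box > 0):
        raise ValueError(f"box lengths must be > 0, got {box}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    d = a - b
    # floor-division form keeps the half-open interval convention exactly
    return d - box * np.floor(d / box + 0.5)


def minimum_image_distance(a, b, box) -> np.ndarray:
    """Euclidean norm of :func:`minimum_image_displacement`."""
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def center_of_mass(
    coords: np.ndarray, masses: np.ndarray, subset: Sequence[int] | np.ndarray | None = None
) -> np.ndarray:
    """Mass-weighted mean position of ``subset`` (all atoms if None)."""
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if subset is not None:
        subset = np.asarray(subset, dtype=np.intp)
        if subset.size == 0:
            raise ValueError("subset must be nonempty")
        coords = coords[subset]
        masses = masses[subset]
    if coords.shape[0] == 0:
        raise ValueError("subset must be nonempty")
    if not np.all(masses > 0):
        raise ValueError("masses must be positive")
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def geometric_center(coords: np.ndarray, subset=None) -> np.ndarray:
    """Unweighted mean position (the 'geometric center')."""
    coords = np.asarray(coords, dtype=float)
    if subset is not None:
        subset = np.asarray(subset, dtype=np.intp)
        if subset.size == 0:
            raise ValueError("subset must be nonempty")
        coords = coords[subset]
    return coords.mean(axis=0)


def concentration_mM(n_copies: int, box_volume: float) -> float:
    """Molar concentration, in mmol/L, of ``n_copies`` solutes in ``box_volume`` A^3.

    20 copies in a 664,424 A^3 cell gives the nominal 50 mM condition.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    if not (box_volume > 0):
        raise ValueError(f"box volume must be > 0, got {box_volume}")
    volume_L = box_volume * 1e-27  # 1 A^3 = 1e-27 L
    return n_copies / (N_AVOGADRO * volume_L) * 1e3  # mol/L -> mmol/L


def unwrap_trajectory(traj: Trajectory, system_map: SystemMap | None = None) -> Trajectory:
    """Remove periodic wrapping so that per-atom paths are continuous.

    Each atom is unwrapped independently by accumulating minimum-image
    frame-to-frame displacements from the first frame.  This requires the
    sampling to be fast enough that no atom travels half a box length
    between saved frames; a larger apparent jump is ambiguous and raises.
    """
    coords = traj.coords_array()
    out = np.empty_like(coords)
    out[0] = coords[0]
    for k in range(1, traj.n_frames):
        box = traj.frames[k].box_lengths
        raw = coords[k] - coords[k - 1]
        step = raw - box * np.floor(raw / box + 0.5)
        # an apparent displacement at exactly half the box cannot be resolved
        too_far = np.abs(step) >= box / 2 - 1e-9
        if np.any(too_far):
            atom = int(np.argwhere(too_far.any(axis=1))[0, 0])
            label = f"atom {atom}"
            if system_map is not None:
                for gi, g in enumerate(system_map.solute_groups):
                    if atom in set(g.tolist()):
                        label = f"solute {gi} (atom {atom})"
                        break
            raise ValueError(
                f"displacement >= half box between frames {k - 1} and {k} for "
                f"{label}; trajectory is sampled too coarsely to unwrap"
            )
        out[k] = out[k - 1] + step
    frames = [
        TrajectoryFrame(f.time, f.box_lengths.copy(), out[k])
        for k, f in enumerate(traj.frames)
    ]
    return Trajectory(frames, traj.frame_interval)


def wrap_trajectory(traj: Trajectory) -> Trajectory:
    """Wrap all coordinates back into the primary cell ``[0, box)``."""
    frames = []
    for f in traj.frames:
        wrapped = f.coords - f.box_lengths * np.floor(f.coords / f.box_lengths)
        frames.append(TrajectoryFrame(f.time, f.box_lengths.copy(), wrapped))
    return Trajectory(frames, traj.frame_interval)
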