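"""Synthetic trajectories with known ground truth.

The analyses in this package were designed against all-atom MD of
carbohydrate solutions (20 solute copies in a 664,424 A^3 cubic cell,
i.e. 50 mM, frames saved every 10 ps).  Running such simulations is out
of scope here; instead this module generates desk-scale surrogates whose
ground truth is known exactly, so every estimator can be validated:

* :func:`simulate_brownian` — independent Gaussian random walks with a
  prescribed diffusion coefficient, for the MSD -> D pipeline;
* :func:`generate_ideal_solvent` — uniform water-oxygen positions, the
  g(r) = 1 null model for RDF and shell-count code;
* :func:`generate_aggregate_fixture` — clusters constructed with exact
  contact distances and frame-level persistence, for the aggregation
  bookkeeping;
* :func:`rigid_body` — point sets with an analytically known radius of
  gyration.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import A2_PER_PS_TO_1E9_M2_S, SystemMap, Trajectory, TrajectoryFrame

__all__ = [
    "BrownianSpec",
    "simulate_brownian",
    "generate_ideal_solvent",
    "generate_aggregate_fixture",
    "rigid_body",
]

#: Default cell matching the reference 50 mM condition: 20 copies in 664,424 A^3.
DEFAULT_BOX_LENGTH = 664424.0 ** (1.0 / 3.0)  # 87.35 A


@dataclass(frozen=True)
class BrownianSpec:
    """Parameters for a Brownian (free-diffusion) surrogate trajectory.

    ``d_true`` is the per-solute diffusion coefficient in 1e-9 m^2/s;
    ``frame_interval`` in ps; ``box_length`` in Angstrom.  Defaults mirror
    the reference study conditions: 20 solutes in an 87.35 A cubic cell
    (50 mM), 10 ps between frames.
    """

    n_solutes: int = 20
    d_true: float = 0.62
    frame_interval: float = 10.0
    n_frames: int = 1000
    box_length: float = DEFAULT_BOX_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.d_true >= 0):
            raise ValueError("d_true must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (self.box_length > 0):
            raise ValueError("box_length must be > 0")
        if self.n_solutes < 1:
            raise ValueError("n_solutes must be >= 1")

    @property
    def step_std(self) -> float:
        """Per-dimension step standard deviation in Angstrom."""
        d_a2ps = self.d_true / A2_PER_PS_TO_1E9_M2_S
        return float(np.sqrt(2.0 * d_a2ps * self.frame_interval))


def simulate_brownian(spec: BrownianSpec, wrap: bool = True) -> tuple[Trajectory, SystemMap]:
    """Independent Gaussian random walks for ``n_solutes`` pseudo-atoms.

    Each solute is one unit-mass pseudo-atom taking i.i.d. Gaussian steps
    with per-dimension variance ``2 * D_true * dt`` (after converting
    D_true from 1e-9 m^2/s to A^2/ps).  With ``wrap=True`` positions are
    folded into the primary cell, which is what a real MD trajectory looks
    like; ``wrap=False`` returns the continuous paths.
    """
    std = spec.step_std
    if std >= spec.box_length / 4:
        raise ValueError(
            f"step std {std:.3g} A >= box/4 ({spec.box_length / 4:.3g} A); "
            "unwrapping such a trajectory would be ambiguous — use a shorter "
            "frame interval or a larger box"
        )
    rng = np.random.default_rng(spec.seed)
    start = rng.uniform(0.0, spec.box_length, size=(spec.n_solutes, 3))
    steps = rng.normal(0.0, std, size=(spec.n_frames - 1, spec.n_solutes, 3))
    paths = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    if wrap:
        paths = paths - spec.box_length * np.floor(paths / spec.box_length)
    box = np.full(3, spec.box_length)
    frames = [
        TrajectoryFrame(time=k * spec.frame_interval, box_lengths=box.copy(), coords=paths[k])
        for k in range(spec.n_frames)
    ]
    system_map = SystemMap(
        solute_groups=[np.array([i]) for i in range(spec.n_solutes)],
        water_oxygen_indices=np.array([], dtype=np.intp),
        masses=np.ones(spec.n_solutes),
    )
    return Trajectory(frames, frame_interval=spec.frame_interval), system_map


def generate_ideal_solvent(
    n_waters: int,
    box: float,
    seed: int = 0,
    n_frames: int = 1,
    solute_at_center: bool = True,
) -> tuple[Trajectory, SystemMap]:
    """Uniform i.i.d. water-oxygen positions in a cubic box.

    This is the ideal-gas null model: the radial distribution function
    around any fixed point is exactly 1 in expectation, and the integrated
    shell count to radius r is (4/3) pi rho r^3.  A single unit-mass solute
    pseudo-atom sits at the box center (index 0) so solvation analyses have
    a reference group; waters occupy the remaining indices.
    """
    if n_waters <= 0:
        raise ValueError("n_waters must be > 0")
    if not (box > 0):
        raise ValueError("box must be > 0")
    rng = np.random.default_rng(seed)
    n_solute = 1 if solute_at_center else 0
    frames = []
    for k in range(n_frames):
        waters = rng.uniform(0.0, box, size=(n_waters, 3))
        if solute_at_center:
            coords = np.vstack([np.full((1, 3), box / 2.0), waters])
        else:
            coords = waters
        frames.append(
            TrajectoryFrame(time=k * 10.0, box_lengths=np.full(3, box), coords=coords)
        )
    system_map = SystemMap(
        solute_groups=[np.array([0])] if solute_at_center else [],
        water_oxygen_indices=np.arange(n_solute, n_solute + n_waters),
        masses=np.ones(n_solute + n_waters),
    )
    return Trajectory(frames, frame_interval=10.0), system_map


def rigid_body(points: np.ndarray, masses: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """A point structure together with its analytic radius of gyration.

    Returns ``(coords, masses, r_g)`` with
    ``r_g = sqrt(sum m_i |r_i - r_com|^2 / sum m_i)`` evaluated directly.
    Used as the closed-form oracle for trajectory-based R_g estimators.
    """
    coords = np.atleast_2d(np.asarray(points, dtype=float))
    if coords.shape[0] < 1:
        raise ValueError("need at least one point")
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    rg2 = (masses * ((coords - com) ** 2).sum(axis=1)).sum() / masses.sum()
    return coords, masses, float(np.sqrt(rg2))


def _cluster_template(size: int, contact_distance: float) -> np.ndarray:
    """Coordinates for a chain cluster whose nearest-atom gaps equal
    ``contact_distance`` exactly.

    Each solute is a 2-atom dumbbell (bond length 1 A) along x; consecutive
    solutes are separated so the closest inter-solute atom pair sits at
    exactly the requested contact distance.
    """
    coords = []
    x = 0.0
    for _ in range(size):
        coords.append([[x, 0.0, 0.0], [x + 1.0, 0.0, 0.0]])
        x += 1.0 + contact_distance
    return np.array(coords)  # (size, 2, 3)


def generate_aggregate_fixture(
    cluster_sizes: list[int],
    contact_distance: float = 2.5,
    separation: float = 10.0,
    box: float = DEFAULT_BOX_LENGTH,
    n_frames: int = 5,
    persistence_pattern: dict[int, list[bool]] | None = None,
    seed: int = 0,
) -> tuple[Trajectory, SystemMap]:
    """Construct solute clusters with exact contact geometry and controlled
    frame-by-frame persistence.

    ``cluster_sizes`` lists the intended aggregate sizes (size 1 = free
    monomer).  Within a cluster, consecutive solutes' nearest atoms sit at
    exactly ``contact_distance``; distinct clusters (and scattered
    monomers) are at least ``separation`` apart.  ``persistence_pattern``
    maps a cluster index to a per-frame boolean mask; in frames where the
    mask is False the cluster's members are pulled apart to ``separation``
    (monomeric), letting tests exercise the minimum-persistence filter.

    Solutes are 2-atom dumbbells of unit mass; there are no waters.
    """
    if not (contact_distance < 2.85 < separation):
        raise ValueError("need contact_distance < 2.85 < separation")
    if any(s < 1 for s in cluster_sizes):
        raise ValueError("cluster sizes must be >= 1")
    n_clusters = len(cluster_sizes)
    # lay clusters on a coarse grid with `separation` margin
    max_extent = max(
        (s - 1) * (1.0 + contact_distance) + 1.0 for s in cluster_sizes
    )
    pitch = max_extent + separation
    per_side = max(1, int(box // pitch))
    if n_clusters > per_side**3:
        raise ValueError(
            f"cannot place {n_clusters} clusters with separation {separation} in box {box:.1f}"
        )
    origins = []
    for idx in range(n_clusters):
        ix, rem = divmod(idx, per_side * per_side)
        iy, iz = divmod(rem, per_side)
        origins.append(np.array([ix, iy, iz], dtype=float) * pitch + 1.0)

    frames = []
    groups: list[np.ndarray] | None = None
    for fk in range(n_frames):
        all_coords = []
        group_list = []
        atom = 0
        for ci, size in enumerate(cluster_sizes):
            present = True
            if persistence_pattern and ci in persistence_pattern:
                present = bool(persistence_pattern[ci][fk])
            tmpl = _cluster_template(size, contact_distance)
            if not present and size > 1:
                # pull members apart along y so nothing is within `separation`
                for m in range(size):
                    tmpl[m, :, 1] += m * separation
            tmpl = tmpl + origins[ci]
            for m in range(size):
                all_coords.append(tmpl[m])
                group_list.append(np.arange(atom, atom + 2))
                atom += 2
        coords = np.vstack(all_coords)
        if coords.max() >= box or coords.min() < 0:
            raise ValueError("infeasible packing: cluster layout exceeds the box")
        frames.append(
            TrajectoryFrame(time=fk * 10.0, box_lengths=np.full(3, box), coords=coords)
        )
        if groups is None:
            groups = group_list
    assert groups is not None
    system_map = SystemMap(
        solute_groups=groups,
        water_oxygen_indices=np.array([], dtype=np.intp),
        masses=np.ones(frames[0].n_atoms),
    )
    return Trajectory(frames, frame_interval=10.0), system_map
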