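"""Solute aggregation: contacts, clusters, persistence and kinetics.

Two solutes are "in contact" in a frame when any atom of one is within a
cutoff (default 2.85 A, the nearest-approach distance of methanol oxygens
in liquid methanol) of any atom of the other, under the minimum-image
convention.  An aggregate is a connected component of the per-frame
contact graph.  An aggregate *event* is a maximal run of consecutive
frames over which an identical membership set persists as a component;
events shorter than a minimum persistence (default 2 frames) are
discarded as transient encounters.  Any gain or loss of a member ends an
event and starts a new one — unambiguous bookkeeping at the cost of
splitting lifetimes when clusters exchange members.

From the surviving events the module reports the mean aggregate size S,
per-size concentrations (mM) and mean lifetimes (ns), and the free-monomer
concentration from per-frame singleton counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import SystemMap, Trajectory, TrajectoryFrame, concentration_mM

__all__ = [
    "ContactGraph",
    "AggregateEvent",
    "AggregateStats",
    "detect_contacts",
    "cluster_frame",
    "aggregate_kinetics",
    "CONTACT_CUTOFF",
]

#: Default heavy-contact cutoff in Angstrom.
CONTACT_CUTOFF = 2.85


@dataclass
class ContactGraph:
    """Solute-solute contacts in one frame: symmetric, no self-edges."""

    frame_index: int
    n_solutes: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges are not allowed")


@dataclass
class AggregateEvent:
    """One persistence run of a fixed membership set."""

    members: frozenset[int]
    start_frame: int
    n_frames: int

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class AggregateStats:
    """Summary of aggregation over a trajectory.

    ``size_distribution`` maps aggregate size -> mean count per frame
    (surviving events only); ``concentrations`` the same in mM;
    ``lifetimes`` size -> mean event duration in ns; ``mean_size_s`` the
    frame-weighted mean aggregate size; ``free_monomer_mM`` from per-frame
    singleton counts.
    """

    size_distribution: dict[int, float]
    concentrations: dict[int, float]
    lifetimes: dict[int, float]
    mean_size_s: float
    free_monomer_mM: float
    max_size: int
    events: list[AggregateEvent] = field(default_factory=list)
    n_frames: int = 0


def _group_arrays(system_map: SystemMap, heavy_only: bool, heavy_mass: float = 2.0):
    """Concatenated solute atom coordinates index + per-atom group labels."""
    idx_list, label_list = [], []
    for gi, g in enumerate(system_map.solute_groups):
        g = np.asarray(g)
        if heavy_only:
            g = g[system_map.masses[g] > heavy_mass]
            if g.size == 0:
                raise ValueError(f"solute group {gi} has no heavy atoms")
        idx_list.append(g)
        label_list.append(np.full(g.size, gi, dtype=np.intp))
    return np.concatenate(idx_list), np.concatenate(label_list)


def detect_contacts(
    frame: TrajectoryFrame,
    system_map: SystemMap,
    cutoff: float = CONTACT_CUTOFF,
    frame_index: int = 0,
    heavy_only: bool = False,
) -> ContactGraph:
    """Contact graph of one frame: edge iff the minimum-image nearest-atom
    distance between two solute groups is <= ``cutoff``.

    Every atom participates by default ("any atom" rule, hydrogens
    included); ``heavy_only`` restricts to atoms heavier than 2 amu.
    Uses a periodic KD-tree over all solute atoms, so the cost is close to
    linear in atom count for dilute systems.
    """
    if system_map.n_solutes < 2:
        raise ValueError("need at least 2 solute groups")
    if not (cutoff > 0):
        raise ValueError("cutoff must be > 0")
    atom_idx, labels = _group_arrays(system_map, heavy_only)
    box = frame.box_lengths
    pos = frame.coords[atom_idx]
    pos = pos - box * np.floor(pos / box)  # cKDTree needs [0, box)
    # guard against coordinates landing exactly on the upper boundary
    pos = np.where(pos >= box, 0.0, pos)
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    edges = set()
    for a, b in pairs:
        ga, gb = labels[a], labels[b]
        if ga != gb:
            edges.add((min(ga, gb), max(ga, gb)))
    return ContactGraph(
        frame_index=frame_index, n_solutes=system_map.n_solutes, edges=frozenset(edges)
    )


def cluster_frame(graph: ContactGraph) -> list[frozenset[int]]:
    """Partition solutes into maximal connected components of the contact
    graph; singletons are free monomers."""
    n = graph.n_solutes
    if not graph.edges:
        return [frozenset([i]) for i in range(n)]
    rows, cols = zip(*graph.edges)
    adj = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    comps: list[set[int]] = [set() for _ in range(n_comp)]
    for node, lab in enumerate(labels):
        comps[lab].add(node)
    return [frozenset(c) for c in comps]


def aggregate_kinetics(
    traj: Trajectory,
    system_map: SystemMap,
    cutoff: float = CONTACT_CUTOFF,
    min_persistence_frames: int = 2,
    heavy_only: bool = False,
) -> AggregateStats:
    """Aggregate size/lifetime/concentration statistics over a trajectory.

    Persistence is applied to whole membership sets: an event is a maximal
    run of consecutive frames in which the identical set of solutes forms
    a connected component, and runs shorter than
    ``min_persistence_frames`` are dropped.  Free monomers are counted
    per frame regardless of event filtering.
    """
    if traj.n_frames < min_persistence_frames:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames < min persistence "
            f"{min_persistence_frames}"
        )
    dt_ns = traj.frame_interval / 1000.0
    n_solutes = system_map.n_solutes

    open_runs: dict[frozenset[int], tuple[int, int]] = {}  # members -> (start, length)
    events: list[AggregateEvent] = []
    singleton_counts = []
    volumes = []
    for k, frame in enumerate(traj.frames):
        graph = detect_contacts(frame, system_map, cutoff, k, heavy_only)
        comps = cluster_frame(graph)
        # per-frame conservation: components partition all solutes
        total = sum(len(c) for c in comps)
        if total != n_solutes:
            raise AssertionError(
                f"frame {k}: component members ({total}) != solutes ({n_solutes})"
            )
        singleton_counts.append(sum(1 for c in comps if len(c) == 1))
        volumes.append(frame.volume)
        current = {c for c in comps if len(c) >= 2}
        for members in list(open_runs):
            if members not in current:
                start, length = open_runs.pop(members)
                events.append(AggregateEvent(members, start, length))
        for members in current:
            if members in open_runs:
                start, length = open_runs[members]
                open_runs[members] = (start, length + 1)
            else:
                open_runs[members] = (k, 1)
    for members, (start, length) in open_runs.items():
        events.append(AggregateEvent(members, start, length))

    surviving = [e for e in events if e.n_frames >= min_persistence_frames]
    n_frames = traj.n_frames
    mean_volume = float(np.mean(volumes))

    frames_by_size: dict[int, int] = {}
    durations_by_size: dict[int, list[int]] = {}
    for e in surviving:
        frames_by_size[e.size] = frames_by_size.get(e.size, 0) + e.n_frames
        durations_by_size.setdefault(e.size, []).append(e.n_frames)

    size_distribution = {s: c / n_frames for s, c in sorted(frames_by_size.items())}
    concentrations = {
        s: concentration_mM(1, mean_volume) * mean for s, mean in size_distribution.items()
    }
    lifetimes = {
        s: float(np.mean(d)) * dt_ns for s, d in sorted(durations_by_size.items())
    }
    total_agg_frames = sum(frames_by_size.values())
    if total_agg_frames:
        mean_size_s = (
            sum(s * c for s, c in frames_by_size.items()) / total_agg_frames
        )
    else:
        mean_size_s = float("nan")
    free_monomer = concentration_mM(1, mean_volume) * float(np.mean(singleton_counts))
    return AggregateStats(
        size_distribution=size_distribution,
        concentrations=concentrations,
        lifetimes=lifetimes,
        mean_size_s=float(mean_size_s),
        free_monomer_mM=free_monomer,
        max_size=max(frames_by_size) if frames_by_size else 1,
        events=surviving,
        n_frames=n_frames,
    )
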