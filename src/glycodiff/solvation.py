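"""Solvation-shell analysis: radial distribution functions and water maps.

The RDF g(r) is computed from the geometric center of one solute copy to
all water oxygen atoms under the minimum-image convention, normalized by
the ideal-gas shell count rho * 4 pi r^2 dr.  The first-shell water count

    N1 = 4 pi rho \\int_0^{r_min} g(r) r^2 dr

integrates to r_min, the bottom of the well between the first and second
peaks.  Peak/minimum location works on a Savitzky-Golay smoothed copy of
the curve to stabilize against bin noise; the raw curve is what gets
integrated and reported.

Water occupancy maps deposit a normalized 3-D Gaussian per water oxygen
per frame onto a cubic voxel grid centered on the solute (frames are
superposed on the solute first, so the map lives in the solute frame),
then average over frames: the voxel values are a time-averaged probability
density (A^-3) of finding a water oxygen there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core import (
    SystemMap,
    Trajectory,
    geometric_center,
    center_of_mass,
    minimum_image_displacement,
)

__all__ = [
    "RDFProfile",
    "OccupancyGrid",
    "compute_rdf",
    "integrate_N1",
    "first_shell_stats",
    "occupancy_map",
]


@dataclass
class RDFProfile:
    """A center-to-water-oxygen radial distribution function.

    ``rho`` is the bulk water number density (A^-3) used for
    normalization.  Shell statistics (peak position/height, first minimum)
    and N1 are filled in by :func:`first_shell_stats` / :func:`integrate_N1`.
    """

    bin_centers: np.ndarray
    g: np.ndarray
    rho: float
    bin_width: float
    first_peak_position: float | None = None
    first_peak_max: float | None = None
    first_min_value: float | None = None
    r_min: float | None = None
    n1: float | None = None

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("g(r) must be nonnegative")


@dataclass
class OccupancyGrid:
    """Gaussian-weighted water-oxygen probability density on a voxel grid.

    ``origin`` is the position (A) of the corner of voxel (0,0,0);
    ``spacing`` the cubic voxel edge (default 0.25 A); values in A^-3.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray
    isovalue_fractions: tuple[float, ...] = (0.036, 0.038, 0.040)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.spacing > 0):
            raise ValueError("spacing must be > 0")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be nonnegative and finite")

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def isovalues(self) -> dict[float, float]:
        """Visualization isovalues as fractions of the grid maximum."""
        vmax = float(self.values.max())
        return {f: f * vmax for f in self.isovalue_fractions}


def compute_rdf(
    traj: Trajectory,
    system_map: SystemMap,
    solute_index: int = 0,
    bin_width: float = 0.05,
    r_max: float | None = None,
    mass_weighted_center: bool = False,
) -> RDFProfile:
    """g(r) from one solute's geometric center to all water oxygens.

    Distances use the minimum-image convention, so ``r_max`` may not
    exceed half the smallest box length (default: exactly that bound).
    The density rho is n_waters / box volume, averaged over frames.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if system_map.water_oxygen_indices.size == 0:
        raise ValueError("system map defines no water oxygens")
    half_min_box = min(f.box_lengths.min() for f in traj.frames) / 2.0
    if r_max is None:
        r_max = half_min_box
    if r_max > half_min_box + 1e-9:
        raise ValueError(
            f"r_max {r_max:.2f} A exceeds half the smallest box ({half_min_box:.2f} A)"
        )
    group = system_map.solute_groups[solute_index]
    widx = system_map.water_oxygen_indices
    n_bins = int(np.floor(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    rho_acc = 0.0
    for f in traj.frames:
        if mass_weighted_center:
            center = center_of_mass(f.coords, system_map.masses, group)
        else:
            center = geometric_center(f.coords, group)
        d = minimum_image_displacement(f.coords[widx], center, f.box_lengths)
        r = np.linalg.norm(d, axis=1)
        counts += np.histogram(r, bins=edges)[0]
        rho_acc += widx.size / f.volume
    rho = rho_acc / traj.n_frames
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / traj.n_frames / (rho * shell_vol)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFProfile(bin_centers=centers, g=g, rho=rho, bin_width=bin_width)


def first_shell_stats(
    profile: RDFProfile,
    smooth_window: int = 11,
    exclusion_radius: float = 1.0,
    prominence: float = 0.05,
) -> tuple[float, float, float, float]:
    """Locate the first solvation peak and the following minimum.

    Works on a Savitzky-Golay smoothed copy of g(r) (polyorder 3) with a
    prominence threshold, so neither a single noisy bin nor a smoothing
    overshoot can masquerade as an extremum; the returned peak height /
    minimum value are read from the raw curve at the located bins.
    Returns ``(peak_position, peak_max, min_value, r_min)`` and stores
    them on the profile.  A profile with no interior maximum followed by
    a minimum raises.
    """
    from scipy.signal import find_peaks

    r = profile.bin_centers
    g = profile.g
    if len(g) < smooth_window + 2:
        raise ValueError("profile too short for shell analysis")
    w = min(smooth_window, len(g) - 1)
    if w % 2 == 0:
        w -= 1
    gs = savgol_filter(g, window_length=w, polyorder=min(3, w - 1))
    start = max(int(np.searchsorted(r, exclusion_radius)), 1)
    maxima, _ = find_peaks(gs, prominence=prominence)
    maxima = maxima[maxima >= start]
    if maxima.size == 0:
        raise ValueError("no interior maximum found in g(r); profile may be monotone or flat")
    peak_idx = int(maxima[0])
    minima, _ = find_peaks(-gs, prominence=prominence)
    minima = minima[minima > peak_idx]
    if minima.size == 0:
        raise ValueError(
            "no minimum after the first peak; increase r_max to capture the full first shell"
        )
    min_idx = int(minima[0])
    profile.first_peak_position = float(r[peak_idx])
    profile.first_peak_max = float(g[peak_idx])
    profile.first_min_value = float(g[min_idx])
    profile.r_min = float(r[min_idx])
    return (
        profile.first_peak_position,
        profile.first_peak_max,
        profile.first_min_value,
        profile.r_min,
    )


def integrate_N1(profile: RDFProfile, r_min: float | None = None) -> float:
    """First-shell water count: N1 = 4 pi rho * integral of g(r) r^2 to r_min.

    The histogram estimator makes g piecewise constant on bins, so the
    integral is evaluated exactly bin by bin (rho * g_i * shell volume);
    the bin containing ``r_min`` contributes its partial shell.  This
    quadrature returns the frame-averaged water count inside r_min
    exactly — a constructed shell of k waters integrates to k.  ``r_min``
    defaults to the profile's located minimum (run
    :func:`first_shell_stats` first, or pass it explicitly).
    """
    if r_min is None:
        r_min = profile.r_min
    if r_min is None:
        raise ValueError(
            "no r_min available: run first_shell_stats first or pass r_min explicitly"
        )
    dr = profile.bin_width
    lo_edges = profile.bin_centers - dr / 2.0
    hi_edges = profile.bin_centers + dr / 2.0
    if r_min <= lo_edges[0] or r_min > hi_edges[-1] + 1e-9:
        raise ValueError(f"r_min {r_min} outside the profile range")
    upper = np.minimum(hi_edges, r_min)
    shell = 4.0 / 3.0 * np.pi * np.clip(upper**3 - lo_edges**3, 0.0, None)
    shell[upper <= lo_edges] = 0.0
    n1 = profile.rho * float((profile.g * shell).sum())
    profile.n1 = n1
    return n1


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns (rotation, mobile_centroid, reference_centroid).  Degenerate
    point sets (< 3 atoms, or collinear) fall back to pure translation.
    """
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    if mobile.shape[0] < 3:
        return np.eye(3), mc, rc
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:  # collinear / degenerate
        return np.eye(3), mc, rc
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, mc, rc


def occupancy_map(
    traj: Trajectory,
    system_map: SystemMap,
    solute_index: int = 0,
    grid_edge: float = 25.0,
    spacing: float = 0.25,
    sigma: float = 1.0,
    align: bool = True,
    cutoff_sigmas: float = 4.0,
) -> OccupancyGrid:
    """Time-averaged Gaussian-weighted water-oxygen density around a solute.

    A cubic grid of edge ``grid_edge`` (A) is centered on the solute's
    geometric center.  Per frame, each water oxygen deposits an isotropic
    normalized Gaussian (std ``sigma`` A, truncated at ``cutoff_sigmas``);
    values are averaged over frames, so integrating the grid recovers the
    mean number of waters inside it.  With ``align=True`` every frame is
    first superposed on the solute of the reference (first) frame, placing
    the map in the solute's own frame.
    """
    widx = system_map.water_oxygen_indices
    if widx.size == 0:
        raise ValueError("system map defines no water oxygens")
    group = system_map.solute_groups[solute_index]
    n_vox = int(round(grid_edge / spacing))
    ref = traj.frames[0].coords[group]
    ref_center = geometric_center(ref)
    origin = ref_center - grid_edge / 2.0
    values = np.zeros((n_vox, n_vox, n_vox))
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    reach = int(np.ceil(cutoff_sigmas * sigma / spacing))

    for f in traj.frames:
        waters = f.coords[widx]
        if align:
            rot, mc, rc = _kabsch(f.coords[group], ref)
            waters = (waters - mc) @ rot.T + rc
        else:
            # keep the solute centered without rotating
            shift = ref_center - geometric_center(f.coords[group])
            waters = waters + shift
        frac = (waters - origin) / spacing
        for w in frac:
            i0 = np.maximum(np.floor(w - reach).astype(int), 0)
            i1 = np.minimum(np.ceil(w + reach).astype(int) + 1, n_vox)
            if np.any(i0 >= i1):
                continue
            gx = np.exp(
                -0.5 * ((np.arange(i0[0], i1[0]) + 0.5 - w[0]) * spacing) ** 2 / sigma**2
            )
            gy = np.exp(
                -0.5 * ((np.arange(i0[1], i1[1]) + 0.5 - w[1]) * spacing) ** 2 / sigma**2
            )
            gz = np.exp(
                -0.5 * ((np.arange(i0[2], i1[2]) + 0.5 - w[2]) * spacing) ** 2 / sigma**2
            )
            values[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] += (
                norm * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
            )
    values /= traj.n_frames
    return OccupancyGrid(origin=origin, spacing=spacing, values=values)
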