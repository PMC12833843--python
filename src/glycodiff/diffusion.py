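"""Translational diffusion from trajectories.

The estimator chain is the standard one for solution MD: per-solute
center-of-mass paths -> mean squared displacement (MSD) -> ordinary
least-squares slope over a fit window -> D = slope / 6 (three dimensions),
reported in 1e-9 m^2/s.  Stokes-Einstein converts between D and the
hydrodynamic radius R_H:

    D = k_B T / (6 pi eta R_H)

with eta the solvent shear viscosity.  A finite-size correction for
periodic cubic cells (hydrodynamic self-interaction across images) is
available as an explicit, optional step.

MSD averaging defaults to all time origins (the variance-optimal windowed
estimator, computed with the FFT autocorrelation identity); a
single-origin mode reproduces the plain <|r(t) - r(0)|^2> definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    A2_PER_PS_TO_1E9_M2_S,
    KB,
    SolventModel,
    SystemMap,
    Trajectory,
    center_of_mass,
)

__all__ = [
    "MSDSeries",
    "DiffusionEstimate",
    "compute_msd",
    "fit_diffusion",
    "stokes_einstein",
    "finite_box_correction",
    "welch_t",
    "XI_CUBIC",
]

#: Cubic-lattice self-interaction constant of the periodic-box correction.
XI_CUBIC = 2.837297


@dataclass
class MSDSeries:
    """Mean squared displacement vs lag time.

    ``msd`` is in A^2, averaged over solutes (and replicates when
    ``per_replicate_msd`` is set); ``lag_times`` in ps, starting at 0.
    """

    lag_times: np.ndarray
    msd: np.ndarray
    per_replicate_msd: np.ndarray | None = None  # (n_replicates, n_lags)

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if self.lag_times.shape != self.msd.shape:
            raise ValueError("lag_times and msd must have equal length")
        if len(self.lag_times) and self.lag_times[0] == 0 and abs(self.msd[0]) > 1e-9:
            raise ValueError("msd at lag 0 must be 0")
        if np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if np.any(self.msd < -1e-12):
            raise ValueError("msd must be nonnegative")


@dataclass
class DiffusionEstimate:
    """A fitted diffusion coefficient.

    ``d`` and ``stderr`` are in 1e-9 m^2/s; ``fit_window`` is the (t_min,
    t_max) lag interval in ps actually used; ``replicate_values`` holds
    per-replicate fits when the series carried them.  ``negative_slope``
    flags an unphysical (descending) MSD rather than silently clamping.
    """

    d: float
    stderr: float
    fit_window: tuple[float, float]
    n_dimensions: int = 3
    replicate_values: list[float] = field(default_factory=list)
    replicate_sd: float | None = None
    negative_slope: bool = False


def _msd_fft_single(path: np.ndarray) -> np.ndarray:
    """All-origin MSD of one walker path (n_frames, 3) via the FFT identity.

    MSD(m) = S1(m) - 2*S2(m) with S2 the positional autocorrelation; see
    the standard Wiener-Khinchin formulation.  O(F log F).
    """
    F = path.shape[0]
    nfft = 1 << (2 * F - 1).bit_length()
    s2 = np.zeros(F)
    for dim in range(path.shape[1]):
        x = path[:, dim]
        fx = np.fft.rfft(x, nfft)
        acf = np.fft.irfft(fx * np.conj(fx), nfft)[:F]
        s2 += acf
    counts = np.arange(F, 0, -1, dtype=float)
    s2 /= counts
    sq = (path**2).sum(axis=1)
    ssq = np.concatenate([sq, [0.0]])
    sum_sq = 2.0 * sq.sum()
    s1 = np.empty(F)
    for m in range(F):
        sum_sq -= ssq[m - 1] + ssq[F - m]
        s1[m] = sum_sq / (F - m)
    return s1 - 2.0 * s2


def _com_paths(traj: Trajectory, system_map: SystemMap, remove_drift: bool) -> np.ndarray:
    """Per-solute center-of-mass paths, (n_frames, n_solutes, 3)."""
    coords = traj.coords_array()
    n_frames = coords.shape[0]
    n_sol = system_map.n_solutes
    paths = np.empty((n_frames, n_sol, 3))
    for si, g in enumerate(system_map.solute_groups):
        m = system_map.masses[g]
        paths[:, si, :] = (coords[:, g, :] * m[None, :, None]).sum(axis=1) / m.sum()
    if remove_drift:
        paths -= paths.mean(axis=1, keepdims=True) - paths[0].mean(axis=0)
    return paths


def compute_msd(
    traj: Trajectory,
    system_map: SystemMap,
    max_lag: float | None = None,
    multi_origin: bool = True,
    remove_drift: bool = False,
) -> MSDSeries:
    """Ensemble MSD of solute centers of mass.

    The trajectory must be unwrapped (continuous paths); a frame-to-frame
    center-of-mass jump larger than half the box is taken as evidence of a
    still-wrapped trajectory and raises.  ``max_lag`` (ps) truncates the
    series; the default keeps every available lag for multi-origin mode.
    ``remove_drift`` subtracts the ensemble center-of-mass motion first.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    dt = traj.frame_interval
    max_avail = (traj.n_frames - 1) * dt
    if max_lag is None:
        max_lag = max_avail
    if max_lag > max_avail + 1e-9:
        raise ValueError(f"max_lag {max_lag} ps exceeds available {max_avail} ps")
    paths = _com_paths(traj, system_map, remove_drift)
    jumps = np.abs(np.diff(paths, axis=0))
    half_box = min(f.box_lengths.min() for f in traj.frames) / 2.0
    if np.any(jumps > half_box):
        k, si = np.argwhere((jumps > half_box).any(axis=2))[0]
        raise ValueError(
            f"solute {si} jumps more than half the box between frames {k} and "
            f"{k + 1}; the trajectory looks wrapped — unwrap it first"
        )
    n_lags = int(round(max_lag / dt)) + 1
    if multi_origin:
        msd_sum = np.zeros(traj.n_frames)
        for si in range(paths.shape[1]):
            msd_sum += _msd_fft_single(paths[:, si, :])
        msd = msd_sum[:n_lags] / paths.shape[1]
    else:
        disp = paths - paths[0]
        msd = (disp**2).sum(axis=2).mean(axis=1)[:n_lags]
    msd[0] = 0.0
    lags = np.arange(n_lags) * dt
    return MSDSeries(lag_times=lags, msd=np.maximum(msd, 0.0))


def average_replicates(series: list[MSDSeries]) -> MSDSeries:
    """Average MSD curves over replicate runs (equal lag grids required)."""
    if not series:
        raise ValueError("no replicate series given")
    lags = series[0].lag_times
    for s in series[1:]:
        if len(s.lag_times) != len(lags) or np.any(s.lag_times != lags):
            raise ValueError("replicate series have differing lag grids")
    per = np.stack([s.msd for s in series])
    return MSDSeries(lag_times=lags, msd=per.mean(axis=0), per_replicate_msd=per)


def fit_diffusion(
    series: MSDSeries,
    window: tuple[float, float] | None = None,
    through_origin: bool = False,
) -> DiffusionEstimate:
    """OLS slope of MSD(t) over ``window`` (ps); D = slope/6 in 1e-9 m^2/s.

    The default window spans [10%, 50%] of the maximum lag, skipping the
    short-time non-diffusive region and the noisy long-lag tail.  When the
    series carries per-replicate curves, each is fitted too and their
    standard deviation reported.  A negative fitted slope is flagged, not
    silently made positive.
    """
    t = series.lag_times
    if window is None:
        window = (0.10 * t[-1], 0.50 * t[-1])
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
        raise ValueError(f"fit window {window} outside available lags [{t[0]}, {t[-1]}]")
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if mask.sum() < 3:
        raise ValueError("need at least 3 points in the fit window")

    def _slope(y: np.ndarray) -> tuple[float, float]:
        if through_origin:
            x = t[mask]
            s = float((x * y[mask]).sum() / (x * x).sum())
            resid = y[mask] - s * x
            dof = max(mask.sum() - 1, 1)
            se = float(np.sqrt((resid**2).sum() / dof / (x * x).sum()))
            return s, se
        res = stats.linregress(t[mask], y[mask])
        return float(res.slope), float(res.stderr)

    slope, se = _slope(series.msd)
    conv = A2_PER_PS_TO_1E9_M2_S / 6.0  # slope in A^2/ps -> D in 1e-9 m^2/s
    reps: list[float] = []
    rep_sd = None
    if series.per_replicate_msd is not None:
        reps = [_slope(y)[0] * conv for y in series.per_replicate_msd]
        if len(reps) > 1:
            rep_sd = float(np.std(reps, ddof=1))
    return DiffusionEstimate(
        d=slope * conv,
        stderr=se * conv,
        fit_window=(float(lo), float(hi)),
        replicate_values=reps,
        replicate_sd=rep_sd,
        negative_slope=slope < 0,
    )


def stokes_einstein(value: float, solvent: SolventModel) -> float:
    """Convert D (1e-9 m^2/s) <-> R_H (Angstrom) via Stokes-Einstein.

    The relation is an involution up to units — k_B T / (6 pi eta x) — so
    one function serves both directions: pass D to get R_H, pass R_H to
    get D.
    """
    if not (value > 0):
        raise ValueError(f"input must be > 0, got {value}")
    # k_B T / (6 pi eta) has units m^2; with x in 1e-9 m^2/s the result is
    # in 1e-10 m = A, and vice versa.
    c = KB * solvent.temperature / (6.0 * np.pi * solvent.viscosity)  # m^3/s scale
    # D [1e-9 m^2/s] * R_H [1e-10 m] = c  =>  other = c / (value * 1e-19)
    return c / (value * 1e-19)


def finite_box_correction(
    d_pbc: float, solvent: SolventModel, box_length: float
) -> float:
    """Correct a periodic-box D for hydrodynamic self-interaction.

    Adds ``k_B T xi / (6 pi eta L)`` with ``xi = 2.837297`` (cubic lattice)
    to the raw estimate; ``box_length`` in Angstrom, D in 1e-9 m^2/s.
    The correction vanishes as L grows.
    """
    if not (box_length > 0):
        raise ValueError("box_length must be > 0")
    L = box_length * 1e-10  # m
    corr = KB * solvent.temperature * XI_CUBIC / (6.0 * np.pi * solvent.viscosity * L)
    return d_pbc + corr / 1e-9


def welch_t(sample_a, sample_b) -> tuple[float, float]:
    """Two-tailed Welch's t test (unequal variances).

    Returns ``(t, p)``; degrees of freedom by Welch-Satterthwaite.  Two
    zero-variance samples with equal means give (0, 1) by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return float(np.inf) * np.sign(np.mean(a) - np.mean(b)), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
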