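"""MSD computation, D fitting, Stokes-Einstein and replicate statistics."""

import numpy as np
import pytest

from glycodiff.core import (
    SystemMap,
    Trajectory,
    TrajectoryFrame,
    WATER_EXPERIMENTAL,
    TIP5P,
    unwrap_trajectory,
)
from glycodiff.diffusion import (
    KB,
    MSDSeries,
    XI_CUBIC,
    _msd_fft_single,
    average_replicates,
    compute_msd,
    finite_box_correction,
    fit_diffusion,
    stokes_einstein,
    welch_t,
)
from glycodiff.synthetic import BrownianSpec, simulate_brownian


def _single_atom_traj(xs, dt=1.0, box=1000.0):
    frames = [
        TrajectoryFrame(time=k * dt, box_lengths=(box, box, box), coords=[[x, 0.0, 0.0]])
        for k, x in enumerate(xs)
    ]
    smap = SystemMap(
        solute_groups=[np.array([0])],
        water_oxygen_indices=np.array([], dtype=int),
        masses=np.ones(1),
    )
    return Trajectory(frames, frame_interval=dt), smap


class TestComputeMSD:
    def test_stationary_is_zero(self):
        traj, smap = _single_atom_traj([2.0] * 20)
        series = compute_msd(traj, smap)
        assert np.allclose(series.msd, 0.0, atol=1e-12)

    def test_ballistic_closed_form(self):
        """x = v t with v = 1 A/ps gives MSD(t) = t^2 (single origin)."""
        traj, smap = _single_atom_traj([float(k) for k in range(30)])
        series = compute_msd(traj, smap, multi_origin=False)
        assert np.allclose(series.msd, series.lag_times**2, atol=1e-9)
        # multi-origin averaging gives the same answer for uniform motion
        multi = compute_msd(traj, smap, multi_origin=True)
        assert np.allclose(multi.msd, multi.lag_times**2, atol=1e-8)

    def test_fft_multi_origin_matches_brute_force(self):
        rng = np.random.default_rng(0)
        path = np.cumsum(rng.normal(size=(64, 3)), axis=0)
        fft = _msd_fft_single(path)
        brute = np.array(
            [0.0]
            + [
                np.mean(((path[m:] - path[:-m]) ** 2).sum(axis=1))
                for m in range(1, 64)
            ]
        )
        assert np.allclose(fft, brute, atol=1e-9)

    def test_wrapped_trajectory_detected(self):
        traj, smap = simulate_brownian(
            BrownianSpec(n_solutes=5, d_true=1.0, n_frames=300, box_length=8.0, seed=2)
        )
        with pytest.raises(ValueError, match="wrapped"):
            compute_msd(traj, smap)

    def test_brownian_msd_matches_6dt(self):
        """MSD(t)/(6t) recovers D_true within 3 standard errors."""
        spec = BrownianSpec(n_solutes=20, d_true=0.62, n_frames=2000, seed=21)
        traj, smap = simulate_brownian(spec)
        series = compute_msd(unwrap_trajectory(traj, smap), smap, max_lag=2000.0)
        t = series.lag_times[50:]
        ratios = series.msd[50:] / (6 * (0.62 / 10.0) * t)
        se = ratios.std() / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1) < 3 * max(se, 0.02)

    def test_translation_invariance(self):
        traj, smap = simulate_brownian(
            BrownianSpec(n_solutes=3, d_true=0.5, n_frames=100, box_length=200.0, seed=5),
            wrap=False,
        )
        base = compute_msd(traj, smap)
        shifted_frames = [
            TrajectoryFrame(f.time, f.box_lengths, f.coords + np.array([3.0, -7.0, 11.0]))
            for f in traj.frames
        ]
        shifted = compute_msd(Trajectory(shifted_frames, traj.frame_interval), smap)
        assert np.allclose(base.msd, shifted.msd, atol=1e-8)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        traj, smap = simulate_brownian(
            BrownianSpec(n_solutes=3, d_true=0.5, n_frames=100, box_length=200.0, seed=6),
            wrap=False,
        )
        rot = Rotation.from_euler("xyz", [20, 30, 40], degrees=True).as_matrix()
        rotated_frames = [
            TrajectoryFrame(f.time, f.box_lengths, f.coords @ rot.T) for f in traj.frames
        ]
        base = compute_msd(traj, smap)
        rotated = compute_msd(Trajectory(rotated_frames, traj.frame_interval), smap)
        assert np.allclose(base.msd, rotated.msd, atol=1e-8)


class TestFitDiffusion:
    def test_exact_line_closed_form(self):
        """MSD = 6 (0.1 A^2/ps) t fits to D = 1.0 x 1e-9 m^2/s."""
        t = np.arange(0, 101, dtype=float)
        series = MSDSeries(t, 6 * 0.1 * t)
        est = fit_diffusion(series)
        assert est.d == pytest.approx(1.0, abs=1e-12)
        assert not est.negative_slope

    def test_noise_stays_within_ci(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 501, dtype=float)
        clean = 6 * 0.05 * t
        noisy = np.clip(clean + rng.normal(0, 2.0, t.shape), 0, None)
        noisy[0] = 0.0
        est = fit_diffusion(MSDSeries(t, noisy))
        assert abs(est.d - 0.5) < 3 * est.stderr

    def test_linearity_in_scale(self):
        t = np.arange(0, 51, dtype=float)
        series = MSDSeries(t, 0.3 * t)
        scaled = MSDSeries(t, 3 * 0.3 * t)
        assert fit_diffusion(scaled).d == pytest.approx(3 * fit_diffusion(series).d)

    def test_replicate_dispersion_reported(self):
        t = np.arange(0, 51, dtype=float)
        per = np.stack([0.30 * t, 0.36 * t])
        series = MSDSeries(t, per.mean(axis=0), per_replicate_msd=per)
        est = fit_diffusion(series)
        assert len(est.replicate_values) == 2
        assert est.replicate_values[0] == pytest.approx(0.30 / 6 * 10)
        assert est.replicate_sd > 0

    def test_negative_slope_flagged(self):
        t = np.arange(0, 51, dtype=float)
        est = fit_diffusion(MSDSeries(t, np.concatenate([[0.0], 100 - t[1:]])))
        assert est.negative_slope

    def test_window_outside_lags_rejected(self):
        series = MSDSeries(np.arange(0, 11, dtype=float), np.arange(0, 11, dtype=float))
        with pytest.raises(ValueError, match="window"):
            fit_diffusion(series, window=(5.0, 50.0))

    def test_doubled_frame_interval_same_physical_motion(self):
        """Subsampling every other frame leaves the fitted D unchanged."""
        spec = BrownianSpec(n_solutes=20, d_true=0.62, n_frames=1000, seed=31)
        traj, smap = simulate_brownian(spec, wrap=False)
        full = fit_diffusion(compute_msd(traj, smap, max_lag=2000.0))
        half_frames = traj.frames[::2]
        half = Trajectory(half_frames, frame_interval=20.0)
        sub = fit_diffusion(compute_msd(half, smap, max_lag=2000.0))
        assert sub.d == pytest.approx(full.d, rel=0.1)


class TestStokesEinstein:
    def test_round_trip_identity(self):
        d = 0.62
        r = stokes_einstein(d, WATER_EXPERIMENTAL)
        assert stokes_einstein(r, WATER_EXPERIMENTAL) == pytest.approx(d, abs=1e-12)

    def test_closed_form_scalar(self):
        # k_B T / (6 pi eta D): independent evaluation in SI
        expected = KB * 298.0 / (6 * np.pi * 0.00089 * 0.62e-9) * 1e10  # A
        assert stokes_einstein(0.62, WATER_EXPERIMENTAL) == pytest.approx(expected)
        assert stokes_einstein(0.62, WATER_EXPERIMENTAL) == pytest.approx(3.96, abs=0.01)

    def test_concentration_rh_increase_21_percent(self):
        """D falling 0.29 -> 0.24 reads as a 21% apparent R_H increase."""
        r_dilute = stokes_einstein(0.29, WATER_EXPERIMENTAL)
        r_50mM = stokes_einstein(0.24, WATER_EXPERIMENTAL)
        assert (r_50mM / r_dilute - 1) * 100 == pytest.approx(21, abs=0.9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            stokes_einstein(0.0, WATER_EXPERIMENTAL)


class TestFiniteBoxCorrection:
    def test_vanishes_for_large_box_and_monotone(self):
        c_small = finite_box_correction(0.0, TIP5P, 50.0)
        c_big = finite_box_correction(0.0, TIP5P, 5000.0)
        c_huge = finite_box_correction(0.0, TIP5P, 5e8)
        assert c_small > c_big > c_huge
        assert c_huge == pytest.approx(0.0, abs=1e-5)

    def test_closed_form_oracle(self):
        # independent SI evaluation at L = 87.34 A, TIP5P viscosity
        expected = KB * 298.0 * XI_CUBIC / (6 * np.pi * 0.0007 * 87.34e-10) / 1e-9
        assert finite_box_correction(0.0, TIP5P, 87.34) == pytest.approx(expected, rel=1e-12)
        assert finite_box_correction(0.5, TIP5P, 87.34) == pytest.approx(0.5 + expected)


class TestWelchT:
    def test_identical_samples(self):
        assert welch_t([1.0, 2, 3], [1.0, 2, 3]) == (0.0, 1.0)

    def test_antisymmetry(self):
        a, b = [0.1, 0.2, 0.3], [0.25, 0.35, 0.4]
        t1, p1 = welch_t(a, b)
        t2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_textbook_formula(self):
        """Welch statistic and Satterthwaite dof against the direct formula."""
        from scipy import stats as sps

        a = np.array([0.63, 0.62, 0.65, 0.61])
        b = np.array([0.70, 0.71, 0.68])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_direct = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p_direct = 2 * sps.t.sf(abs(t_direct), dof)
        t, p = welch_t(a, b)
        assert t == pytest.approx(t_direct, abs=1e-6)
        assert p == pytest.approx(p_direct, abs=1e-6)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
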