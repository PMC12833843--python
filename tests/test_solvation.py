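"""RDF, first-shell statistics, N1 and water occupancy grids."""

import numpy as np
import pytest

from glycodiff.core import SystemMap, Trajectory, TrajectoryFrame
from glycodiff.solvation import (
    RDFProfile,
    compute_rdf,
    first_shell_stats,
    integrate_N1,
    occupancy_map,
)
from glycodiff.synthetic import generate_ideal_solvent


def _system(coords, n_waters, box, solute_atoms=1):
    smap = SystemMap(
        solute_groups=[np.arange(solute_atoms)],
        water_oxygen_indices=np.arange(solute_atoms, solute_atoms + n_waters),
        masses=np.ones(solute_atoms + n_waters),
    )
    frames = [TrajectoryFrame(time=0.0, box_lengths=(box, box, box), coords=coords)]
    return Trajectory(frames, frame_interval=10.0), smap


class TestRDF:
    def test_ideal_gas_is_flat_unity(self):
        traj, smap = generate_ideal_solvent(3000, 30.0, seed=12, n_frames=60)
        prof = compute_rdf(traj, smap, bin_width=0.05)
        mask = (prof.bin_centers > 2.0) & (prof.bin_centers < prof.bin_centers[-1])
        assert prof.g[mask].mean() == pytest.approx(1.0, abs=0.02)

    def test_single_water_occupies_one_bin(self):
        coords = np.array([[10.0, 10, 10], [13.0, 10, 10]])  # one water at d = 3.0
        traj, smap = _system(coords, 1, 20.0)
        prof = compute_rdf(traj, smap, bin_width=0.1)
        occupied = np.nonzero(prof.g)[0]
        assert len(occupied) == 1
        assert prof.bin_centers[occupied[0]] == pytest.approx(3.0, abs=0.1)

    def test_density_normalization_cancels(self):
        """Doubling n_waters at fixed box leaves g(r) unchanged within noise."""
        t1, m1 = generate_ideal_solvent(2000, 25.0, seed=13, n_frames=40)
        t2, m2 = generate_ideal_solvent(4000, 25.0, seed=14, n_frames=40)
        g1 = compute_rdf(t1, m1, bin_width=0.25)
        g2 = compute_rdf(t2, m2, bin_width=0.25)
        mask = g1.bin_centers > 3.0
        assert g1.g[mask].mean() == pytest.approx(g2.g[mask].mean(), abs=0.02)

    def test_r_max_beyond_half_box_rejected(self):
        traj, smap = generate_ideal_solvent(100, 20.0, seed=0)
        with pytest.raises(ValueError, match="half"):
            compute_rdf(traj, smap, r_max=15.0)

    def test_translation_and_relabel_invariance(self):
        traj, smap = generate_ideal_solvent(500, 20.0, seed=15, n_frames=5)
        base = compute_rdf(traj, smap, bin_width=0.2)
        shifted_frames = [
            TrajectoryFrame(f.time, f.box_lengths, f.coords + 3.7) for f in traj.frames
        ]
        shifted = compute_rdf(Trajectory(shifted_frames, 10.0), smap, bin_width=0.2)
        assert np.allclose(base.g, shifted.g)


class TestFirstShell:
    @staticmethod
    def _bump_profile(center=4.68, width=0.4, bin_width=0.05, r_max=10.0):
        """Smooth surrogate RDF: excluded core, first peak, depression, bulk."""
        r = np.arange(bin_width / 2, r_max, bin_width)
        onset = 0.5 * (1 + np.tanh((r - 2.5) / 0.4))
        g = onset * (
            1.0
            + 0.8 * np.exp(-0.5 * ((r - center) / width) ** 2)
            - 0.25 * np.exp(-0.5 * ((r - center - 1.8) / 0.6) ** 2)
        )
        return RDFProfile(bin_centers=r, g=np.clip(g, 0, None), rho=0.033, bin_width=bin_width)

    def test_constructed_bump_located(self):
        prof = self._bump_profile(center=4.68)
        peak, peak_max, min_val, r_min = first_shell_stats(prof)
        assert peak == pytest.approx(4.68, abs=2 * prof.bin_width)
        assert peak_max > 1.5
        assert r_min > peak
        assert min_val < 1.0

    def test_two_bump_minimum_between(self):
        bin_width = 0.05
        r = np.arange(bin_width / 2, 12.0, bin_width)
        onset = 0.5 * (1 + np.tanh((r - 2.5) / 0.4))
        g = onset * (
            1.0
            + 0.8 * np.exp(-0.5 * ((r - 4.0) / 0.4) ** 2)
            + 0.4 * np.exp(-0.5 * ((r - 7.0) / 0.5) ** 2)
        )
        prof = RDFProfile(bin_centers=r, g=g, rho=0.033, bin_width=bin_width)
        _, _, _, r_min = first_shell_stats(prof)
        assert 4.0 < r_min < 7.0

    def test_flat_profile_rejected(self):
        r = np.arange(0.025, 10.0, 0.05)
        prof = RDFProfile(bin_centers=r, g=np.ones_like(r), rho=0.033, bin_width=0.05)
        with pytest.raises(ValueError, match="maximum"):
            first_shell_stats(prof)


class TestN1:
    def test_uniform_g_analytic(self):
        """g = 1 integrates to the uniform-density sphere count exactly."""
        bin_width = 0.05
        r = np.arange(bin_width / 2, 10.0, bin_width)
        rho = 0.0334
        prof = RDFProfile(bin_centers=r, g=np.ones_like(r), rho=rho, bin_width=bin_width)
        r_min = 5.0
        assert integrate_N1(prof, r_min=r_min) == pytest.approx(
            4 / 3 * np.pi * rho * r_min**3, rel=1e-9
        )

    def test_ideal_gas_within_one_percent(self):
        traj, smap = generate_ideal_solvent(2000, 30.0, seed=16, n_frames=100)
        prof = compute_rdf(traj, smap, bin_width=0.05)
        r_min = 10.0
        analytic = 4 / 3 * np.pi * prof.rho * r_min**3
        assert integrate_N1(prof, r_min=r_min) == pytest.approx(analytic, rel=0.01)

    def test_constructed_shell_counts_exactly(self):
        """k waters placed inside r_min integrate to N1 = k."""
        k, box = 7, 30.0
        rng = np.random.default_rng(17)
        dirs = rng.normal(size=(k, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        shell = box / 2 + dirs * rng.uniform(2.5, 3.5, k)[:, None]
        far = box / 2 + rng.normal(size=(40, 3)) * 0.5 + np.array([9.0, 0, 0])
        coords = np.vstack([[[box / 2] * 3], shell, far])
        traj, smap = _system(coords, k + 40, box)
        prof = compute_rdf(traj, smap, bin_width=0.05)
        assert integrate_N1(prof, r_min=5.0) == pytest.approx(k, abs=1e-9)

    def test_density_linearity(self):
        bin_width = 0.05
        r = np.arange(bin_width / 2, 8.0, bin_width)
        g = np.ones_like(r)
        p1 = RDFProfile(bin_centers=r, g=g, rho=0.02, bin_width=bin_width)
        p2 = RDFProfile(bin_centers=r, g=g, rho=0.04, bin_width=bin_width)
        assert integrate_N1(p2, r_min=3.0) == pytest.approx(2 * integrate_N1(p1, r_min=3.0))

    def test_missing_r_min_rejected(self):
        r = np.arange(0.025, 5.0, 0.05)
        prof = RDFProfile(bin_centers=r, g=np.ones_like(r), rho=0.03, bin_width=0.05)
        with pytest.raises(ValueError, match="r_min"):
            integrate_N1(prof)


class TestOccupancyMap:
    def test_static_water_peaks_at_its_position(self):
        box = 20.0
        coords = np.array([[10.0, 10, 10], [12.0, 10, 10]])
        traj, smap = _system(coords, 1, box)
        grid = occupancy_map(traj, smap, grid_edge=10.0, spacing=0.5, align=False)
        peak = np.unravel_index(np.argmax(grid.values), grid.values.shape)
        peak_pos = grid.origin + (np.array(peak) + 0.5) * grid.spacing
        assert np.allclose(peak_pos, [12.0, 10, 10], atol=grid.spacing)

    def test_deposited_mass_conserved(self):
        """Voxel sum x voxel volume ~ number of waters inside the grid."""
        box = 30.0
        rng = np.random.default_rng(18)
        waters = box / 2 + rng.uniform(-4, 4, size=(25, 3))
        coords = np.vstack([[[box / 2] * 3], waters])
        traj, smap = _system(coords, 25, box)
        grid = occupancy_map(traj, smap, grid_edge=25.0, spacing=0.5, sigma=1.0, align=False)
        assert grid.values.sum() * grid.voxel_volume == pytest.approx(25, rel=1e-3)

    def test_translation_equivariance(self):
        box = 40.0
        rng = np.random.default_rng(19)
        waters = box / 2 + rng.uniform(-3, 3, size=(10, 3))
        coords = np.vstack([[[box / 2] * 3], waters])
        traj1, smap = _system(coords, 10, box)
        traj2, _ = _system(coords + 2.5, 10, box)
        g1 = occupancy_map(traj1, smap, grid_edge=15.0, spacing=0.5, align=False)
        g2 = occupancy_map(traj2, smap, grid_edge=15.0, spacing=0.5, align=False)
        assert np.allclose(g1.values, g2.values, atol=1e-9)

    def test_alignment_cancels_rigid_motion(self):
        """A solute tumbling rigidly with its waters gives the static map."""
        from scipy.spatial.transform import Rotation

        box = 40.0
        rng = np.random.default_rng(20)
        solute = box / 2 + rng.uniform(-1.5, 1.5, size=(4, 3))
        waters = box / 2 + rng.uniform(-3, 3, size=(8, 3))
        base = np.vstack([solute, waters])
        center = solute.mean(axis=0)
        frames = []
        for k in range(4):
            rot = Rotation.from_euler("z", 25 * k, degrees=True).as_matrix()
            moved = (base - center) @ rot.T + center + k * np.array([0.5, 0.2, 0.0])
            frames.append(TrajectoryFrame(time=k * 10.0, box_lengths=(box,) * 3, coords=moved))
        smap = SystemMap(
            solute_groups=[np.arange(4)],
            water_oxygen_indices=np.arange(4, 12),
            masses=np.ones(12),
        )
        traj = Trajectory(frames, frame_interval=10.0)
        static = occupancy_map(
            Trajectory(frames[:1], 10.0), smap, grid_edge=15.0, spacing=0.5, align=False
        )
        aligned = occupancy_map(traj, smap, grid_edge=15.0, spacing=0.5, align=True)
        assert np.allclose(aligned.values, static.values, atol=1e-6)

    def test_empty_water_set_rejected(self):
        coords = np.array([[0.0, 0, 0]])
        smap = SystemMap(
            solute_groups=[np.array([0])],
            water_oxygen_indices=np.array([], dtype=int),
            masses=np.ones(1),
        )
        traj = Trajectory(
            [TrajectoryFrame(time=0.0, box_lengths=(10, 10, 10), coords=coords)], 10.0
        )
        with pytest.raises(ValueError, match="water"):
            occupancy_map(traj, smap)
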