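"""Superposition, RMSD/RMSF analytics and trajectory dipole statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import biofet
from biofet import synthetic_data as syn
from biofet import trajectory_analysis as ta
from biofet.errors import (
    ConfigurationError,
    EmptyAnalysisError,
    SuperpositionError,
)
from conftest import quaternion_superpose_rmsd, random_coords


class TestSuperpose:
    def test_identical_sets(self):
        rng = np.random.default_rng(0)
        x = random_coords(rng)
        r_mat, t, rmsd = ta.superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(r_mat, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_rigid_copy_recovers_zero_rmsd(self):
        rng = np.random.default_rng(1)
        x = random_coords(rng)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = x @ rot.T + np.array([5.0, -3.0, 2.0])
        r_mat, t, rmsd = ta.superpose(x, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(moved @ r_mat.T + t, x, atol=1e-8)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a, b = random_coords(rng), random_coords(rng)
            _, _, rmsd = ta.superpose(a, b)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(a, b), abs=1e-8)

    def test_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(3)
        a, b = random_coords(rng), random_coords(rng)
        _, _, r_ab = ta.superpose(a, b)
        _, _, r_ba = ta.superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.normal(size=3) * 10
        _, _, r_common = ta.superpose(a @ rot.T + shift, b @ rot.T + shift)
        assert r_common == pytest.approx(r_ab, abs=1e-9)

    def test_proper_rotation_only(self):
        rng = np.random.default_rng(4)
        a = random_coords(rng)
        mirrored = a * np.array([1.0, 1.0, -1.0])
        r_mat, _, _ = ta.superpose(a, mirrored)
        assert np.linalg.det(r_mat) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SuperpositionError):
            ta.superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(SuperpositionError):
            ta.superpose(line, line + 1.0)


class TestRmsdSeries:
    def test_frozen_trajectory_all_zero(self, bead_tetramer):
        frames = np.repeat(bead_tetramer.positions[None], 5, axis=0)
        traj = ta.Trajectory(bead_tetramer, frames)
        assert np.allclose(ta.rmsd_series(traj), 0.0, atol=1e-10)

    def test_single_frame_vs_itself(self, bead_tetramer):
        traj = ta.Trajectory(bead_tetramer, bead_tetramer.positions[None])
        series = ta.rmsd_series(traj)
        assert series.shape == (1,) and series[0] == pytest.approx(0.0, abs=1e-10)

    def test_wobble_matches_gaussian_expectation(self, bead_tetramer):
        # Against the noiseless base structure each CA deviates by an
        # isotropic Gaussian, so E[RMSD] -> sigma*sqrt(3) over many atoms.
        sigma = 1.1547
        spec = syn.WobbleSpec(structure=bead_tetramer, n_frames=2000, seed=9,
                              sigma=sigma, loop_regimes={})
        traj = syn.gen_wobble_trajectory(spec)
        series = ta.rmsd_series(traj, reference=bead_tetramer.positions)
        assert series.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestRmsf:
    def test_frozen_atoms_zero(self, bead_tetramer):
        frames = np.repeat(bead_tetramer.positions[None], 4, axis=0)
        profile = ta.rmsf(ta.Trajectory(bead_tetramer, frames), trim_fraction=0.0)
        assert np.allclose(profile.per_atom, 0.0, atol=1e-10)

    def test_isotropic_wobble_rmsf_is_sigma_root_three(self, bead_tetramer):
        sigma = 1.1547
        spec = syn.WobbleSpec(structure=bead_tetramer, n_frames=2000, seed=5,
                              sigma=sigma, loop_regimes={})
        profile = ta.rmsf(syn.gen_wobble_trajectory(spec), trim_fraction=0.0)
        loop_free = profile.per_residue.rmsf_A.to_numpy()
        assert loop_free.mean() == pytest.approx(2.0, rel=0.05)

    def test_open_closed_loop_contrast(self, bead_tetramer):
        # open sigma 2.31 A and closed sigma 1.155 A per axis yield loop
        # RMSF of about 4 A vs about 2 A (sigma*sqrt(3)).
        out = {}
        for regime in ("open", "closed"):
            spec = syn.WobbleSpec(structure=bead_tetramer, n_frames=600,
                                  seed=31, sigma=0.5, regime=regime)
            prof = ta.rmsf(syn.gen_wobble_trajectory(spec), trim_fraction=0.1)
            out[regime] = prof.per_loop
        assert out["open"]["L3,4"] == pytest.approx(4.0, rel=0.1)
        assert out["closed"]["L3,4"] == pytest.approx(2.0, rel=0.1)
        assert out["open"]["pooled"] / out["closed"]["pooled"] == pytest.approx(
            2.0, rel=0.15)

    def test_rigid_motion_invariance(self, bead_tetramer):
        base = syn.WobbleSpec(structure=bead_tetramer, n_frames=60, seed=8,
                              sigma=0.4, loop_regimes={})
        moved = syn.WobbleSpec(structure=bead_tetramer, n_frames=60, seed=8,
                               sigma=0.4, loop_regimes={}, rigid_motion=True)
        p0 = ta.rmsf(syn.gen_wobble_trajectory(base), trim_fraction=0.0).per_atom
        p1 = ta.rmsf(syn.gen_wobble_trajectory(moved), trim_fraction=0.0).per_atom
        assert np.allclose(p0, p1, atol=1e-8)

    def test_parseval_msd_equals_summed_axis_variances(self, quiet_wobble):
        # mean squared displacement about the time mean equals the sum of
        # per-axis variances, frame-aligned data (no rigid motion applied).
        frames = quiet_wobble.frames
        msd = ((frames - frames.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0)
        axis_var = frames.var(axis=0).sum(axis=1)
        assert np.allclose(msd, axis_var, rtol=1e-10)

    def test_trim_reduces_frames_and_zero_trim_is_identity(self, quiet_wobble):
        full = ta.rmsf(quiet_wobble, trim_fraction=0.0)
        trimmed = ta.rmsf(quiet_wobble, trim_frames=50)
        assert trimmed.n_frames_used == full.n_frames_used - 50
        again = ta.rmsf(quiet_wobble, trim_frames=0)
        assert np.allclose(again.per_atom, full.per_atom)

    def test_overtrim_raises(self, quiet_wobble):
        with pytest.raises(EmptyAnalysisError):
            ta.rmsf(quiet_wobble, trim_frames=quiet_wobble.n_frames)


class TestTrajectoryDipoleStats:
    def test_static_replication_zero_sd(self, bead_tetramer):
        frames = np.repeat(bead_tetramer.positions[None], 6, axis=0)
        stats = ta.trajectory_dipole_stats(
            ta.Trajectory(bead_tetramer, frames), trim_fraction=0.0)
        assert stats.sd == pytest.approx(0.0, abs=1e-9)
        assert stats.mean == pytest.approx(154.0, rel=1e-9)

    def test_recovers_generator_truth_within_two_se(self, bead_tetramer):
        spec = syn.WobbleSpec(structure=bead_tetramer, n_frames=400, seed=13,
                              sigma=0.25, loop_regimes={},
                              dipole_fluctuation_d=35.0)
        stats = ta.trajectory_dipole_stats(syn.gen_wobble_trajectory(spec),
                                           trim_fraction=0.1)
        n = len(stats.series)
        se = stats.sd / np.sqrt(n)
        assert abs(stats.mean - 154.0) <= 2 * se
        assert stats.sd == pytest.approx(35.0, rel=0.25)

    def test_bound_unbound_contrast_doubles(self):
        bound = biofet.gen_bead_tetramer(target_dipole=283.0, seed=2)
        unbound = biofet.gen_bead_tetramer(target_dipole=154.0, seed=2)
        kw = dict(n_frames=100, seed=3, sigma=0.25, loop_regimes={},
                  dipole_fluctuation_d=33.0)
        sb = ta.trajectory_dipole_stats(
            syn.gen_wobble_trajectory(syn.WobbleSpec(structure=bound, **kw)),
            trim_fraction=0.1)
        su = ta.trajectory_dipole_stats(
            syn.gen_wobble_trajectory(syn.WobbleSpec(structure=unbound, **kw)),
            trim_fraction=0.1)
        assert sb.mean / su.mean == pytest.approx(283.0 / 154.0, rel=0.1)

    def test_missing_charges_rejected(self, bead_tetramer):
        from dataclasses import replace
        uncharged = replace(bead_tetramer, provenance=None)
        traj = ta.Trajectory(uncharged, np.repeat(uncharged.positions[None], 3, 0))
        with pytest.raises(ConfigurationError):
            ta.trajectory_dipole_stats(traj, trim_fraction=0.0)
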