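import numpy as np
import pytest

from pdzflex.errors import EmptySelectionError, MismatchedResiduesError
from pdzflex.profiles import ResidueProfile
from pdzflex.rmsf import (
    Trajectory,
    aggregate_replicates,
    flag_high_rmsf,
    nm_to_angstrom,
    read_trajectory_tsv,
    rmsf,
    select_frames,
    write_trajectory_tsv,
)
from pdzflex.synthetic import make_scaffold, make_trajectory

from conftest import random_rotation


def static_trajectory(n_frames=10, n_res=12, seed=0):
    scaffold = make_scaffold(n_res, seed)
    frames = np.repeat(scaffold[None], n_frames, axis=0)
    return Trajectory("static", np.arange(n_frames) * 100.0, frames, np.arange(1, n_res + 1))


class TestSelectFrames:
    def test_production_window_frame_count(self):
        """0..200 ns at 100 ps spacing, window = final 160 ns -> 1601 frames."""
        times = np.arange(0, 200_001, 100, dtype=float)
        frames = np.zeros((times.size, 4, 3))
        frames[:, :, 0] = np.arange(4)[None, :] * 3.8
        traj = Trajectory("r", times, frames, np.arange(1, 5))
        sel = select_frames(traj, 40_000.0, 200_000.0, 100.0)
        assert sel.n_frames == 1601
        assert sel.times[0] == 40_000.0 and sel.times[-1] == 200_000.0

    def test_native_stride_is_pure_window_cut(self):
        traj = static_trajectory(n_frames=20)
        sel = select_frames(traj, 500.0, 1200.0, 100.0)
        assert np.array_equal(sel.times, traj.times[(traj.times >= 500) & (traj.times <= 1200)])

    def test_coarser_stride_subsamples(self):
        traj = static_trajectory(n_frames=21)
        sel = select_frames(traj, 0.0, 2000.0, 500.0)
        assert np.array_equal(sel.times, [0.0, 500.0, 1000.0, 1500.0, 2000.0])

    def test_empty_window_raises(self):
        traj = static_trajectory(n_frames=5)
        with pytest.raises(EmptySelectionError):
            select_frames(traj, 10_000.0, 20_000.0, 100.0)


class TestRmsf:
    def test_static_trajectory_zero_everywhere(self):
        prof = rmsf(static_trajectory())
        assert np.allclose(prof.values, 0.0, atol=1e-12)

    def test_two_frame_hand_case(self):
        """Atom i at +/- a along x about its mean, rigid elsewhere -> RMSF_i = a."""
        scaffold = make_scaffold(10, seed=1)
        a = 0.8
        f1, f2 = scaffold.copy(), scaffold.copy()
        f1[4, 0] += a
        f2[4, 0] -= a
        traj = Trajectory("r", np.array([0.0, 100.0]), np.stack([f1, f2]), np.arange(10))
        fit = np.array([i for i in range(10) if i != 4])
        prof = rmsf(traj, fit_selection=fit)
        assert prof.values[4] == pytest.approx(a, abs=1e-8)
        assert np.allclose(prof.values[fit], 0.0, atol=1e-8)

    def test_gaussian_noise_converges_to_sigma_root3(self):
        """iid per-coordinate noise sigma -> RMSF ~ sigma * sqrt(3)."""
        sigma, n_frames, n_res = 0.4, 1600, 160
        traj = make_trajectory(n_frames, np.full(n_res, sigma), seed=11)
        prof = rmsf(traj)
        se = sigma * np.sqrt(1.0 / (2 * n_frames))  # delta-method SE per residue
        assert abs(prof.values.mean() - sigma * np.sqrt(3)) <= 3 * se

    def test_fixed_rigid_motion_leaves_rmsf_unchanged(self):
        traj = make_trajectory(100, np.full(20, 0.3), seed=5)
        base = rmsf(traj)
        rng = np.random.default_rng(6)
        rot = random_rotation(rng)
        moved = Trajectory(
            "r",
            traj.times,
            traj.frames @ rot.T + np.array([5.0, -3.0, 2.0]),
            traj.residue_numbers,
        )
        assert np.allclose(rmsf(moved).values, base.values, atol=1e-8)

    def test_per_frame_random_motions_undone_by_fitting(self):
        """Random rigid motion per frame on a rigid scaffold fits back to ~0."""
        scaffold = make_scaffold(30, seed=2)
        rng = np.random.default_rng(3)
        frames = np.stack(
            [
                scaffold @ random_rotation(rng).T + rng.normal(scale=5, size=3)
                for _ in range(40)
            ]
        )
        traj = Trajectory("r", np.arange(40) * 100.0, frames, np.arange(30))
        assert rmsf(traj).values.max() <= 1e-6

    def test_measure_selection_restricts_profile(self):
        traj = make_trajectory(50, np.full(20, 0.2), seed=7)
        prof = rmsf(traj, measure_selection=np.arange(5, 10))
        assert np.array_equal(prof.residues, traj.residue_numbers[5:10])


class TestAggregateReplicates:
    def test_identical_profiles_sd_zero(self):
        prof = ResidueProfile(np.arange(5), np.full(5, 0.3), kind="rmsf")
        agg = aggregate_replicates([prof] * 5)
        assert np.allclose(agg.sd.values, 0.0)
        assert np.allclose(agg.mean.values, 0.3)

    def test_population_sd_of_two(self):
        """Values v and v+2 -> mean v+1, population sd 1."""
        p1 = ResidueProfile(np.arange(4), np.full(4, 0.5), kind="rmsf")
        p2 = ResidueProfile(np.arange(4), np.full(4, 2.5), kind="rmsf")
        agg = aggregate_replicates([p1, p2])
        assert np.allclose(agg.mean.values, 1.5)
        assert np.allclose(agg.sd.values, 1.0)

    def test_single_profile(self):
        prof = ResidueProfile(np.arange(4), np.array([0.1, 0.2, 0.3, 0.4]), kind="rmsf")
        agg = aggregate_replicates([prof])
        assert np.allclose(agg.mean.values, prof.values)
        assert np.allclose(agg.sd.values, 0.0)

    def test_mismatched_residues_rejected(self):
        p1 = ResidueProfile(np.arange(4), np.zeros(4), kind="rmsf")
        p2 = ResidueProfile(np.arange(1, 5), np.zeros(4), kind="rmsf")
        with pytest.raises(MismatchedResiduesError):
            aggregate_replicates([p1, p2])


class TestFlagHighRmsf:
    def test_uniform_low_flags_nothing(self):
        prof = ResidueProfile(np.arange(20), np.full(20, 0.05), kind="rmsf")
        assert flag_high_rmsf(prof) == []

    def test_elevated_span_flagged(self):
        values = np.full(20, 0.05)
        values[6:10] = 0.2
        prof = ResidueProfile(np.arange(20), values, kind="rmsf")
        assert [(r.first, r.last) for r in flag_high_rmsf(prof)] == [(6, 9)]

    def test_exact_threshold_excluded(self):
        prof = ResidueProfile(np.arange(10), np.full(10, 0.12), kind="rmsf")
        assert flag_high_rmsf(prof, threshold=0.12) == []


def test_tandem_restraint_lowers_interface_rmsf():
    """Cross-domain restraints suppress interface fluctuation vs single domain."""
    residues = np.arange(114, 194)
    sigma = np.full(residues.size, 0.05)
    sigma[(residues >= 132) & (residues <= 135)] = 0.4
    lower = 0
    for seed in range(5):
        single = rmsf(make_trajectory(300, sigma, seed=seed, residue_numbers=residues))
        tandem = rmsf(
            make_trajectory(
                300, sigma, seed=seed + 100, residue_numbers=residues,
                restrained_regions=[(132, 135)],
            )
        )
        iface = (residues >= 132) & (residues <= 135)
        lower += tandem.values[iface].mean() < single.values[iface].mean()
    assert lower == 5


def test_trajectory_tsv_round_trip(tmp_path):
    traj = make_trajectory(5, np.full(8, 0.3), seed=9, residue_numbers=np.arange(114, 122))
    path = tmp_path / "traj.tsv"
    write_trajectory_tsv(traj, path)
    back = read_trajectory_tsv(path, replicate_id="r")
    assert np.array_equal(back.residue_numbers, traj.residue_numbers)
    assert np.allclose(back.frames, traj.frames, atol=1e-6)
    assert np.allclose(back.times, traj.times)


def test_nm_converter():
    assert np.allclose(nm_to_angstrom(np.ones((2, 3)) * 0.38), 3.8)
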