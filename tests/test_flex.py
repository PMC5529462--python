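import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from serpinflex import flex, synthetic
from serpinflex.flex import (
    DeviationHistogram,
    FitError,
    FlexProfile,
    MissingResidueError,
    average_structure,
    bin_deviations,
    per_frame_residue_deviation,
    pool_deviations,
    replicate_stats,
    rmsd_series_vs_first,
    rmsf_per_residue,
    superpose,
)
from serpinflex.traj_io import Trajectory

from conftest import make_trajectory, random_rigid_transform


def oracle_min_rmsd(mobile, reference):
    """Numerically minimize RMSD over rotations (rotation-vector
    parameterization, centroid-optimal translation); independent of the
    SVD-based implementation."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)

    def cost(rv):
        moved = Rotation.from_rotvec(rv).apply(P)
        return np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(12345)
    for start in [np.zeros(3), *rng.uniform(-np.pi, np.pi, size=(6, 3))]:
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_identity(self):
        coords = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = superpose(coords, coords)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)

    def test_recovers_applied_transform(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(10, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ Rz.T + np.array([1.0, 2.0, 3.0])
        R, t, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        # returned transform maps mobile back onto the reference
        np.testing.assert_allclose(mobile @ R.T + t, ref, atol=1e-10)

    def test_matches_numerical_minimization_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            ref = rng.normal(scale=5.0, size=(10, 3))
            mobile = ref + rng.normal(scale=0.3, size=(10, 3))
            _, _, rmsd = superpose(mobile, ref)
            assert rmsd == pytest.approx(oracle_min_rmsd(mobile, ref),
                                         abs=1e-3)

    def test_rotation_is_proper_even_for_reflections(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3))
        mobile = ref.copy()
        mobile[:, 2] *= -1  # mirror image
        R, _, _ = superpose(mobile, ref)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("coords", [
        np.zeros((2, 3)),
        np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)]),
    ], ids=["too-few", "collinear"])
    def test_degenerate_geometry(self, coords):
        with pytest.raises(FitError):
            superpose(coords, coords)


class TestRmsdSeries:
    def test_first_frame_zero_and_rigid_frames_zero(self):
        rng = np.random.default_rng(4)
        base = rng.normal(scale=4.0, size=(10, 3))
        frames = [base]
        for _ in range(4):
            R, t = random_rigid_transform(rng)
            frames.append(base @ R.T + t)
        traj = make_trajectory(np.stack(frames))
        series = rmsd_series_vs_first(traj)
        assert series[0] == 0.0
        np.testing.assert_allclose(series, 0.0, atol=1e-8)

    def test_matches_hand_computed_deviations(self):
        # anchors pin the fit; one atom moves by a known amount per frame
        anchors = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                            [10, 10, 0], [10, 0, 10], [0, 10, 10],
                            [10, 10, 10], [5, 5, 0]], dtype=float)
        probe = np.array([5.0, 5.0, 5.0])
        disp = [0.0, 1.0, 2.0, 0.5, 3.0]
        frames = []
        for d in disp:
            coords = np.vstack([anchors, probe + [d, 0, 0]])
            frames.append(coords)
        traj = make_trajectory(np.stack(frames))
        fit = list(range(9))
        series = rmsd_series_vs_first(traj, fit_indices=fit,
                                      measure_indices=[9])
        np.testing.assert_allclose(series, disp, atol=1e-10)

    def test_measure_set_can_exclude_mobile_residues(self):
        rng = np.random.default_rng(5)
        base = rng.normal(scale=5.0, size=(12, 3))
        frames = np.repeat(base[None], 4, axis=0).copy()
        frames[1:, -2:, :] += 5.0  # a mobile loop
        traj = make_trajectory(frames)
        full = rmsd_series_vs_first(traj, fit_indices=list(range(10)))
        loopless = rmsd_series_vs_first(traj, fit_indices=list(range(10)),
                                        measure_indices=list(range(10)))
        assert np.all(loopless[1:] <= full[1:])
        np.testing.assert_allclose(loopless, 0.0, atol=1e-10)


class TestAverageStructure:
    def test_single_frame_is_identity(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(size=(7, 3))
        traj = make_trajectory(coords[None])
        np.testing.assert_allclose(average_structure(traj), coords,
                                   atol=1e-12)

    def test_breathing_mode_recovers_midpoint(self):
        # symmetric expansion/contraction about the centroid: the optimal
        # fit is exactly the identity, so the average is the midpoint
        rng = np.random.default_rng(7)
        m = rng.normal(scale=5.0, size=(9, 3))
        c = m.mean(axis=0)
        frames = np.stack([c + 0.9 * (m - c), c + 1.1 * (m - c)])
        traj = make_trajectory(frames)
        np.testing.assert_allclose(average_structure(traj), m, atol=1e-9)

    def test_noise_average_converges_to_reference(self):
        # compact geometry keeps the per-frame alignment bias small; the
        # average is compared to the noise-free reference after a final
        # fit because it lives in the first frame's (noisy) orientation
        rng = np.random.default_rng(8)
        base = rng.normal(scale=3.0, size=(40, 3))
        frames = base[None] + rng.normal(scale=0.1, size=(1000, 40, 3))
        traj = make_trajectory(frames)
        avg = average_structure(traj)
        _, _, resid = superpose(avg, base)
        # statistical oracle: per-coordinate error sigma/sqrt(1000), so
        # the fitted RMSD is ~sqrt(3)*sigma/sqrt(1000); 5x margin
        assert resid < 5 * np.sqrt(3) * 0.1 / np.sqrt(1000)


class TestRmsf:
    def test_static_trajectory_is_zero(self, toy_ca_chain):
        frames = np.repeat(toy_ca_chain.coords[None], 5, axis=0)
        traj = Trajectory(toy_ca_chain, frames, 2.0)
        profile = rmsf_per_residue(traj)
        np.testing.assert_allclose(profile.values, 0.0, atol=1e-12)

    def test_two_frame_symmetric_displacement_gives_one_angstrom(self):
        anchors = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                            [10, 10, 0], [5, 0, 5]], dtype=float)
        probe = np.array([5.0, 5.0, 5.0])
        f0 = np.vstack([anchors, probe - [1, 0, 0]])
        f1 = np.vstack([anchors, probe + [1, 0, 0]])
        traj = make_trajectory(np.stack([f0, f1]))
        profile = rmsf_per_residue(traj, fit_indices=list(range(6)))
        assert profile.values[-1] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(profile.values[:-1], 0.0, atol=1e-9)

    def test_white_noise_closed_form(self):
        # per-axis sigma 0.5 -> RMSF = 0.5 * sqrt(3); near-rigid anchors
        # bound the superposition bias
        n_res = 60
        sigma = np.full(n_res, 0.5)
        sigma[:20] = 1e-3
        structure = synthetic.build_toy_chain(n_res, ca_only=True)
        spec = synthetic.FluctuationSpec(sigma=sigma, seed=9)
        traj, _ = synthetic.generate_trajectory(structure, spec, 5000)
        profile = rmsf_per_residue(traj)
        expected = 0.5 * np.sqrt(3.0)
        assert np.all(np.abs(profile.values[20:] / expected - 1) < 0.05)

    def test_missing_ca_lists_residues(self, toy_ca_chain):
        frames = np.repeat(toy_ca_chain.coords[None], 2, axis=0)
        traj = Trajectory(toy_ca_chain, frames, 2.0)
        with pytest.raises(MissingResidueError) as err:
            rmsf_per_residue(traj, target_res_nums=[1, 2, 999])
        assert err.value.res_nums == [999]

    def test_rigid_body_invariance(self):
        structure = synthetic.build_toy_chain(30, ca_only=True)
        spec = synthetic.FluctuationSpec(sigma=0.3, seed=10)
        traj, _ = synthetic.generate_trajectory(structure, spec, 200)
        base = rmsf_per_residue(traj)
        rng = np.random.default_rng(11)
        R, t = random_rigid_transform(rng)
        moved = Trajectory(structure, traj.frames @ R.T + t, 2.0)
        np.testing.assert_allclose(rmsf_per_residue(moved).values,
                                   base.values, atol=1e-6)


class TestDeviationsAndBins:
    def test_zero_when_avg_equals_frames(self, toy_ca_chain):
        frames = np.repeat(toy_ca_chain.coords[None], 4, axis=0)
        traj = Trajectory(toy_ca_chain, frames, 2.0)
        dev = per_frame_residue_deviation(traj, toy_ca_chain.coords)
        np.testing.assert_allclose(dev.matrix, 0.0, atol=1e-12)

    def test_known_single_displacement(self):
        anchors = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10],
                            [10, 10, 10]], dtype=float)
        probe = np.array([5.0, 5.0, 5.0])
        avg = np.vstack([anchors, probe])
        frames = np.repeat(avg[None], 3, axis=0).copy()
        frames[1, 5] = probe + [0, 0, 2.0]
        traj = make_trajectory(frames)
        dev = per_frame_residue_deviation(traj, avg,
                                          fit_indices=list(range(5)))
        assert dev.matrix[1, 5] == pytest.approx(2.0, abs=1e-10)

    def test_stride_must_divide_interval(self, toy_ca_chain):
        frames = np.repeat(toy_ca_chain.coords[None], 10, axis=0)
        traj = Trajectory(toy_ca_chain, frames, 2.0)
        with pytest.raises(ValueError, match="stride"):
            per_frame_residue_deviation(traj, toy_ca_chain.coords,
                                        stride_ps=3.0)

    def test_rmsf_squared_equals_mean_squared_deviation(self):
        structure = synthetic.build_toy_chain(25, ca_only=True)
        spec = synthetic.FluctuationSpec(sigma=0.4, seed=12)
        traj, _ = synthetic.generate_trajectory(structure, spec, 300)
        profile = rmsf_per_residue(traj)
        avg = average_structure(traj)
        dev = per_frame_residue_deviation(traj, avg)
        np.testing.assert_allclose(profile.values ** 2,
                                   (dev.matrix ** 2).mean(axis=0),
                                   rtol=1e-9)

    def test_all_mass_in_one_bin(self):
        matrix = np.full((50, 3), 0.37)
        hist = bin_deviations(matrix, bin_width=0.1)
        j = int(0.37 / 0.1)
        assert np.all(hist.fractions[:, j] == 100.0)
        np.testing.assert_allclose(hist.means, 0.37)

    def test_uniform_deviations_fill_bins_evenly(self):
        rng = np.random.default_rng(13)
        n = 20000
        matrix = rng.uniform(0, 1, size=(n, 2))
        hist = bin_deviations(matrix, bin_width=0.1)
        # multinomial oracle: each bin p=0.1, 3 sigma band
        sd = 100 * np.sqrt(0.1 * 0.9 / n)
        assert hist.fractions.shape[1] == 10
        assert np.all(np.abs(hist.fractions - 10.0) < 3 * sd)

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(14)
        hist = bin_deviations(rng.exponential(0.5, size=(500, 7)))
        np.testing.assert_allclose(hist.fractions.sum(axis=1), 100.0,
                                   atol=1e-9)

    def test_rare_excursions_recover_event_rate(self):
        # frequent ~0.3 A noise plus 5%-rate 3 A excursions
        rng = np.random.default_rng(15)
        n = 20000
        base = np.abs(rng.normal(0.3, 0.05, size=(n, 1)))
        excited = rng.random((n, 1)) < 0.05
        matrix = np.where(excited, 3.0 + rng.normal(0, 0.05, size=(n, 1)),
                          base)
        hist = bin_deviations(matrix, bin_width=0.1)
        high = hist.fractions[0, hist.bin_edges[:-1] >= 1.5].sum()
        sd = 100 * np.sqrt(0.05 * 0.95 / n)
        assert abs(high - 5.0) < 3 * sd

    def test_pooled_replicates_stack_rows(self):
        mats = [flex.DeviationMatrix(np.zeros((10, 4)) + i, [1, 2, 3, 4],
                                     200.0) for i in range(4)]
        pooled = pool_deviations(mats)
        assert pooled.matrix.shape == (40, 4)

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            bin_deviations(np.ones((3, 2)), bin_width=0.0)


class TestReplicateStats:
    def test_identical_replicates_have_zero_sd(self):
        p = FlexProfile([1, 2, 3], np.array([0.5, 1.0, 1.5]))
        mean, sd = replicate_stats([p, p, p])
        np.testing.assert_allclose(mean.values, p.values)
        np.testing.assert_allclose(sd.values, 0.0, atol=1e-12)

    def test_two_replicate_hand_values(self):
        a = FlexProfile([7], np.array([1.0]))
        b = FlexProfile([7], np.array([3.0]))
        mean, sd = replicate_stats([a, b])
        assert mean.values[0] == pytest.approx(2.0)
        assert sd.values[0] == pytest.approx(np.sqrt(2.0))

    def test_four_replicates_match_brute_force(self):
        rng = np.random.default_rng(16)
        values = rng.uniform(0, 2, size=(4, 10))
        profiles = [FlexProfile(list(range(10)), v) for v in values]
        mean, sd = replicate_stats(profiles)
        for i in range(10):
            col = values[:, i]
            m = sum(col) / 4
            s = np.sqrt(sum((x - m) ** 2 for x in col) / 3)
            assert mean.values[i] == pytest.approx(m)
            assert sd.values[i] == pytest.approx(s)

    def test_mismatched_residues_rejected(self):
        a = FlexProfile([1, 2], np.array([0.1, 0.2]))
        b = FlexProfile([1, 3], np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            replicate_stats([a, b])


def test_histogram_rejects_bad_fractions():
    with pytest.raises(ValueError):
        DeviationHistogram([1], 0.1, np.array([0.0, 0.1]),
                           np.array([[50.0]]), np.array([0.05]))
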