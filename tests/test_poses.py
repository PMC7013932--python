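"""Superposition, RMSD, clustering, state assignment, unbound fractions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepbind import poses, synthetic
from pepbind.poses import (
    PoseEnsemble,
    StateSeries,
    assign_states,
    cluster_poses,
    derive_bound_cutoff,
    ensemble_unbound_fraction,
    pairwise_rmsd_matrix,
    rmsd_to_reference,
    superpose_kabsch,
)


def quaternion_rmsd(mobile, target):
    """Independent minimum-RMSD oracle via the quaternion eigen-decomposition."""
    x = mobile - mobile.mean(axis=0)
    y = target - target.mean(axis=0)
    n = len(x)
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(key).max()
    msd = max((np.sum(x**2) + np.sum(y**2) - 2 * lam) / n, 0.0)
    return np.sqrt(msd)


def naive_agglomerative(d, linkage, threshold):
    """O(n^3) reference clustering: merge the closest pair while its linkage
    distance stays at or below the threshold."""
    clusters = [[i] for i in range(len(d))]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                pd = [d[a, b] for a in clusters[i] for b in clusters[j]]
                dist = min(pd) if linkage == "single" else sum(pd) / len(pd)
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        if best[0] > threshold:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(len(d), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


def partitions_equal(a, b):
    return {frozenset(np.flatnonzero(a == c)) for c in np.unique(a)} == {
        frozenset(np.flatnonzero(b == c)) for c in np.unique(b)
    }


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(8, 3))
        rot, trans, rmsd = superpose_kabsch(x, x)
        assert np.allclose(rot, np.eye(3), atol=1e-10)
        assert np.allclose(trans, 0.0, atol=1e-10)
        assert rmsd < 1e-10

    def test_recovers_constructed_rigid_motion(self, rng):
        mobile = rng.normal(size=(10, 3)) * 3
        r_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        target = mobile @ r_true.T + np.array([1.0, 2.0, 3.0])
        rot, trans, rmsd = superpose_kabsch(mobile, target)
        assert rmsd < 1e-10
        assert np.abs(mobile @ rot.T + trans - target).max() < 1e-10

    def test_rmsd_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            mobile = rng.normal(size=(10, 3)) * 2
            target = rng.normal(size=(10, 3)) * 2
            _, _, rmsd = superpose_kabsch(mobile, target)
            assert rmsd == pytest.approx(quaternion_rmsd(mobile, target), abs=1e-6)

    def test_invariant_under_joint_rigid_motion(self, rng):
        mobile = rng.normal(size=(7, 3))
        target = rng.normal(size=(7, 3))
        _, _, rmsd0 = superpose_kabsch(mobile, target)
        q = Rotation.from_euler("xyz", rng.uniform(0, 360, 3), degrees=True).as_matrix()
        shift = rng.normal(size=3) * 5
        _, _, rmsd1 = superpose_kabsch(mobile @ q.T + shift, target @ q.T + shift)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            superpose_kabsch(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="collinear"):
            superpose_kabsch(line, line)


class TestRmsdSeries:
    def test_identical_frames_zero(self, rng):
        ref = rng.normal(size=(6, 3))
        ens = PoseEnsemble(
            times=np.arange(4.0), coords=np.tile(ref, (4, 1, 1)), reference=ref
        )
        assert np.allclose(rmsd_to_reference(ens), 0.0)

    def test_uniform_translation_gives_norm(self, rng):
        ref = rng.normal(size=(6, 3))
        d = np.array([1.0, 2.0, 2.0])  # |d| = 3
        ens = PoseEnsemble(
            times=np.array([0.0]), coords=(ref + d)[None], reference=ref
        )
        assert rmsd_to_reference(ens)[0] == pytest.approx(3.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        ref = rng.normal(size=(5, 3))
        coords = rng.normal(size=(9, 5, 3))
        ens = PoseEnsemble(times=np.arange(9.0), coords=coords, reference=ref)
        expected = [
            np.sqrt(np.mean(np.sum((coords[i] - ref) ** 2, axis=1)))
            for i in range(9)
        ]
        assert np.allclose(rmsd_to_reference(ens), expected)


class TestClustering:
    def test_all_zero_distances_single_cluster(self):
        d = np.zeros((5, 5))
        result = cluster_poses(d, rmsd_to_ref=np.zeros(5), threshold_angstrom=1.0)
        assert result.n_clusters == 1
        assert result.occupancy[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_planted_clusters_recovered(self, rng):
        ref = rng.normal(size=(8, 3)) * 3
        ens = synthetic.generate_pose_cloud(
            ref, [(2.0, 0.2, 12), (12.0, 0.2, 8)], seed=5
        )
        d = pairwise_rmsd_matrix(ens)
        result = cluster_poses(
            d, rmsd_to_ref=rmsd_to_reference(ens), threshold_angstrom=5.0
        )
        assert result.n_clusters == 2
        assert partitions_equal(result.labels, ens.true_labels)
        assert result.native_like_cluster_id == 0

    @pytest.mark.parametrize("linkage", ["single", "average"])
    def test_matches_naive_agglomerative_oracle(self, linkage, rng):
        for _ in range(10):
            n = 30
            pts = rng.normal(size=(n, 2)) * 4
            d = np.sqrt(np.sum((pts[:, None] - pts[None]) ** 2, axis=2))
            got = cluster_poses(d, linkage=linkage, threshold_angstrom=3.0)
            expected = naive_agglomerative(d, linkage, 3.0)
            assert partitions_equal(got.labels, expected)

    def test_permutation_invariant(self, rng):
        ref = rng.normal(size=(6, 3)) * 3
        ens = synthetic.generate_pose_cloud(
            ref, [(1.0, 0.3, 10), (9.0, 0.3, 10)], n_decoys=4, seed=9
        )
        d = pairwise_rmsd_matrix(ens)
        r = rmsd_to_reference(ens)
        base = cluster_poses(d, rmsd_to_ref=r, threshold_angstrom=4.0)
        perm = rng.permutation(len(r))
        shuffled = cluster_poses(
            d[np.ix_(perm, perm)], rmsd_to_ref=r[perm], threshold_angstrom=4.0
        )
        assert partitions_equal(shuffled.labels, base.labels[perm])
        assert derive_bound_cutoff(shuffled) == pytest.approx(
            derive_bound_cutoff(base), abs=1e-12
        )

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            cluster_poses(d)


class TestBoundCutoff:
    def test_direct_sum(self):
        from pepbind.poses import ClusterResult

        result = ClusterResult(
            labels=np.zeros(3, dtype=int),
            mean_rmsd_to_reference=np.array([2.5]),
            max_within_cluster_distance=np.array([1.5]),
            occupancy=np.array([1.0]),
            native_like_cluster_id=0,
        )
        assert derive_bound_cutoff(result) == pytest.approx(4.0)

    def test_singleton_native_cluster_contributes_zero_width(self, rng):
        ref = rng.normal(size=(5, 3))
        ens = synthetic.generate_pose_cloud(
            ref, [(0.5, 0.0, 1), (10.0, 0.1, 6)], seed=3
        )
        d = pairwise_rmsd_matrix(ens)
        result = cluster_poses(
            d, rmsd_to_ref=rmsd_to_reference(ens), threshold_angstrom=3.0
        )
        native = result.native_like_cluster_id
        assert result.max_within_cluster_distance[native] == 0.0
        assert derive_bound_cutoff(result) == pytest.approx(
            result.mean_rmsd_to_reference[native]
        )

    def test_planted_statistics_recomputed_independently(self, rng):
        ref = rng.normal(size=(7, 3)) * 2
        ens = synthetic.generate_pose_cloud(
            ref, [(2.0, 0.3, 15), (14.0, 0.3, 10)], seed=21
        )
        d = pairwise_rmsd_matrix(ens)
        r = rmsd_to_reference(ens)
        result = cluster_poses(d, rmsd_to_ref=r, threshold_angstrom=5.0)
        native_members = np.flatnonzero(ens.true_labels == 0)
        expected = r[native_members].mean() + d[
            np.ix_(native_members, native_members)
        ].max()
        assert derive_bound_cutoff(result) == pytest.approx(expected, abs=1e-12)


class TestStates:
    def test_boundary_counts_as_bound(self):
        states = assign_states([0.0, 1.0, 2.0], [1.0, 4.41, 5.0], cutoff_angstrom=4.41)
        assert states.bound.tolist() == [True, True, False]

    def test_matches_elementwise_comparison(self, rng):
        r = rng.uniform(0, 10, size=50)
        states = assign_states(np.arange(50.0), r, cutoff_angstrom=4.0)
        assert np.array_equal(states.bound, r <= 4.0)


class TestUnboundFraction:
    def test_half_bound(self):
        series = [
            StateSeries(np.array([0.0]), np.array([b]), 1.0)
            for b in (True, True, False, False)
        ]
        frac = ensemble_unbound_fraction(series, np.array([0.0, 1.0]))
        assert np.allclose(frac.values, 0.5)

    def test_all_unbound_constant_one(self):
        series = [
            StateSeries(np.array([0.0, 1.0]), np.array([False, False]), 1.0)
            for _ in range(3)
        ]
        frac = ensemble_unbound_fraction(series, np.linspace(0, 1, 5))
        assert np.allclose(frac.values, 1.0)

    def test_matches_per_timepoint_counting(self):
        config = synthetic.SimulationConfig(
            k1=3.0, k_minus1=0.8, mode="singlepair", n_replicas=40,
            t_end=4.0, grid_step=0.25, seed=17,
        )
        series, replicas = synthetic.simulate_binding_gillespie(config)
        grid = series.times
        frac = ensemble_unbound_fraction(replicas, grid)
        for gi, t in enumerate(grid):
            n_unbound = 0
            for rep in replicas:
                state = False
                for ft, fb in zip(rep.times, rep.bound):
                    if ft <= t:
                        state = fb
                n_unbound += not state
            assert frac.values[gi] == pytest.approx(n_unbound / 40)

    def test_empty_replica_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_unbound_fraction([], np.array([0.0]))

    def test_conservation_bound_plus_unbound(self):
        config = synthetic.SimulationConfig(
            k1=2.0, k_minus1=1.0, mode="singlepair", n_replicas=25,
            t_end=3.0, grid_step=0.5, seed=2,
        )
        series, replicas = synthetic.simulate_binding_gillespie(config)
        frac = ensemble_unbound_fraction(replicas, series.times)
        assert np.all((0 <= frac.values) & (frac.values <= 1))
        bound_frac = np.array(
            [
                np.mean([rep.bound[np.searchsorted(rep.times, t, side="right") - 1]
                         for rep in replicas])
                for t in series.times
            ]
        )
        assert np.allclose(frac.values + bound_frac, 1.0)
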