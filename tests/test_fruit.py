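"""Eigen-features, KDE-mode thresholds, wood/fruit criteria, DBSCAN, scoring."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fruitherm import (PointCloud, SceneSpec, generate_tree, FRUIT, WOOD,
                       compute_eigen_features, threshold_from_mode,
                       derive_thresholds, segment_wood,
                       segment_fruit_candidates, cluster_fruit, dbscan,
                       score_detection, ThresholdSet, FruitCluster)
from fruitherm.fruit import ProvenanceError, _DEFAULT_DIRECTIONS


def brute_force_features(xyz, k):
    """Independent dense-distance + covariance/eigen oracle."""
    n = len(xyz)
    L = np.empty(n)
    C = np.empty(n)
    lam_all = np.empty((n, 3))
    for i in range(n):
        d2 = ((xyz - xyz[i]) ** 2).sum(axis=1)
        nbrs = xyz[np.argsort(d2, kind="stable")[:k]]
        cov = np.cov(nbrs.T, bias=True)
        lam = np.sort(np.linalg.eigvals(cov).real)[::-1]
        lam_all[i] = lam
        L[i] = (lam[0] - lam[1]) / lam[0]
        C[i] = 300.0 * lam[2] / lam.sum()
    return lam_all, L, C


class TestEigenFeatures:
    def test_line_is_linear_plane_and_line_are_flat(self, rng):
        t = np.linspace(0, 1, 60)
        line = PointCloud(np.column_stack([t, 2 * t, -t]) + rng.normal(0, 1e-9, (60, 3)))
        f = compute_eigen_features(line, k=10)
        assert f.linearity.min() > 0.999
        assert f.curvature.max() < 1e-3
        plane = PointCloud(np.column_stack(
            [rng.uniform(0, 1, 80), rng.uniform(0, 1, 80), np.zeros(80)]))
        fp = compute_eigen_features(plane, k=10)
        assert fp.curvature.max() < 1e-9

    def test_sphere_shell_curvature_exceeds_plane_and_matches_oracle(self, rng):
        v = rng.normal(size=(150, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        shell = PointCloud(0.035 * v)
        k = 30
        f = compute_eigen_features(shell, k=k)
        lam_o, L_o, C_o = brute_force_features(shell.xyz, k)
        np.testing.assert_allclose(f.linearity, L_o, atol=1e-10)
        np.testing.assert_allclose(f.curvature, C_o, atol=1e-10)
        np.testing.assert_allclose(f.eigenvalues, lam_o, atol=1e-10)
        assert np.median(f.curvature) > 10.0  # materially above planar ≈ 0

    def test_matches_oracle_on_mixed_cloud(self, rng):
        xyz = rng.uniform(0, 1, (200, 3))
        f = compute_eigen_features(PointCloud(xyz), k=12)
        _, L_o, C_o = brute_force_features(xyz, 12)
        np.testing.assert_allclose(f.linearity, L_o, atol=1e-10)
        np.testing.assert_allclose(f.curvature, C_o, atol=1e-10)

    def test_feature_ranges_and_eigenvalue_order(self, default_scene):
        _, cloud, _ = default_scene
        f = compute_eigen_features(cloud, k=30)
        lam = f.eigenvalues
        assert (lam[:, 0] >= lam[:, 1]).all() and (lam[:, 1] >= lam[:, 2]).all()
        assert (lam >= 0).all()
        ok = np.isfinite(f.linearity)
        assert (f.linearity[ok] >= 0).all() and (f.linearity[ok] <= 1 + 1e-12).all()
        assert (f.curvature[ok] >= 0).all() and (f.curvature[ok] <= 100 + 1e-9).all()

    def test_degenerate_neighbourhood_gives_missing_features(self):
        xyz = np.zeros((20, 3))  # all points identical
        f = compute_eigen_features(PointCloud(xyz), k=5)
        assert np.isnan(f.linearity).all() and np.isnan(f.curvature).all()

    def test_small_k_or_small_cloud_rejected(self, rng):
        cloud = PointCloud(rng.uniform(0, 1, (10, 3)))
        with pytest.raises(ValueError):
            compute_eigen_features(cloud, k=2)
        with pytest.raises(ValueError):
            compute_eigen_features(cloud, k=10)


class TestThresholdFromMode:
    def test_unimodal_gaussian_mode_near_mean(self):
        v = np.random.default_rng(1).normal(10.0, 1.0, 10_000)
        assert threshold_from_mode(v) == pytest.approx(10.0, abs=0.1)

    def test_constant_series_returns_constant_with_warning(self):
        with pytest.warns(UserWarning, match="zero bandwidth"):
            assert threshold_from_mode(np.full(100, 7.0)) == 7.0

    def test_bimodal_mixture_picks_taller_mode_not_mean(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(3.0, 0.4, 3500), rng.normal(8.0, 0.4, 1500)])
        mode = threshold_from_mode(v)
        assert mode == pytest.approx(3.0, abs=0.3)
        # independent check: fine-histogram argmax lands on the same peak
        hist, edges = np.histogram(v, bins=200)
        hist_mode = (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]) / 2
        assert abs(mode - hist_mode) < 0.3

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            threshold_from_mode(np.arange(10.0))


@pytest.fixture(scope="module")
def segmented_tree():
    """Default tree with features, thresholds and wood/candidate masks."""
    spec = SceneSpec(seed=3)
    cloud, truth = generate_tree(spec)
    feats = compute_eigen_features(cloud, k=30)
    th = derive_thresholds(cloud, feats, fruit_reference=cloud.label == FRUIT)
    wood_mask, remainder, rem_feats = segment_wood(cloud, feats, th)
    cand = segment_fruit_candidates(remainder, rem_feats, th)
    return spec, cloud, truth, feats, th, wood_mask, remainder, rem_feats, cand


class TestSegmentation:
    def test_wood_criteria_are_a_conjunction(self):
        th = ThresholdSet(0.5, 30.0, 30.0, 20.0, 50.0)
        cloud = PointCloud(np.zeros((3, 3)) + [[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                           intensity=np.array([20.0, 20.0, 80.0]))
        from fruitherm.fruit import EigenFeatures
        feats = EigenFeatures(
            eigenvalues=np.tile([1.0, 0.1, 0.0], (3, 1)),
            linearity=np.array([0.9, 0.2, 0.9]),   # second fails L, third fails R
            curvature=np.array([35.0, 35.0, 35.0]), k=5)
        wood, remainder, _ = segment_wood(cloud, feats, th)
        assert wood.tolist() == [True, False, False]
        assert len(remainder) == 2

    def test_trunk_mostly_removed_with_wood_like_thresholds(self):
        # leafless, branchless tree: the trunk is the only linear structure.
        # Thresholds configured between the wood and fruit feature
        # populations (trunk: high L, high surface variation, dark returns).
        spec = SceneSpec(seed=8, leaf_density=0.0, branch_count=0)
        cloud, truth = generate_tree(spec)
        feats = compute_eigen_features(cloud, k=30)
        th = ThresholdSet(l_wood=0.3, c_wood=5.0, r_wood=35.0,
                          c_fruit=10.0, r_fruit=50.0)
        wood_mask, _, _ = segment_wood(cloud, feats, th)
        trunk = truth.label == WOOD
        assert (wood_mask & trunk).sum() / trunk.sum() >= 0.9
        # and fruit survives
        assert (wood_mask & (truth.label == FRUIT)).sum() < 0.02 * (truth.label == FRUIT).sum()

    def test_everything_wood_leaves_empty_remainder_with_warning(self, rng):
        t = np.linspace(0, 1, 100)
        line = PointCloud(np.column_stack([t, t, t]) + rng.normal(0, 1e-6, (100, 3)),
                          intensity=np.full(100, 10.0))
        feats = compute_eigen_features(line, k=10)
        th = ThresholdSet(0.5, 0.0, 50.0, 20.0, 50.0)
        with pytest.warns(UserWarning, match="every point"):
            wood, remainder, _ = segment_wood(line, feats, th)
        assert wood.all() and len(remainder) == 0

    def test_candidate_selection_is_a_conjunction(self, segmented_tree):
        *_, remainder, rem_feats, cand = segmented_tree
        th_c, th_r = 0.0, 0.0  # recompute membership from the actual thresholds
        spec, cloud, truth, feats, th, wood_mask, _, _, _ = segmented_tree
        high_c = rem_feats.curvature >= th.c_fruit
        high_r = remainder.intensity >= th.r_fruit
        np.testing.assert_array_equal(cand, high_c & high_r
                                      & np.isfinite(rem_feats.curvature))
        # planar leaf points (low C) are never candidates
        leaf_low_c = (remainder.label == 2) & (rem_feats.curvature < th.c_fruit)
        assert not cand[leaf_low_c].any()

    def test_candidates_are_dominated_by_true_fruit(self, segmented_tree):
        *_, remainder, rem_feats, cand = segmented_tree
        assert cand.sum() > 100
        assert (remainder.label[cand] == FRUIT).mean() > 0.95

    def test_provenance_check_rejects_foreign_thresholds(self, segmented_tree, rng):
        spec, cloud, truth, feats, th, *_ = segmented_tree
        other = PointCloud(rng.uniform(0, 1, (200, 3)),
                           intensity=rng.uniform(0, 100, 200))
        other_feats = compute_eigen_features(other, k=10)
        with pytest.raises(ProvenanceError):
            segment_wood(other, other_feats, th)

    def test_partition_of_the_cloud_is_exact(self, segmented_tree):
        spec, cloud, truth, feats, th, wood_mask, remainder, rem_feats, cand = segmented_tree
        clusters = cluster_fruit(remainder, cand, eps=spec.fruit_diameter_mean / 2)
        in_cluster = np.zeros(len(remainder), dtype=bool)
        for c in clusters:
            assert cand[c.indices].all()  # members carry the candidate flag
            in_cluster[c.indices] = True
        n_wood = int(wood_mask.sum())
        n_clustered = int(in_cluster.sum())
        n_noise = int((cand & ~in_cluster).sum())
        n_other = int((~cand).sum())
        assert n_wood + n_clustered + n_noise + n_other == len(cloud)


class TestDBSCAN:
    def test_matches_reference_implementation_on_blobs(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        centers = rng.uniform(0, 1, (4, 3))
        pts = np.vstack([c + rng.normal(0, 0.01, (40, 3)) for c in centers])
        ours = dbscan(pts, eps=0.05, min_samples=10)
        ref = sklearn.DBSCAN(eps=0.05, min_samples=10).fit_predict(pts)
        # same partition up to label permutation
        assert (ours == -1).tolist() == (ref == -1).tolist()
        for lab in np.unique(ours[ours >= 0]):
            ref_labs = ref[ours == lab]
            assert len(set(ref_labs.tolist())) == 1

    def test_two_blobs_half_metre_apart_give_two_clusters(self, rng):
        a = rng.normal(0, 0.01, (30, 3))
        b = rng.normal(0, 0.01, (30, 3)) + [0.5, 0, 0]
        cloud = PointCloud(np.vstack([a, b]))
        clusters = cluster_fruit(cloud, np.ones(60, bool), eps=0.04, min_neighbors=10)
        assert len(clusters) == 2
        assert sorted(c.n_points for c in clusters) == [30, 30]

    def test_fewer_points_than_min_neighbors_is_noise(self, rng):
        pts = rng.normal(0, 0.005, (9, 3))
        cloud = PointCloud(pts)
        assert cluster_fruit(cloud, np.ones(9, bool), eps=0.05, min_neighbors=10) == []

    def test_clustering_invariant_to_point_order_and_rigid_motion(self, rng):
        pts = np.vstack([rng.normal(0, 0.01, (25, 3)),
                         rng.normal(0, 0.01, (25, 3)) + [0.4, 0, 0]])
        base = dbscan(pts, eps=0.05, min_samples=10)
        perm = rng.permutation(len(pts))
        permuted = dbscan(pts[perm], eps=0.05, min_samples=10)
        # permuting the input permutes labels consistently
        for lab in np.unique(base[base >= 0]):
            idx = np.flatnonzero(base == lab)
            mapped = permuted[np.argsort(perm)][idx]
            assert len(set(mapped.tolist())) == 1
        R = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        rotated = dbscan(pts @ R.T + [5.0, -3.0, 1.0], eps=0.05, min_samples=10)
        np.testing.assert_array_equal(rotated, base)

    def test_no_candidates_gives_empty_list(self):
        cloud = PointCloud(np.zeros((5, 3)))
        assert cluster_fruit(cloud, np.zeros(5, bool), eps=0.05) == []

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            dbscan(np.zeros((5, 3)), eps=0.0, min_samples=3)


def _cluster(indices):
    idx = np.asarray(indices)
    return FruitCluster(idx, np.zeros(3), len(idx), np.nan, np.nan, np.nan, 0.0)


class TestDetectionScore:
    # 50 points: fruit 1..5 own points 0-9, 10-19, ..., plus 10 background
    TRUTH = np.concatenate([np.repeat(np.arange(1, 6), 10), np.zeros(10, int)])

    def test_perfect_clustering_scores_one(self):
        clusters = [_cluster(range(i * 10, (i + 1) * 10)) for i in range(5)]
        s = score_detection(clusters, self.TRUTH, 60)
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_four_found_one_spurious_gives_point_eight(self):
        clusters = [_cluster(range(i * 10, (i + 1) * 10)) for i in range(4)]
        clusters.append(_cluster(range(50, 60)))  # background-only cluster
        s = score_detection(clusters, self.TRUTH, 60)
        assert s.precision == pytest.approx(0.8)
        assert s.recall == pytest.approx(0.8)
        assert s.f1 == pytest.approx(0.8)

    def test_no_clusters_gives_zero_recall_and_f1(self):
        s = score_detection([], self.TRUTH, 60)
        assert s.recall == 0.0 and s.f1 == 0.0
        assert s.false_negatives == 5

    def test_double_detection_of_one_fruit_counts_false_positive(self):
        clusters = [_cluster(range(0, 5)), _cluster(range(5, 10))]
        s = score_detection(clusters, self.TRUTH, 60)
        assert s.true_positives == 1 and s.false_positives == 1

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_detection([], self.TRUTH, 59)
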