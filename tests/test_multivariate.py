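"""PCA, clustering, model selection, and the cluster-stratified report."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage

from posturekit.errors import InsufficientSampleError, InvalidInputError
from posturekit.geometry import PARAMETER_NAMES
from posturekit.multivariate import (
    cluster,
    cluster_stratified_comparison,
    elbow_curve,
    run_pca,
    select_components,
    silhouette,
)

from _bruteforce import naive_agglomerative, naive_silhouette, partitions_equal


def _blobs(rng, centers, n_per=30, sd=1.0):
    pts = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


class TestPca:
    def test_diagonal_two_variable_ratios(self, rng):
        # var 9 and 1, uncorrelated -> ratios (0.9, 0.1)
        x = np.column_stack([rng.normal(0, 3, 4000), rng.normal(0, 1, 4000)])
        res = run_pca(x, scaling="none")
        assert res.explained_variance_ratio[0] == pytest.approx(0.9, abs=0.02)
        assert res.explained_variance_ratio[1] == pytest.approx(0.1, abs=0.02)

    def test_isotropic_gaussian_flat_spectrum(self, rng):
        x = rng.normal(size=(2000, 5))
        res = run_pca(x, scaling="none")
        assert np.all(res.explained_variance_ratio >= 0.15)
        assert np.all(res.explained_variance_ratio <= 0.25)

    def test_loadings_orthonormal_and_reconstruction_lossless(self, rng):
        x = rng.normal(size=(50, 8)) @ rng.normal(size=(8, 8))
        res = run_pca(x, scaling="none")
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert np.max(np.abs(res.reconstruct() - x)) < 1e-8
        res_z = run_pca(x, scaling="zscore")
        assert np.max(np.abs(res_z.reconstruct() - x)) < 1e-8

    def test_sign_convention_deterministic(self, rng):
        x = rng.normal(size=(40, 5))
        res = run_pca(x)
        for j in range(res.loadings.shape[1]):
            k = np.argmax(np.abs(res.loadings[:, j]))
            assert res.loadings[k, j] > 0

    def test_rejects_missing_values(self):
        x = np.ones((10, 3))
        x[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            run_pca(x)


class TestSelectComponents:
    @pytest.mark.parametrize(
        "ratios,retention,expected",
        [
            # the published spectrum: two components reach 90%
            ((0.815, 0.093, 0.052, 0.040), 0.90, 2),
            ((1.0,), 0.9, 1),
            ((0.5, 0.3, 0.15, 0.05), 1.0, 4),
            ((0.6, 0.3, 0.1), 0.6, 1),
        ],
    )
    def test_smallest_count_reaching_retention(self, ratios, retention, expected):
        assert select_components(np.array(ratios), retention) == expected

    def test_rejects_bad_retention(self):
        with pytest.raises(InvalidInputError):
            select_components(np.array([1.0]), 0.0)


class TestSilhouette:
    def test_two_singletons_score_zero(self):
        pts = np.array([[0.0], [1.0]])
        assert silhouette(pts, [0, 1]) == pytest.approx(0.0)

    def test_tight_pairs_score_high_and_match_hand_value(self):
        pts = np.array([[0, 0], [0, 0.1], [10, 0], [10, 0.1]], dtype=float)
        labels = [0, 0, 1, 1]
        s = silhouette(pts, labels)
        assert s > 0.95
        assert s == pytest.approx(naive_silhouette(pts, labels), abs=1e-9)

    def test_matches_brute_force_on_random_small_instances(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(9, 3))
            labels = rng.integers(0, 3, 9)
            if len(set(labels.tolist())) < 2:
                continue
            assert silhouette(pts, labels) == pytest.approx(
                naive_silhouette(pts, labels), abs=1e-9
            )

    def test_permuting_cluster_ids_invariant(self, rng):
        pts = rng.normal(size=(20, 2))
        labels = rng.integers(0, 3, 20)
        labels[:3] = [0, 1, 2]
        perm = (labels + 1) % 3
        assert silhouette(pts, labels) == pytest.approx(silhouette(pts, perm))

    def test_random_labels_on_one_blob_near_zero(self, rng):
        ok = 0
        for _ in range(40):
            pts = rng.normal(size=(60, 2))
            labels = rng.integers(0, 2, 60)
            if silhouette(pts, labels) <= 0.1:
                ok += 1
        assert ok >= 38

    def test_single_cluster_undefined(self, rng):
        with pytest.raises(InvalidInputError):
            silhouette(rng.normal(size=(5, 2)), [0] * 5)


class TestClusterMethods:
    @pytest.mark.parametrize("method", ["kmeans", "meanshift", "ward", "complete", "average"])
    def test_separated_blobs_recovered_by_every_method(self, rng, method):
        pts, true = _blobs(rng, [(0, 0), (20, 0)], n_per=40, sd=1.0)  # 20 SD apart
        res = cluster(pts, method, n_clusters=2)
        assert res.n_clusters == 2
        assert partitions_equal(res.labels, true)
        assert res.silhouette > 0.7

    def test_kmeans_reproducible_bit_identically(self, rng):
        pts, _ = _blobs(rng, [(0, 0), (8, 8), (0, 8)], n_per=25, sd=1.2)
        r1 = cluster(pts, "kmeans", n_clusters=3, seed=99)
        r2 = cluster(pts, "kmeans", n_clusters=3, seed=99)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.params["inertia"] == r2.params["inertia"]

    def test_identical_points_meanshift_single_cluster(self):
        pts = np.zeros((10, 2))
        res = cluster(pts, "meanshift")
        assert res.n_clusters == 1
        assert res.silhouette is None

    def test_infeasible_k_raises(self, rng):
        with pytest.raises(InsufficientSampleError):
            cluster(rng.normal(size=(4, 2)), "kmeans", n_clusters=7)

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            cluster(rng.normal(size=(10, 2)), "dbscan")


class TestLinkageOracle:
    @pytest.mark.parametrize("method", ["ward", "complete", "average"])
    def test_agrees_with_exhaustive_agglomeration(self, rng, method):
        for trial in range(6):
            pts = rng.normal(size=(10, 2))
            for k in (2, 3):
                res = cluster(pts, method, n_clusters=k)
                naive_labels, _ = naive_agglomerative(pts, method, k)
                assert partitions_equal(res.labels, naive_labels)

    @pytest.mark.parametrize("method", ["complete", "average"])
    def test_merge_heights_match_scipy_exactly(self, rng, method):
        pts = rng.normal(size=(9, 3))
        _, naive_heights = naive_agglomerative(pts, method, 1)
        z = scipy_linkage(pts, method=method)
        assert np.allclose(sorted(naive_heights), z[:, 2], atol=1e-9)

    def test_two_triads_hand_instance(self):
        pts = np.array(
            [[0, 0], [1, 0], [0.5, 0.8], [10, 10], [11, 10], [10.5, 10.8]], dtype=float
        )
        expected = [0, 0, 0, 1, 1, 1]
        for method in ("ward", "complete", "average"):
            res = cluster(pts, method, n_clusters=2)
            assert partitions_equal(res.labels, expected)
            naive_labels, _ = naive_agglomerative(pts, method, 2)
            assert partitions_equal(naive_labels, expected)


class TestElbow:
    def test_knee_at_two_for_two_blobs(self, rng):
        pts, _ = _blobs(rng, [(0, 0), (15, 0)], n_per=40)
        ec = elbow_curve(pts, range(1, 7))
        assert ec.knee == 2
        assert not ec.low_confidence
        assert all(a >= b - 1e-9 for a, b in zip(ec.wcss, ec.wcss[1:]))

    def test_single_blob_flagged_low_confidence(self, rng):
        pts = rng.normal(size=(60, 2))
        ec = elbow_curve(pts, range(1, 7))
        assert ec.low_confidence

    def test_wcss_vanishes_at_k_equals_n(self, rng):
        pts = rng.normal(size=(6, 2))
        ec = elbow_curve(pts, range(1, 7))
        assert ec.wcss[-1] == pytest.approx(0.0, abs=1e-9)


class TestStratifiedComparison:
    def _frame(self, rng, n=40):
        import pandas as pd

        frame = pd.DataFrame(
            {p: rng.normal(10, 2, 2 * n) for p in PARAMETER_NAMES}
        )
        sex = np.array(["M"] * n + ["F"] * n)
        frame["shoulder_hip_difference"] = np.where(
            sex == "M", rng.normal(84, 15, 2 * n), rng.normal(63, 13, 2 * n)
        )
        return frame, sex

    def test_sex_labels_reproduce_sex_comparison(self, rng):
        from posturekit.stats import comparison_table

        frame, sex = self._frame(rng)
        comps, named = cluster_stratified_comparison(frame, (sex == "M").astype(int))
        # CG1 must be the smaller shoulder-hip group (women here)
        assert set(named[sex == "F"]) == {"CG1"}
        direct = comparison_table(frame, np.where(sex == "M", "CG2", "CG1"), ("CG1", "CG2"))
        by_param = {c.parameter: c for c in direct}
        for c in comps:
            assert c.p_value == pytest.approx(by_param[c.parameter].p_value)
            assert c.cohens_d == pytest.approx(by_param[c.parameter].cohens_d)

    def test_requires_exactly_two_clusters(self, rng):
        frame, _ = self._frame(rng)
        with pytest.raises(InvalidInputError):
            cluster_stratified_comparison(frame, np.zeros(len(frame), dtype=int))

    def test_tiny_cluster_rejected(self, rng):
        frame, _ = self._frame(rng)
        labels = np.zeros(len(frame), dtype=int)
        labels[0] = 1
        with pytest.raises(InsufficientSampleError):
            cluster_stratified_comparison(frame, labels)
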