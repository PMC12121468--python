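"""Clustering algorithms, validation indices and k/algorithm selection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from astromorph import (
    connectivity_index,
    dunn_index,
    hcluster,
    kmeans_fit,
    mean_silhouette,
    pam_fit,
    select_algorithm,
    select_k,
    som_fit,
    validation_indices,
)

from conftest import best_medoids, best_partition_wss, indices_reference, ward_naive


def blobs(n_per, centers, spread=1.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [c + spread * rng.standard_normal((n_per, len(c))) for c in centers]
    )
    truth = np.repeat(np.arange(1, len(centers) + 1), n_per)
    return pts, truth


class TestHierarchical:
    def test_two_separated_pairs(self):
        pts = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        sol = hcluster(pts, 2)
        assert sol.labels[0] == sol.labels[1]
        assert sol.labels[2] == sol.labels[3]
        assert sol.labels[0] != sol.labels[2]

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(5)
        sol = hcluster(rng.standard_normal((40, 3)), 2)
        heights = sol.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_labels_match_naive_agglomeration(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((30, 2))
        sol = hcluster(pts, 3)
        oracle = ward_naive(pts, 3)
        assert adjusted_rand_score(sol.labels, oracle) == pytest.approx(1.0)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hcluster(np.zeros((4, 2)), 4)


class TestKMeans:
    def test_separated_gaussians_recovered(self):
        pts, truth = blobs(40, [(0, 0), (10, 0), (0, 10)], spread=1.0, seed=1)
        sol = kmeans_fit(pts, 3, seed=0)
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_matches_exhaustive_best_partition(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((8, 2))
        sol = kmeans_fit(pts, 2, n_restarts=50, seed=0)

        def wss(labels):
            return sum(
                ((pts[labels == c] - pts[labels == c].mean(axis=0)) ** 2).sum()
                for c in np.unique(labels)
            )

        best_wss, _ = best_partition_wss(pts, 2)
        assert wss(sol.labels) == pytest.approx(best_wss, rel=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((50, 3))
        a = kmeans_fit(pts, 4, seed=9).labels
        b = kmeans_fit(pts, 4, seed=9).labels
        np.testing.assert_array_equal(a, b)


class TestPAM:
    def test_k1_medoid_minimises_total_distance(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((12, 2))
        sol = pam_fit(pts, 1)
        cost, subset = best_medoids(pts, 1)
        np.testing.assert_allclose(sol.centers[0], pts[subset[0]])

    def test_three_blobs_one_medoid_each(self):
        pts, truth = blobs(15, [(0, 0), (12, 0), (0, 12)], seed=5)
        sol = pam_fit(pts, 3)
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_cost_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((10, 2))
        sol = pam_fit(pts, 2)
        from scipy.spatial.distance import cdist

        cost = cdist(pts, sol.centers).min(axis=1).sum()
        best_cost, _ = best_medoids(pts, 2)
        assert cost == pytest.approx(best_cost, rel=1e-9)


class TestSOM:
    def test_blobs_one_unit_each(self):
        pts, truth = blobs(25, [(0, 0), (10, 0), (0, 10)], seed=7)
        sol = som_fit(pts, 3, seed=1)
        assert sol.k == 3
        assert adjusted_rand_score(truth, sol.labels) == 1.0

    def test_zero_radius_reaches_kmeans_fixed_point(self):
        """With no neighbourhood the SOM settles at a Lloyd fixed point."""
        pts, _ = blobs(30, [(0, 0), (8, 0)], seed=8)
        sol = som_fit(pts, 2, seed=2, radius=(0.0, 0.0), epochs=80)
        km = kmeans_fit(pts, 2, seed=0)
        assert adjusted_rand_score(sol.labels, km.labels) == 1.0

    def test_identical_seed_identical_labels(self):
        rng = np.random.default_rng(9)
        pts = rng.standard_normal((60, 4))
        a = som_fit(pts, 3, seed=11).labels
        b = som_fit(pts, 3, seed=11).labels
        np.testing.assert_array_equal(a, b)


class TestValidationIndices:
    def test_two_tight_far_pairs(self):
        pts = np.array([[0.0, 0], [0.2, 0], [50.0, 0], [50.2, 0]])
        labels = np.array([1, 1, 2, 2])
        conn = connectivity_index(pts, labels, n_neighbors=1)
        dunn = dunn_index(pts, labels)
        sil = mean_silhouette(pts, labels)
        assert conn == 0.0
        assert dunn > 100
        assert sil > 0.98

    def test_coincident_points_dunn_zero(self):
        pts = np.zeros((6, 2))
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert dunn_index(pts, labels) == 0.0

    def test_match_definitional_reference(self):
        rng = np.random.default_rng(10)
        for trial in range(4):
            pts = rng.standard_normal((12, 3))
            labels = rng.integers(1, 4, size=12)
            while len(np.unique(labels)) < 3:
                labels = rng.integers(1, 4, size=12)
            conn, dunn, sil = (
                connectivity_index(pts, labels),
                dunn_index(pts, labels),
                mean_silhouette(pts, labels),
            )
            conn_ref, dunn_ref, sil_ref = indices_reference(pts, labels)
            assert conn == pytest.approx(conn_ref, abs=1e-9)
            assert dunn == pytest.approx(dunn_ref, rel=1e-9)
            assert sil == pytest.approx(sil_ref, rel=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((25, 3))
        sol = hcluster(pts, 3)
        conn, dunn, sil = validation_indices(pts, sol)
        perm = rng.permutation(25)
        conn2 = connectivity_index(pts[perm], sol.labels[perm])
        dunn2 = dunn_index(pts[perm], sol.labels[perm])
        sil2 = mean_silhouette(pts[perm], sol.labels[perm])
        assert conn2 == pytest.approx(conn, abs=1e-9)
        assert dunn2 == pytest.approx(dunn, rel=1e-12)
        assert sil2 == pytest.approx(sil, rel=1e-12)


class TestSelectK:
    def test_three_separated_blobs(self):
        pts, _ = blobs(100, [(0, 0), (8, 0), (4, 7)], spread=1.0, seed=12)
        report = select_k(pts, k_range=(2, 8), seed=3, n_ref=25)
        assert report.chosen_k == 3

    def test_degenerate_range_forces_k(self):
        rng = np.random.default_rng(13)
        pts = rng.standard_normal((30, 2))
        report = select_k(pts, k_range=(2, 2), seed=1, n_ref=10)
        assert report.chosen_k == 2

    def test_report_complete(self):
        pts, _ = blobs(30, [(0, 0), (6, 0)], seed=14)
        report = select_k(pts, k_range=(2, 4), seed=2, n_ref=10)
        assert set(report.votes) == {
            "calinski_harabasz", "silhouette", "dunn", "davies_bouldin",
            "gap", "hartigan", "c_index", "krzanowski_lai",
        }
        assert not report.index_table.isna().any().any()


class TestSelectAlgorithm:
    def test_separated_blobs_winner_near_best_silhouette(self):
        pts, _ = blobs(30, [(0, 0), (10, 0), (0, 10)], seed=15)
        sol, report = select_algorithm(pts, 3, seed=4)
        best_sil = report.index_table["silhouette"].max()
        winner_sil = report.index_table.loc[sol.algorithm, "silhouette"]
        assert winner_sil == pytest.approx(best_sil, abs=1e-6)

    def test_report_lists_all_candidates_and_indices(self):
        pts, _ = blobs(20, [(0, 0), (7, 0)], seed=16)
        _, report = select_algorithm(pts, 2, seed=5)
        assert set(report.index_table.index) == {
            "hierarchical", "kmeans", "pam", "som",
        }
        assert not report.index_table.isna().any().any()

    def test_chained_clusters_single_linkage_diagnostic(self):
        """Single linkage beats k-means on Dunn for chained elongated sets."""
        t = np.linspace(0, 4 * np.pi, 60)
        line1 = np.column_stack([t, np.sin(t) * 0.1])
        line2 = np.column_stack([t, np.sin(t) * 0.1 + 3.0])
        pts = np.vstack([line1, line2])
        single = hcluster(pts, 2, linkage_method="single")
        km = kmeans_fit(pts, 2, seed=0)
        assert dunn_index(pts, single.labels) > dunn_index(pts, km.labels)
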