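"""k-means / elbow / kNN graph / Leiden contracts on 2-D maps."""

import logging

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from vizclust.clustering import (
    elbow_select_k,
    kmeans_cluster,
    knn_graph,
    leiden_cluster,
    leiden_on_embedding,
)
from vizclust.types import ValidationError

from conftest import blobs


class TestKmeans:
    def test_two_pairs_closed_form_wss(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0], [11.0, 0.0]])
        res = kmeans_cluster(pts, 2, seed=0)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]
        # each pair contributes 2 * (half distance)^2 = 0.5
        assert res.params["inertia"] == pytest.approx(1.0)

    def test_k_bounds(self):
        pts = np.random.default_rng(0).normal(size=(10, 2))
        kmeans_cluster(pts, 9, seed=0)  # k = n - 1 accepted
        with pytest.raises(ValidationError, match="k must"):
            kmeans_cluster(pts, 10, seed=0)
        with pytest.raises(ValidationError, match="k must"):
            kmeans_cluster(pts, 1, seed=0)

    def test_separated_blobs_recovered_exactly(self, three_blobs):
        pts, labels = three_blobs
        res = kmeans_cluster(pts, 3, seed=1)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_permutation_invariance_up_to_relabeling(self, three_blobs):
        pts, _ = three_blobs
        perm = np.random.default_rng(5).permutation(len(pts))
        a = kmeans_cluster(pts, 3, seed=2)
        b = kmeans_cluster(pts[perm], 3, seed=2)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0


class TestElbow:
    def test_three_blobs_select_three(self):
        pts, _ = blobs([(0, 0), (10, 0), (0, 10)], 0.5, 50, seed=3)
        assert elbow_select_k(pts, seed=0) == 3

    def test_single_blob_falls_back_to_two_with_warning(self, caplog):
        pts = np.random.default_rng(4).normal(size=(150, 2))
        with caplog.at_level(logging.WARNING, logger="vizclust.clustering"):
            k = elbow_select_k(pts, seed=0)
        assert k == 2
        assert any("low-confidence" in r.message for r in caplog.records)

    def test_duplicated_dataset_selects_same_k(self):
        pts, _ = blobs([(0, 0), (10, 0), (0, 10)], 0.5, 30, seed=6)
        doubled = np.vstack([pts, pts])
        assert elbow_select_k(pts, seed=0) == elbow_select_k(doubled, seed=0)

    def test_degenerate_embedding_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            elbow_select_k(np.ones((30, 2)), seed=0)


class TestKnnGraph:
    def test_degree_at_least_k(self, three_blobs):
        pts, _ = three_blobs
        g = knn_graph(pts, 10)
        assert min(g.degree()) >= 10

    def test_isometry_invariance(self, three_blobs):
        pts, _ = three_blobs
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        g1 = knn_graph(pts, 8)
        g2 = knn_graph(pts @ R.T + np.array([5.0, -3.0]), 8)
        assert sorted(g1.get_edgelist()) == sorted(g2.get_edgelist())

    def test_matches_brute_force_sort_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(50, 2))
        g = knn_graph(pts, 6)
        edges = set(g.get_edgelist())
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        for i in range(50):
            nbrs = [j for j in np.argsort(d[i], kind="stable") if j != i][:6]
            for j in nbrs:
                assert (min(i, j), max(i, j)) in edges

    def test_neighbor_bound(self):
        with pytest.raises(ValidationError, match="n_neighbors"):
            knn_graph(np.zeros((5, 2)), 5)


class TestLeiden:
    def test_two_disjoint_cliques(self):
        import igraph

        g1 = igraph.Graph.Full(10)
        g2 = igraph.Graph.Full(10)
        g = g1.disjoint_union(g2)
        res = leiden_cluster(g, resolution=1.0, seed=0)
        assert res.n_clusters == 2
        assert len(set(res.labels[:10])) == 1
        assert len(set(res.labels[10:])) == 1

    def test_resolution_to_zero_merges_connected_graph(self):
        import igraph

        g = igraph.Graph.Erdos_Renyi(n=40, p=0.2)
        g = g.connected_components().giant()
        res = leiden_cluster(g, resolution=1e-4, seed=0)
        assert res.n_clusters == 1

    def test_cluster_count_non_increasing_with_lower_resolution(self, three_blobs):
        pts, _ = three_blobs
        g = knn_graph(pts, 15)
        high = leiden_cluster(g, resolution=1.0, seed=0)
        low = leiden_cluster(g, resolution=0.05, seed=0)
        assert low.n_clusters <= high.n_clusters

    def test_two_small_blobs_recovered_at_default_resolution(self):
        # blob size 20 with 15 neighbors: near-complete subgraphs
        pts, labels = blobs([(0, 0), (20, 0)], 0.5, 20, seed=8)
        res = leiden_on_embedding(pts, n_neighbors=15, resolution=1.0, seed=0)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_empty_graph_rejected(self):
        import igraph

        with pytest.raises(ValidationError, match="empty"):
            leiden_cluster(igraph.Graph(), resolution=1.0, seed=0)

    def test_deterministic_given_seed(self, three_blobs):
        pts, _ = three_blobs
        a = leiden_on_embedding(pts, 15, 1.0, seed=3)
        b = leiden_on_embedding(pts, 15, 1.0, seed=3)
        assert np.array_equal(a.labels, b.labels)
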