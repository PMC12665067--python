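"""Neighbor graphs, Leiden clustering, retention and UMAP."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from seedspatial.cluster import (ClusterAssignment, NeighborGraph,
                                 expression_knn_graph, leiden_cluster,
                                 retain_tissue_clusters,
                                 spatial_neighbors_graph, umap_embed)
from seedspatial.errors import EmptyInputError, ParameterError
from seedspatial.preprocess import Embedding

from conftest import make_binned


def embedding_from(coords):
    coords = np.asarray(coords, dtype=float)
    bins = pd.DataFrame({"bin_x": np.arange(len(coords)),
                         "bin_y": np.zeros(len(coords), dtype=int)})
    return Embedding(bins=bins, n_components=coords.shape[1],
                     coordinates=coords,
                     explained_variance_ratio=np.ones(coords.shape[1]))


class TestExpressionKnnGraph:
    def test_collinear_middle_degree_two(self):
        emb = embedding_from([[0.0], [1.0], [2.0]])
        g = expression_knn_graph(emb, k=1)
        degrees = np.asarray((g.weights > 0).sum(axis=1)).ravel()
        assert degrees[1] == 2          # union symmetrization

    def test_complete_graph_at_max_k(self):
        emb = embedding_from(np.arange(6.0).reshape(-1, 1))
        g = expression_knn_graph(emb, k=5)
        assert (np.asarray((g.weights > 0).sum(axis=1)) == 5).all()

    def test_separated_blobs_no_cross_edges(self):
        """Brute-force check: no kNN edge crosses two distant blobs."""
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(20, 2))
        b = rng.normal(100, 1, size=(20, 2))
        emb = embedding_from(np.vstack([a, b]))
        g = expression_knn_graph(emb, k=5)
        cross = g.weights[:20, 20:]
        assert cross.nnz == 0

    def test_weights_are_inverse_distance(self):
        emb = embedding_from([[0.0], [3.0], [10.0]])
        g = expression_knn_graph(emb, k=1)
        assert g.weights[0, 1] == pytest.approx(1 / (1 + 3.0))

    def test_k_out_of_range(self):
        emb = embedding_from([[0.0], [1.0]])
        with pytest.raises(ParameterError):
            expression_knn_graph(emb, k=2)


class TestSpatialNeighborsGraph:
    def _grid_graph(self, lam):
        bins = pd.DataFrame([(x, y) for x in range(3) for y in range(3)],
                            columns=["bin_x", "bin_y"])
        coords = bins.to_numpy(dtype=float)
        emb = Embedding(bins=bins, n_components=2, coordinates=coords,
                        explained_variance_ratio=np.ones(2))
        expr = expression_knn_graph(emb, k=2)
        return expr, spatial_neighbors_graph(bins, expr, lam)

    def test_lambda_zero_is_expression_graph(self):
        expr, comb = self._grid_graph(0.0)
        assert np.allclose(comb.weights.toarray(), expr.weights.toarray())

    def test_center_bin_eight_spatial_neighbors(self):
        _, comb = self._grid_graph(1.0)
        center = 4  # (1, 1) in row-major (x, y) enumeration
        assert (comb.weights[center] > 0).sum() == 8

    def test_isolated_bin_keeps_expression_edges(self):
        bins = pd.DataFrame({"bin_x": [0, 1, 50], "bin_y": [0, 0, 50]})
        emb = Embedding(bins=bins, n_components=1,
                        coordinates=np.array([[0.0], [1.0], [2.0]]),
                        explained_variance_ratio=np.ones(1))
        expr = expression_knn_graph(emb, k=1)
        comb = spatial_neighbors_graph(bins, expr, 0.5)
        assert comb.weights[2].nnz > 0

    def test_lambda_out_of_range(self):
        bins = pd.DataFrame({"bin_x": [0, 1], "bin_y": [0, 0]})
        emb = Embedding(bins=bins, n_components=1,
                        coordinates=np.array([[0.0], [1.0]]),
                        explained_variance_ratio=np.ones(1))
        expr = expression_knn_graph(emb, k=1)
        with pytest.raises(ParameterError):
            spatial_neighbors_graph(bins, expr, 1.5)


def two_cliques_graph():
    n = 20
    W = np.zeros((n, n))
    W[:10, :10] = 1.0
    W[10:, 10:] = 1.0
    np.fill_diagonal(W, 0)
    bins = pd.DataFrame({"bin_x": np.arange(n), "bin_y": np.zeros(n, int)})
    return NeighborGraph(bins=bins, weights=sp.csr_matrix(W),
                         provenance="expression")


class TestLeiden:
    def test_two_cliques_two_clusters(self):
        a = leiden_cluster(two_cliques_graph(), resolution=1.0, seed=0)
        assert a.n_clusters == 2
        assert len(set(a.labels[:10])) == 1
        assert len(set(a.labels[10:])) == 1

    def test_deterministic_rerun(self):
        g = two_cliques_graph()
        a1 = leiden_cluster(g, resolution=1.0, seed=7)
        a2 = leiden_cluster(g, resolution=1.0, seed=7)
        assert np.array_equal(a1.labels, a2.labels)

    def test_labels_invariant_to_bin_order(self):
        g = two_cliques_graph()
        perm = np.random.default_rng(3).permutation(20)
        gp = NeighborGraph(bins=g.bins.iloc[perm].reset_index(drop=True),
                           weights=g.weights[perm][:, perm].tocsr(),
                           provenance="expression")
        a = leiden_cluster(g, 1.0, 0)
        ap = leiden_cluster(gp, 1.0, 0)
        # same partition up to the permutation
        lab_by_bin = dict(zip(g.bins["bin_x"], a.labels))
        lab_by_bin_p = dict(zip(gp.bins["bin_x"], ap.labels))
        assert lab_by_bin == lab_by_bin_p

    def test_empty_graph_raises(self):
        bins = pd.DataFrame({"bin_x": [], "bin_y": []})
        g = NeighborGraph(bins=bins, weights=sp.csr_matrix((0, 0)),
                          provenance="expression")
        with pytest.raises(EmptyInputError):
            leiden_cluster(g, 1.0, 0)

    def test_spatial_only_clusters_are_contiguous(self):
        """lambda = 1 on a split mask yields spatially contiguous clusters."""
        bins = pd.DataFrame(
            [(x, y) for x in range(4) for y in range(3)] +
            [(x + 20, y) for x in range(4) for y in range(3)],
            columns=["bin_x", "bin_y"])
        coords = np.random.default_rng(0).normal(size=(len(bins), 2))
        emb = Embedding(bins=bins, n_components=2, coordinates=coords,
                        explained_variance_ratio=np.ones(2))
        comb = spatial_neighbors_graph(bins, expression_knn_graph(emb, 3), 1.0)
        a = leiden_cluster(comb, 0.5, 0)
        left = set(a.labels[:12])
        right = set(a.labels[12:])
        assert left.isdisjoint(right)


class TestRetention:
    def _assignment(self, labels):
        labels = np.asarray(labels)
        bins = pd.DataFrame({"bin_x": np.arange(len(labels)),
                             "bin_y": np.zeros(len(labels), int)})
        return ClusterAssignment(bins=bins, labels=labels, resolution=1.0,
                                 seed=0,
                                 retained={c: True for c in set(labels)})

    def test_inside_mask_retained_outside_discarded(self):
        a = self._assignment([0, 0, 0, 1, 1, 1])
        binned = make_binned([[10]] * 6)
        mask = {(0, 0), (1, 0), (2, 0)}     # cluster 0 inside, 1 outside
        a, report = retain_tissue_clusters(a, binned, tissue_mask=mask)
        assert a.retained[0] and not a.retained[1]
        assert not report[report.cluster == 1].retained.iloc[0]

    def test_quantile_rule_without_mask(self):
        # cluster 1 has background-level totals
        counts = [[100], [110], [120], [2], [1], [3], [100], [100], [100],
                  [100]]
        a = self._assignment([0, 0, 0, 1, 1, 1, 0, 0, 0, 0])
        binned = make_binned(counts)
        a, _ = retain_tissue_clusters(a, binned, tissue_mask=None,
                                      background_quantile=0.35)
        assert a.retained[0] and not a.retained[1]


class TestUmap:
    def test_deterministic_and_shape(self):
        emb = embedding_from(np.random.default_rng(0).normal(size=(30, 5)))
        c1 = umap_embed(emb, seed=1)
        c2 = umap_embed(emb, seed=1)
        assert c1.shape == (30, 2)
        assert np.allclose(c1, c2)

    def test_blob_separation_preserved(self):
        rng = np.random.default_rng(2)
        coords = np.vstack([rng.normal(0, 0.5, (20, 4)),
                            rng.normal(50, 0.5, (20, 4))])
        out = umap_embed(embedding_from(coords), seed=0)
        # linear separability: nearest-centroid classification is perfect
        c0, c1 = out[:20].mean(axis=0), out[20:].mean(axis=0)
        d0 = np.linalg.norm(out - c0, axis=1)
        d1 = np.linalg.norm(out - c1, axis=1)
        pred = (d1 < d0).astype(int)
        assert pred[:20].sum() == 0 and pred[20:].sum() == 20
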