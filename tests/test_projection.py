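"""Projections, pruning, community detection and cluster validation."""

import igraph as ig
import numpy as np
import pytest

import gapmine as gm
from gapmine.projection import DETERMINISTIC_METHODS, ProjectionGraph
from _oracles import brute_force_silhouette


def _graph_from_weights(W):
    n = W.shape[0]
    src, tgt = np.nonzero(np.triu(W, k=1))
    g = ig.Graph(n=n, edges=list(zip(src.tolist(), tgt.tolist())))
    g.es["weight"] = [float(W[i, j]) for i, j in zip(src, tgt)]
    return ProjectionGraph("V", [f"n{i}" for i in range(n)], g, np.zeros(n))


def _two_cliques(k=5, w_in=1.0):
    W = np.zeros((2 * k, 2 * k))
    W[:k, :k] = w_in
    W[k:, k:] = w_in
    np.fill_diagonal(W, 0.0)
    return _graph_from_weights(W)


# -------------------------------------------------------------- projection
class TestProject:
    def test_hand_product(self, mk):
        M = mk([[1.0, 2.0], [3.0, 4.0]])
        G = gm.project(M, "V")
        assert G.graph.ecount() == 1
        assert G.edge_weights[0] == pytest.approx(1 * 3 + 2 * 4)
        assert G.self_similarity == pytest.approx([5.0, 25.0])

    def test_identity_matrix_no_edges(self, mk):
        M = mk([[1.0, np.nan], [np.nan, 1.0]])
        assert gm.project(M, "V").graph.ecount() == 0
        assert gm.project(M, "W").graph.ecount() == 0

    def test_single_row(self, mk):
        M = mk([[1.0, 2.0, 3.0]])
        G = gm.project(M, "V")
        assert G.n_nodes == 1 and G.graph.ecount() == 0

    def test_matches_dense_oracle(self, mk, rng):
        A = np.where(rng.random((12, 9)) < 0.7, rng.random((12, 9)), np.nan)
        A[0, 0] = 1.0
        M = mk(A)
        G = gm.project(M, "W")
        A0 = np.nan_to_num(A, nan=0.0)
        S = A0.T @ A0
        for e in G.graph.es:
            assert e["weight"] == pytest.approx(S[e.source, e.target], abs=1e-12)
        # every positive off-diagonal entry is an edge
        off = np.triu(S, k=1)
        assert G.graph.ecount() == int((off > 0).sum())


# ----------------------------------------------------------------- pruning
class TestPruneWeakEdges:
    def test_zero_threshold_keeps_positive_weights(self):
        G = _graph_from_weights(np.array([[0, 1.0], [1.0, 0]]))
        assert gm.prune_weak_edges(G, threshold=0.0).graph.ecount() == 1

    def test_quantile_rule(self):
        W = np.zeros((5, 5))
        for (i, j), w in zip([(0, 1), (1, 2), (2, 3), (3, 4)], [1, 2, 3, 4]):
            W[i, j] = W[j, i] = w
        G = gm.prune_weak_edges(_graph_from_weights(W), quantile=0.5)
        assert sorted(G.edge_weights) == [3.0, 4.0]

    def test_prune_all_warns(self):
        G = _graph_from_weights(np.array([[0, 2.0], [2.0, 0]]))
        with pytest.warns(UserWarning):
            out = gm.prune_weak_edges(G, threshold=2.0)
        assert out.graph.ecount() == 0 and out.n_nodes == 2


# -------------------------------------------------------------- clustering
class TestFindClusters:
    def test_two_disconnected_triangles_all_methods(self):
        G = _two_cliques(k=3)
        for res in gm.find_clusters(G, methods="all", seed=5):
            mem = np.array([res.membership[n] for n in G.names])
            assert (mem[:3] == mem[0]).all() and (mem[3:] == mem[3]).all()
            assert mem[0] != mem[3], res.method

    def test_cliques_with_weak_bridge(self):
        W = np.zeros((10, 10))
        W[:5, :5] = 10.0
        W[5:, 5:] = 10.0
        np.fill_diagonal(W, 0.0)
        W[4, 5] = W[5, 4] = 1.0
        G = _graph_from_weights(W)
        for method in ("multilevel", "fast_greedy", "walktrap", "leading_eigenvector"):
            res = gm.find_clusters(G, methods=method, seed=2)[0]
            mem = np.array([res.membership[n] for n in G.names])
            assert len(set(mem[:5])) == 1 and len(set(mem[5:])) == 1
            assert mem[0] != mem[9]
            assert res.Q == pytest.approx(
                gm.modularity(G.graph, mem), abs=1e-12
            )

    def test_uniform_complete_graph_single_cluster(self):
        W = np.ones((6, 6)) - np.eye(6)
        res = gm.find_clusters(_graph_from_weights(W), methods="multilevel", seed=1)[0]
        assert res.n_clusters == 1
        assert res.Q == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_methods_stable(self):
        W = np.zeros((12, 12))
        rng = np.random.default_rng(4)
        idx = np.triu_indices(12, k=1)
        vals = rng.random(len(idx[0]))
        W[idx] = vals
        W += W.T
        G = _graph_from_weights(W)
        for method in DETERMINISTIC_METHODS:
            a = gm.find_clusters(G, methods=method, seed=3)[0].membership
            b = gm.find_clusters(G, methods=method, seed=3)[0].membership
            assert a == b

    def test_spinglass_on_disconnected_graph(self):
        G = _two_cliques(k=5)
        res = gm.find_clusters(G, methods="spinglass", seed=11)[0]
        mem = np.array([res.membership[n] for n in G.names])
        assert len(set(mem[:5])) == 1 and len(set(mem[5:])) == 1
        assert mem[0] != mem[5]

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            gm.find_clusters(_two_cliques(), methods="best_method_ever")


# -------------------------------------------------------------- silhouette
class TestSilhouette:
    def test_two_cliques_matches_brute_force(self):
        G = _two_cliques(k=4, w_in=1.0)
        mem = [0] * 4 + [1] * 4
        from gapmine.projection import graph_distances

        D = graph_distances(G)
        expected = brute_force_silhouette(D, mem)
        assert gm.silhouette_score(G, mem) == pytest.approx(expected, abs=1e-9)
        # within-distance d, between-distance 2d (unreachable penalty):
        # each term is (2d - d)/2d = 1/2 regardless of the edge weight
        assert expected == pytest.approx(0.5)

    def test_random_partition_of_uniform_graph_nonpositive(self):
        W = 3.0 * (np.ones((8, 8)) - np.eye(8))
        G = _graph_from_weights(W)
        mem = [0, 1, 0, 1, 0, 1, 0, 1]
        assert gm.silhouette_score(G, mem) <= 0.0

    def test_all_singletons_zero_by_convention(self):
        G = _two_cliques(k=3)
        assert gm.silhouette_score(G, list(range(6))) == 0.0

    def test_single_cluster_undefined(self):
        G = _two_cliques(k=3)
        assert np.isnan(gm.silhouette_score(G, [0] * 6))

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(5):
            n = 9
            W = np.zeros((n, n))
            idx = np.triu_indices(n, k=1)
            w = np.where(rng.random(len(idx[0])) < 0.5, rng.random(len(idx[0])), 0.0)
            W[idx] = w
            W += W.T
            if not W.any():
                continue
            G = _graph_from_weights(W)
            mem = rng.integers(0, 3, size=n)
            if len(set(mem.tolist())) < 2:
                continue
            from gapmine.projection import graph_distances

            expected = brute_force_silhouette(graph_distances(G), mem)
            assert gm.silhouette_score(G, mem) == pytest.approx(expected, abs=1e-9)


# ------------------------------------------------------ external validation
class TestExternalValidation:
    def test_identical_partitions(self):
        mem = {"a": 0, "b": 0, "c": 1}
        out = gm.external_validation(mem, {"a": "x", "b": "x", "c": "y"})
        assert out == {"rand": 1.0, "jaccard": 1.0}

    def test_crossed_partitions(self):
        out = gm.external_validation(
            {"a": 0, "b": 0, "c": 1}, {"a": 0, "b": 1, "c": 1}
        )
        assert out["rand"] == pytest.approx(1 / 3)
        assert out["jaccard"] == 0.0

    def test_big_cluster_vs_singletons(self):
        out = gm.external_validation(
            {"a": 0, "b": 0, "c": 0}, {"a": 0, "b": 1, "c": 2}
        )
        assert out["rand"] == 0.0 and out["jaccard"] == 0.0

    def test_rand_symmetric(self, rng):
        nodes = [f"n{i}" for i in range(10)]
        m1 = {n: int(rng.integers(0, 3)) for n in nodes}
        m2 = {n: int(rng.integers(0, 3)) for n in nodes}
        assert gm.external_validation(m1, m2)["rand"] == pytest.approx(
            gm.external_validation(m2, m1)["rand"]
        )
        assert gm.external_validation(m1, m2)["jaccard"] == pytest.approx(
            gm.external_validation(m2, m1)["jaccard"]
        )

    def test_mismatched_nodes_raise(self):
        with pytest.raises(ValueError):
            gm.external_validation({"a": 0}, {"b": 0})
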