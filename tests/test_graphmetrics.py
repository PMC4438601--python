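import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netchange.graphmetrics import (WeightedGraph, threshold_proportional,
                                    clustering_coefficient, clustering_mean,
                                    path_and_efficiency, path_efficiency_detail,
                                    local_efficiency, newman_modularity,
                                    modularity, randomize_graph,
                                    normalized_metrics, node_level_metrics,
                                    metric_curves)
from conftest import random_weighted_graph


# ---------------------------------------------------------------- oracles

def clustering_oracle(W):
    """Exhaustive triangle enumeration of Onnela clustering."""
    n = W.shape[0]
    if W.max() == 0:
        return np.zeros(n)
    Wh = W / W.max()
    c = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(W[i] > 0)
        k = nb.size
        if k < 2:
            continue
        tri = 0.0
        for j, h in itertools.combinations(nb, 2):
            if W[j, h] > 0:
                tri += (Wh[i, j] * Wh[i, h] * Wh[j, h]) ** (1 / 3)
        c[i] = 2 * tri / (k * (k - 1))
    return c


def shortest_paths_oracle(W):
    """All-pairs shortest distance by brute-force simple-path enumeration."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    nodes = list(range(n))

    def all_paths(s, t, visited):
        if s == t:
            yield [t]
            return
        for nxt in nodes:
            if W[s, nxt] > 0 and nxt not in visited:
                for rest in all_paths(nxt, t, visited | {nxt}):
                    yield [s] + rest

    for s in range(n):
        for t in range(s + 1, n):
            best = np.inf
            for path in all_paths(s, t, {s}):
                length = sum(1.0 / W[path[q], path[q + 1]]
                             for q in range(len(path) - 1))
                best = min(best, length)
            D[s, t] = D[t, s] = best
    return D


def efficiency_from_distances(D):
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    inv = np.where(np.isfinite(D[off]), 1.0 / D[off], 0.0)
    return float(inv.mean())


def set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, sub in enumerate(smaller):
            yield smaller[:i] + [[first] + sub] + smaller[i + 1:]
        yield [[first]] + smaller


def best_partition_oracle(W):
    """Exhaustive maximum modularity over all set partitions."""
    n = W.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(n))):
        member = np.empty(n, int)
        for label, block in enumerate(part):
            member[block] = label
        best = max(best, newman_modularity(W, member))
    return best


def betweenness_oracle(W):
    """Node and edge betweenness by enumerating all shortest paths."""
    n = W.shape[0]
    D = shortest_paths_oracle(W)
    node_b = np.zeros(n)
    edge_b = {}
    nodes = list(range(n))

    def all_paths(s, t, visited):
        if s == t:
            yield [t]
            return
        for nxt in nodes:
            if W[s, nxt] > 0 and nxt not in visited:
                for rest in all_paths(nxt, t, visited | {nxt}):
                    yield [s] + rest

    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(D[s, t]):
                continue
            shortest = []
            for path in all_paths(s, t, {s}):
                length = sum(1.0 / W[path[q], path[q + 1]]
                             for q in range(len(path) - 1))
                if abs(length - D[s, t]) < 1e-9:
                    shortest.append(path)
            total = len(shortest)
            for path in shortest:
                for v in path[1:-1]:
                    node_b[v] += 1.0 / total
                for q in range(len(path) - 1):
                    e = (min(path[q], path[q + 1]), max(path[q], path[q + 1]))
                    edge_b[e] = edge_b.get(e, 0.0) + 1.0 / total
    return node_b, edge_b


# ------------------------------------------------------------- threshold

class TestThreshold:
    def test_k4_keeps_three_strongest(self):
        W = np.zeros((4, 4))
        weights = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7,
                   (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4}
        for (i, j), w in weights.items():
            W[i, j] = W[j, i] = w
        g = threshold_proportional(W, 0.5)
        assert g.n_edges == 3
        assert g.adjacency[0, 1] == 0.9
        assert g.adjacency[0, 2] == 0.8
        assert g.adjacency[0, 3] == 0.7
        assert g.adjacency[2, 3] == 0.0

    def test_full_sparsity_keeps_positive_part(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(6, 6))
        W = np.triu(W, 1) + np.triu(W, 1).T
        with pytest.warns(UserWarning):
            g = threshold_proportional(W, 0.999)
        np.testing.assert_array_equal(g.adjacency, np.where(W > 0, W, 0.0))

    def test_tie_break_is_lexicographic_and_stable(self):
        W = np.zeros((4, 4))
        for (i, j) in [(0, 1), (0, 2), (0, 3), (1, 2)]:
            W[i, j] = W[j, i] = 0.5  # four-way tie
        runs = [threshold_proportional(W, 2 / 6).adjacency for _ in range(3)]
        np.testing.assert_array_equal(runs[0], runs[1])
        np.testing.assert_array_equal(runs[0], runs[2])
        # explicit oracle: sort by (-w, i, j) keeps (0,1) and (0,2)
        assert runs[0][0, 1] == 0.5 and runs[0][0, 2] == 0.5
        assert runs[0][0, 3] == 0.0 and runs[0][1, 2] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.05, 0.95))
    def test_edge_count_property(self, seed, S):
        rng = np.random.default_rng(seed)
        W = random_weighted_graph(rng, 10, p=0.6, ensure_connected=False)
        n_pos = int((W[np.triu_indices(10, 1)] > 0).sum())
        m_req = int(round(S * 45))
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            g = threshold_proportional(W, S)
        assert g.n_edges == min(m_req, n_pos)


# ---------------------------------------------------------------- metrics

class TestClustering:
    def test_binary_triangle(self):
        W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
        np.testing.assert_allclose(clustering_coefficient(W), 1.0)
        assert clustering_mean(W) == 1.0

    def test_star_has_no_triangles(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        assert clustering_mean(W) == 0.0

    def test_matches_triangle_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            W = random_weighted_graph(rng, 6, p=0.6, ensure_connected=False)
            np.testing.assert_allclose(clustering_coefficient(W),
                                       clustering_oracle(W), atol=1e-12)


class TestPaths:
    def test_binary_k4(self):
        W = 1.0 - np.eye(4)
        L, eg = path_and_efficiency(W)
        assert L == pytest.approx(1.0)
        assert eg == pytest.approx(1.0)

    def test_binary_path_graph(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 2] = 1.0
        W = W + W.T
        L, eg = path_and_efficiency(W)
        assert L == pytest.approx(4 / 3)
        assert eg == pytest.approx(5 / 6)

    def test_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(2)
        W = random_weighted_graph(rng, 7, p=0.5)
        D = shortest_paths_oracle(W)
        off = ~np.eye(7, dtype=bool)
        L, eg = path_and_efficiency(W)
        assert L == pytest.approx(D[off][np.isfinite(D[off])].mean(),
                                  abs=1e-12)
        assert eg == pytest.approx(efficiency_from_distances(D), abs=1e-12)

    def test_disconnected_pairs_counted(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        L, eg, n_disc = path_efficiency_detail(W)
        assert n_disc == 8
        assert L == pytest.approx(1.0)
        assert eg == pytest.approx(4 / 12)


class TestLocalEfficiency:
    def test_binary_triangle_all_ones(self):
        W = 1.0 - np.eye(3)
        eloc, mean = local_efficiency(W)
        np.testing.assert_allclose(eloc, 1.0)

    def test_star_zero(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        _, mean = local_efficiency(W)
        assert mean == 0.0

    def test_matches_induced_subgraph_oracle(self):
        rng = np.random.default_rng(3)
        W = random_weighted_graph(rng, 8, p=0.5)
        eloc, _ = local_efficiency(W)
        for i in range(8):
            nb = np.flatnonzero(W[i] > 0)
            if nb.size < 2:
                assert eloc[i] == 0.0
                continue
            D = shortest_paths_oracle(W[np.ix_(nb, nb)])
            assert eloc[i] == pytest.approx(efficiency_from_distances(D),
                                            abs=1e-12)


class TestModularity:
    def test_two_disconnected_cliques(self):
        block = 1.0 - np.eye(4)
        W = np.block([[block, np.zeros((4, 4))], [np.zeros((4, 4)), block]])
        q, member = modularity(W, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(np.unique(member)) == 2
        assert len(np.unique(member[:4])) == 1

    def test_single_community_zero_by_formula(self):
        rng = np.random.default_rng(4)
        W = random_weighted_graph(rng, 6, p=0.7)
        assert newman_modularity(W, np.zeros(6, int)) == pytest.approx(
            0.0, abs=1e-12)

    def test_louvain_attains_enumerated_optimum(self):
        # exact_max=0 forces the Louvain branch even on tiny graphs
        rng = np.random.default_rng(5)
        for _ in range(5):
            W = random_weighted_graph(rng, 6, p=0.5)
            q, _ = modularity(W, n_restarts=20, seed=1, exact_max=0)
            assert q == pytest.approx(best_partition_oracle(W), abs=1e-12)

    def test_exact_branch_agrees_with_louvain_when_louvain_succeeds(self):
        rng = np.random.default_rng(6)
        W = random_weighted_graph(rng, 7, p=0.6)
        q_exact, _ = modularity(W, seed=0)
        q_louvain, _ = modularity(W, n_restarts=50, seed=0, exact_max=0)
        assert q_louvain <= q_exact + 1e-12


class TestRandomize:
    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_degree_and_weight_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        W = random_weighted_graph(rng, 10, p=0.4, ensure_connected=False)
        null = randomize_graph(W, seed=seed + 1)
        np.testing.assert_array_equal((W > 0).sum(1),
                                      (null.adjacency > 0).sum(1))
        iu = np.triu_indices(10, 1)
        np.testing.assert_allclose(np.sort(W[iu][W[iu] > 0]),
                                   np.sort(null.adjacency[iu][
                                       null.adjacency[iu] > 0]), atol=0)

    def test_lattice_clustering_destroyed(self):
        import networkx as nx

        W = nx.to_numpy_array(nx.watts_strogatz_graph(30, 4, 0.0, seed=0))
        c_orig = clustering_mean(W)
        rng = np.random.default_rng(0)
        c_null = np.mean([clustering_mean(randomize_graph(W, rng=rng).adjacency)
                          for _ in range(100)])
        assert c_null < c_orig

    def test_rewiring_actually_changes_topology(self):
        rng = np.random.default_rng(6)
        W = random_weighted_graph(rng, 12, p=0.3)
        null = randomize_graph(W, seed=3)
        assert not np.array_equal(W > 0, null.adjacency > 0)


class TestNormalized:
    def test_sigma_consistent_with_null_means(self):
        rng = np.random.default_rng(7)
        W = random_weighted_graph(rng, 15, p=0.4)
        gm = normalized_metrics(W, n_rand=6, seed=11, keep_null_values=True)
        c_null = np.array(gm.null_values["clustering"])
        l_null = np.array(gm.null_values["path_length"])
        gamma = gm.clustering / c_null[c_null > 0].mean()
        lam = gm.path_length / l_null[np.isfinite(l_null)].mean()
        assert gm.gamma == pytest.approx(gamma, rel=1e-12)
        assert gm.lam == pytest.approx(lam, rel=1e-12)
        assert gm.sigma == pytest.approx(gamma / lam, rel=1e-12)

    def test_small_world_ring_exceeds_random(self):
        import networkx as nx

        ws = nx.to_numpy_array(nx.watts_strogatz_graph(60, 6, 0.1, seed=1))
        er = nx.to_numpy_array(nx.gnp_random_graph(60, 0.3, seed=1))
        sw = normalized_metrics(ws, n_rand=20, seed=2, n_restarts=1,
                                normalize_efficiency=False)
        rnd = normalized_metrics(er, n_rand=20, seed=2, n_restarts=1,
                                 normalize_efficiency=False)
        assert sw.sigma > 1.5
        assert 0.7 < rnd.sigma < 1.3
        assert sw.sigma > rnd.sigma


class TestNodeMetrics:
    def test_star_center_betweenness(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        nm = node_level_metrics(W)
        assert nm.betweenness[0] == pytest.approx(6.0)  # (n-1)(n-2)/2
        np.testing.assert_allclose(nm.betweenness[1:], 0.0)
        np.testing.assert_array_equal(nm.degree, [4, 1, 1, 1, 1])

    def test_bridge_edge_has_maximal_edge_betweenness(self):
        # two triangles joined by a single bridge edge (2,3)
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)]:
            W[i, j] = W[j, i] = 1.0
        nm = node_level_metrics(W)
        bridge = nm.edge_betweenness[(2, 3)]
        assert bridge == max(nm.edge_betweenness.values())
        _, edge_oracle = betweenness_oracle(W)
        for e, v in edge_oracle.items():
            assert nm.edge_betweenness[e] == pytest.approx(v, abs=1e-9)

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        W = random_weighted_graph(rng, 7, p=0.5)
        nm = node_level_metrics(W)
        node_oracle, edge_oracle = betweenness_oracle(W)
        np.testing.assert_allclose(nm.betweenness, node_oracle, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        W = random_weighted_graph(rng, 7, p=0.6)
        perm = rng.permutation(7)
        Wp = W[np.ix_(perm, perm)]
        a = node_level_metrics(W)
        b = node_level_metrics(Wp)
        np.testing.assert_allclose(b.betweenness, a.betweenness[perm],
                                   atol=1e-9)
        np.testing.assert_allclose(b.clustering, a.clustering[perm],
                                   atol=1e-12)


class TestScaleInvariance:
    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    def test_weight_rescaling_invariants(self, seed, scale):
        rng = np.random.default_rng(seed)
        W = random_weighted_graph(rng, 8, p=0.5)
        np.testing.assert_allclose(clustering_coefficient(W * scale),
                                   clustering_coefficient(W), atol=1e-12)
        np.testing.assert_array_equal((W * scale > 0).sum(1), (W > 0).sum(1))
        q1, m1 = modularity(W, n_restarts=5, seed=0)
        q2, m2 = modularity(W * scale, n_restarts=5, seed=0)
        assert q1 == pytest.approx(q2, abs=1e-12)


class TestMetricCurves:
    def test_single_point_grid(self):
        rng = np.random.default_rng(10)
        W = random_weighted_graph(rng, 12, p=0.8)
        curves = metric_curves(W, sparsity_grid=(0.3,), n_rand=3, seed=0,
                               n_restarts=2)
        assert set(curves["sparsity"]) == {0.3}
        assert len(curves) == 10  # one row per metric

    def test_grid_refinement_preserves_shared_points(self):
        rng = np.random.default_rng(11)
        W = random_weighted_graph(rng, 12, p=0.8)
        coarse = metric_curves(W, sparsity_grid=(0.2, 0.4), n_rand=3, seed=5,
                               n_restarts=2)
        fine = metric_curves(W, sparsity_grid=(0.2, 0.3, 0.4), n_rand=3,
                             seed=5, n_restarts=2)
        for s in (0.2, 0.4):
            a = coarse[coarse["sparsity"] == s].set_index("metric")["value"]
            b = fine[fine["sparsity"] == s].set_index("metric")["value"]
            np.testing.assert_allclose(a.to_numpy(), b[a.index].to_numpy(),
                                       atol=1e-12)

    def test_rerun_identical(self):
        rng = np.random.default_rng(12)
        W = random_weighted_graph(rng, 12, p=0.8)
        a = metric_curves(W, sparsity_grid=(0.2, 0.4), n_rand=4, seed=9)
        b = metric_curves(W, sparsity_grid=(0.2, 0.4), n_rand=4, seed=9)
        np.testing.assert_array_equal(a["value"].to_numpy(),
                                      b["value"].to_numpy())
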