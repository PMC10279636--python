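"""Thresholding and network statistics against brute-force oracles."""

import numpy as np
import pytest

from plvnet.graphs import (
    NodeSetAssignment,
    ThresholdedGraph,
    global_efficiency,
    modularity,
    modularity_value,
    proportional_threshold,
    routing_efficiency,
    routing_matrix,
    shortest_paths,
)

from conftest import (
    enumerate_shortest_paths,
    exhaustive_best_modularity,
    random_weighted_graph,
)


def _graph_from_edges(n, edges):
    adj = np.zeros((n, n))
    for i, j, w in edges:
        adj[i, j] = adj[j, i] = w
    n_edges = len(edges)
    return ThresholdedGraph(adjacency=adj, density=n_edges / (n * (n - 1) / 2), n_edges=n_edges)


class TestProportionalThreshold:
    def test_keeps_strongest_edges(self):
        mat = np.eye(4)
        weights = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1}
        for (i, j), w in weights.items():
            mat[i, j] = mat[j, i] = w
        g = proportional_threshold(mat, density=0.5)
        assert g.n_edges == 3
        kept = {(i, j) for i, j in zip(*np.triu_indices(4, 1)) if g.adjacency[i, j] > 0}
        assert kept == {(0, 1), (0, 2), (0, 3)}
        assert g.adjacency[0, 1] == 0.9  # weighted, not binarized

    def test_full_density_identity(self, rng):
        mat = rng.uniform(0.1, 1.0, (5, 5))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        g = proportional_threshold(mat, density=1.0)
        expected = mat.copy()
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(g.adjacency, expected)

    def test_whole_brain_edge_count(self, rng):
        mat = rng.uniform(0, 1, (148, 148))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        g = proportional_threshold(mat, density=0.2)
        assert g.n_edges == 2176  # round(0.2 * 148 * 147 / 2)

    def test_tie_break_deterministic(self):
        mat = np.eye(4)
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
            mat[i, j] = mat[j, i] = 0.5
        g1 = proportional_threshold(mat, density=0.5)
        g2 = proportional_threshold(mat, density=0.5)
        np.testing.assert_array_equal(g1.adjacency, g2.adjacency)
        assert g1.adjacency[0, 1] > 0  # lowest-index pairs first

    def test_invalid_density(self):
        with pytest.raises(ValueError):
            proportional_threshold(np.eye(3), density=0.0)


class TestShortestPaths:
    def test_unit_weight_path(self):
        g = _graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
        d = shortest_paths(g)
        assert d[0, 2] == pytest.approx(2.0)

    def test_triangle_direct_vs_two_hop(self):
        # direct edge weight 1 -> length 1; two 0.5-edges -> 2 + 2 = 4
        g = _graph_from_edges(3, [(0, 1, 0.5), (1, 2, 0.5), (0, 2, 1.0)])
        d = shortest_paths(g)
        assert d[0, 2] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            g = random_weighted_graph(rng, n, density=0.45)
            np.testing.assert_allclose(
                shortest_paths(g), enumerate_shortest_paths(g.adjacency), atol=1e-12
            )

    def test_negative_weight_rejected(self):
        g = _graph_from_edges(3, [(0, 1, 1.0)])
        g.adjacency[0, 1] = g.adjacency[1, 0] = -0.5
        with pytest.raises(ValueError):
            shortest_paths(g)


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        g = _graph_from_edges(4, [(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)])
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_three_node_path(self):
        g = _graph_from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])
        assert global_efficiency(g) == pytest.approx(5.0 / 6.0)

    def test_edgeless_graph(self):
        g = ThresholdedGraph(adjacency=np.zeros((4, 4)), density=0.0, n_edges=0)
        assert global_efficiency(g) == 0.0

    def test_too_small(self):
        g = ThresholdedGraph(adjacency=np.zeros((1, 1)), density=0.0, n_edges=0)
        with pytest.raises(ValueError):
            global_efficiency(g)


class TestModularity:
    def test_single_community_is_zero(self, rng):
        g = random_weighted_graph(rng, 7, density=0.5)
        q = modularity_value(g.adjacency, np.zeros(7, dtype=int))
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques(self):
        edges = [(i, j, 1.0) for i in range(3) for j in range(i + 1, 3)]
        edges += [(i, j, 1.0) for i in range(3, 6) for j in range(i + 1, 6)]
        g = _graph_from_edges(6, edges)
        part = modularity(g, n_restarts=20, seed=0)
        assert part.q == pytest.approx(0.5, abs=1e-12)
        labels = [part.communities[f"node{i}"] for i in range(6)]
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]
        best_q, _ = exhaustive_best_modularity(g.adjacency)
        assert best_q == pytest.approx(0.5, abs=1e-12)

    def test_reported_q_equals_formula(self, rng):
        g = random_weighted_graph(rng, 8, density=0.5)
        part = modularity(g, n_restarts=10, seed=3)
        member = np.array([part.communities[f"node{i}"] for i in range(8)])
        assert part.q == pytest.approx(modularity_value(g.adjacency, member), abs=1e-12)

    def test_louvain_near_exhaustive_optimum(self, rng):
        hits = 0
        trials = 20
        for _ in range(trials):
            n = int(rng.integers(5, 8))
            g = random_weighted_graph(rng, n, density=0.5)
            if g.n_edges == 0:
                hits += 1
                continue
            part = modularity(g, n_restarts=20, seed=1)
            best_q, _ = exhaustive_best_modularity(g.adjacency)
            if best_q <= 0 or part.q >= 0.95 * best_q:
                hits += 1
        assert hits >= 0.95 * trials

    def test_deterministic_given_seed(self, rng):
        g = random_weighted_graph(rng, 10, density=0.4)
        a = modularity(g, n_restarts=15, seed=42)
        b = modularity(g, n_restarts=15, seed=42)
        assert a.q == b.q
        assert a.communities == b.communities

    def test_empty_graph_rejected(self):
        g = ThresholdedGraph(adjacency=np.zeros((3, 3)), density=0.0, n_edges=0)
        with pytest.raises(ValueError):
            modularity(g)


class TestRouting:
    def test_chain_inverse_path_length(self):
        g = _graph_from_edges(4, [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)])
        r = routing_matrix(g)
        assert r.r[0, 3] == pytest.approx(1.0 / 3.0)
        np.testing.assert_allclose(np.diag(r.r), 1.0)

    def test_disconnected_components_zero(self):
        g = _graph_from_edges(4, [(0, 1, 1.0), (2, 3, 1.0)])
        r = routing_matrix(g)
        assert r.r[0, 2] == 0.0
        assert r.r[1, 3] == 0.0

    def test_adjacent_cross_pair(self):
        g = _graph_from_edges(4, [(0, 2, 0.9), (0, 1, 0.3), (2, 3, 0.2)])
        sets = NodeSetAssignment(core={"node0", "node1"}, extended={"node2", "node3"})
        r = routing_matrix(g)
        assert routing_efficiency(r, sets) == pytest.approx(0.9)

    def test_cross_component_sets_zero(self):
        g = _graph_from_edges(4, [(0, 1, 1.0), (2, 3, 1.0)])
        sets = NodeSetAssignment(core={"node0", "node1"}, extended={"node2", "node3"})
        assert routing_efficiency(routing_matrix(g), sets) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(15):
            n = int(rng.integers(5, 11))
            g = random_weighted_graph(rng, n, density=0.4)
            labels = g.node_labels
            half = n // 2
            sets = NodeSetAssignment(core=set(labels[:half]), extended=set(labels[half:]))
            d = enumerate_shortest_paths(g.adjacency)
            with np.errstate(divide="ignore"):
                inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1), 0.0)
            expected = inv[:half, half:].max()
            assert routing_efficiency(routing_matrix(g), sets) == pytest.approx(
                expected, abs=1e-12
            )

    def test_empty_set_rejected(self):
        g = _graph_from_edges(3, [(0, 1, 1.0)])
        sets = NodeSetAssignment(core={"nodeX"}, extended={"node1"})
        with pytest.raises(ValueError):
            routing_efficiency(routing_matrix(g), sets)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            NodeSetAssignment(core={"a"}, extended={"a", "b"})


class TestMonotonicity:
    def test_edge_addition_never_decreases_efficiency(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 9))
            g = random_weighted_graph(rng, n, density=0.3)
            absent = [
                (i, j)
                for i, j in zip(*np.triu_indices(n, 1))
                if g.adjacency[i, j] == 0
            ]
            if not absent:
                continue
            i, j = absent[int(rng.integers(len(absent)))]
            before_ge = global_efficiency(g)
            sets = NodeSetAssignment(
                core=set(g.node_labels[: n // 2]), extended=set(g.node_labels[n // 2 :])
            )
            before_re = routing_efficiency(routing_matrix(g), sets)
            adj = g.adjacency.copy()
            adj[i, j] = adj[j, i] = rng.uniform(0.1, 1.0)
            g2 = ThresholdedGraph(adjacency=adj, density=0.0, n_edges=g.n_edges + 1)
            assert global_efficiency(g2) >= before_ge - 1e-12
            assert routing_efficiency(routing_matrix(g2), sets) >= before_re - 1e-12


def test_values_bounded_for_plv_weights(rng):
    for _ in range(5):
        g = random_weighted_graph(rng, 8, density=0.5)
        assert 0.0 <= global_efficiency(g) <= 1.0
        r = routing_matrix(g).r
        assert r.min() >= 0.0 and r.max() <= 1.0 + 1e-12


def test_node_set_csv_roundtrip(tmp_path):
    sets = NodeSetAssignment(core={"lh_A", "rh_A"}, extended={"lh_B"})
    path = tmp_path / "sets.csv"
    sets.to_csv(path)
    back = NodeSetAssignment.from_csv(path)
    assert back.core == sets.core
    assert back.extended == sets.extended
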