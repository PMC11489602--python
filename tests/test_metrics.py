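"""Graph measures against independent oracles.

Betweenness is checked against an exhaustive shortest-path enumeration on all
small graphs; core-periphery against exhaustive evaluation of every two-block
assignment; modularity against planted structure and self-consistency.
"""

import itertools

import numpy as np
import pytest

from symptomnet import (
    betweenness,
    core_periphery,
    degree,
    modularity_partition,
    strength,
)
from symptomnet.data import PrevalenceSummary
from symptomnet.metrics import (
    NodeMetrics,
    core_periphery_quality,
    node_metric_table,
)


def brute_force_betweenness(adj):
    """Enumerate all shortest paths between every unordered pair (test oracle)."""
    k = adj.shape[0]
    bc = np.zeros(k)
    for s, t in itertools.combinations(range(k), 2):
        # BFS-free exhaustive search: enumerate all simple paths, keep shortest
        paths = []
        stack = [[s]]
        while stack:
            path = stack.pop()
            node = path[-1]
            if node == t:
                paths.append(path)
                continue
            for nxt in range(k):
                if adj[node, nxt] and nxt not in path:
                    stack.append(path + [nxt])
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for p in geodesics:
            for inner in p[1:-1]:
                bc[inner] += 1.0 / len(geodesics)
    return bc


def exhaustive_core_periphery(weights):
    """Best two-block assignment by evaluating all 2^k of them (test oracle)."""
    k = weights.shape[0]
    best_q, best_c = -np.inf, np.zeros(k, dtype=bool)
    for bits in itertools.product([False, True], repeat=k):
        c = np.array(bits)
        q = core_periphery_quality(weights, c)
        if not np.isnan(q) and q > best_q:
            best_q, best_c = q, c
    return best_c, best_q


def adjacency_networks():
    """Every connected-ish test topology on <= 7 nodes used for the sweep."""
    graphs = []
    # all graphs on 4 nodes; a sample of named topologies on 5-7
    for n_edges in range(0, 7):
        for edges in itertools.combinations(itertools.combinations(range(4), 2), n_edges):
            adj = np.zeros((4, 4), dtype=bool)
            for i, j in edges:
                adj[i, j] = adj[j, i] = True
            graphs.append(adj)
    named = [
        [(0, 1), (1, 2), (2, 3), (3, 4)],                      # path P5
        [(0, 1), (0, 2), (0, 3), (0, 4)],                      # star
        [(0, 1), (1, 2), (2, 0), (2, 3), (3, 4), (4, 5)],      # lollipop
        [(0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (4, 5), (5, 6)],
        [(i, j) for i, j in itertools.combinations(range(6), 2)],  # K6
    ]
    for edges in named:
        k = max(max(e) for e in edges) + 1
        adj = np.zeros((k, k), dtype=bool)
        for i, j in edges:
            adj[i, j] = adj[j, i] = True
        graphs.append(adj)
    return graphs


class TestDegreeStrength:
    def test_empty_network_all_zero(self, network_factory):
        net = network_factory(np.zeros((4, 4)))
        assert degree(net).sum() == 0
        assert strength(net).sum() == 0.0

    def test_complete_graph_degrees(self, network_factory):
        w = np.full((4, 4), 0.1)
        np.fill_diagonal(w, 0)
        net = network_factory(w)
        np.testing.assert_array_equal(degree(net), [3, 3, 3, 3])

    def test_star_degrees(self, network_factory):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.2
        net = network_factory(w)
        np.testing.assert_array_equal(degree(net), [4, 1, 1, 1, 1])

    def test_single_edge_strength(self, network_factory):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.23
        net = network_factory(w)
        np.testing.assert_allclose(strength(net), [0.23, 0.23, 0, 0])

    def test_strength_linear_in_weights(self, network_factory, rng):
        w = np.triu(rng.uniform(0.01, 0.3, (5, 5)), 1)
        w = w + w.T
        assert np.allclose(
            strength(network_factory(2 * w)), 2 * strength(network_factory(w))
        )

    def test_handshake_identities(self, network_factory, rng):
        w = np.triu(rng.uniform(0, 0.3, (6, 6)) * (rng.random((6, 6)) < 0.5), 1)
        w = w + w.T
        net = network_factory(w)
        assert degree(net).sum() == 2 * net.n_edges
        assert strength(net).sum() == pytest.approx(
            2 * np.triu(w * net.significant, 1).sum()
        )


class TestBetweenness:
    def test_path_graph_center(self, network_factory):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 0.2
        bc = betweenness(network_factory(w))
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_complete_graph_zero(self, network_factory):
        w = np.full((5, 5), 0.1)
        np.fill_diagonal(w, 0)
        assert betweenness(network_factory(w)).max() == 0.0

    def test_exhaustive_sweep_small_graphs(self, network_factory):
        """Unweighted betweenness equals brute-force path enumeration."""
        for adj in adjacency_networks():
            net = network_factory(adj * 0.2)
            np.testing.assert_allclose(
                betweenness(net), brute_force_betweenness(adj), atol=1e-9
            )

    def test_inverse_weight_mode_uses_strong_edges(self, network_factory):
        # triangle with one weak direct edge: the weighted geodesic 0-2 runs
        # through node 1 (1/0.5 + 1/0.5 = 4 < 1/0.1 = 10)
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 0.5
        w[0, 2] = w[2, 0] = 0.1
        net = network_factory(w)
        assert betweenness(net, mode="unweighted")[1] == 0.0
        assert betweenness(net, mode="inverse-weight")[1] == pytest.approx(1.0)

    def test_unknown_mode_rejected(self, network_factory):
        with pytest.raises(ValueError, match="unknown betweenness mode"):
            betweenness(network_factory(np.zeros((3, 3))), mode="harmonic")


class TestCorePeriphery:
    def test_planted_ideal_core_recovered_exactly(self, network_factory):
        """Clique of 5 with all periphery wired to the core, no periphery-
        periphery edges: the ideal pattern, recovered exactly (checked against
        exhaustive evaluation of all 2^10 assignments)."""
        k = 10
        w = np.zeros((k, k))
        for i, j in itertools.combinations(range(5), 2):
            w[i, j] = w[j, i] = 0.3
        for p in range(5, k):
            for c in range(5):
                w[p, c] = w[c, p] = 0.2
        net = network_factory(w)
        is_core, quality = core_periphery(
            net, restarts=40, rng=np.random.default_rng(0)
        )
        best_c, best_q = exhaustive_core_periphery(w)
        np.testing.assert_array_equal(is_core, best_c)
        np.testing.assert_array_equal(is_core, [True] * 5 + [False] * 5)
        assert quality == pytest.approx(best_q, abs=1e-12)

    def test_pendant_periphery_attains_exhaustive_optimum(self, network_factory):
        """With pendant (single-edge) periphery wiring the global optimum need
        not be the planted clique; the search must still find that optimum."""
        k = 10
        w = np.zeros((k, k))
        for i, j in itertools.combinations(range(5), 2):
            w[i, j] = w[j, i] = 0.3
        for p in range(5):
            w[p, 5 + p] = w[5 + p, p] = 0.2
        net = network_factory(w)
        _, quality = core_periphery(net, restarts=40, rng=np.random.default_rng(0))
        _, best_q = exhaustive_core_periphery(w)
        assert quality == pytest.approx(best_q, abs=1e-12)

    def test_empty_network_all_periphery(self, network_factory):
        net = network_factory(np.zeros((5, 5)))
        is_core, quality = core_periphery(net, restarts=10)
        assert not is_core.any()
        assert np.isnan(quality)

    def test_fewer_than_three_nodes_error(self, network_factory):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.2
        with pytest.raises(ValueError, match="at least 3"):
            core_periphery(network_factory(w))

    def test_matches_exhaustive_search(self, network_factory, rng):
        """Local search attains the global optimum on random <= 10-node nets."""
        for trial in range(8):
            k = int(rng.integers(5, 11))
            w = np.triu(
                rng.uniform(0.05, 0.3, (k, k)) * (rng.random((k, k)) < 0.4), 1
            )
            w = w + w.T
            if not w.any():
                continue
            net = network_factory(w)
            is_core, quality = core_periphery(
                net, restarts=40, rng=np.random.default_rng(trial)
            )
            _, best_q = exhaustive_core_periphery(w * net.significant)
            assert quality == pytest.approx(best_q, abs=1e-9)

    def test_quality_invariant_to_relabeling(self, network_factory, rng):
        k = 8
        w = np.triu(rng.uniform(0.05, 0.3, (k, k)) * (rng.random((k, k)) < 0.5), 1)
        w = w + w.T
        net = network_factory(w)
        _, q1 = core_periphery(net, restarts=30, rng=np.random.default_rng(0))
        perm = rng.permutation(k)
        net_p = network_factory(w[np.ix_(perm, perm)])
        _, q2 = core_periphery(net_p, restarts=30, rng=np.random.default_rng(1))
        assert q1 == pytest.approx(q2, abs=1e-9)


class TestModularity:
    def _two_triangles(self, network_factory):
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)]:
            w[i, j] = w[j, i] = 0.2
        return network_factory(w)

    def test_two_disconnected_triangles_split_exactly(self, network_factory):
        net = self._two_triangles(network_factory)
        part = modularity_partition(net, restarts=10)
        labels = part.labels
        assert len(set(labels)) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_quality_recomputed_from_labels(self, network_factory):
        import networkx as nx

        net = self._two_triangles(network_factory)
        part = modularity_partition(net, restarts=5)
        g = net.to_graph()
        comms = [
            {net.variable_names[i] for i in range(6) if part.labels[i] == m}
            for m in sorted(set(part.labels))
        ]
        recomputed = nx.community.modularity(g, comms, weight="weight")
        assert part.quality == pytest.approx(recomputed, abs=1e-12)

    def test_isolated_nodes_become_singletons(self, network_factory):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 0.2
        part = modularity_partition(network_factory(w), restarts=5)
        # nodes 2, 3, 4 are isolated: each its own module
        assert len({part.labels[i] for i in (2, 3, 4)}) == 3

    def test_labels_renumbered_by_size(self, network_factory):
        w = np.zeros((7, 7))
        for i, j in [(0, 1), (1, 2), (2, 0), (0, 3), (4, 5)]:  # sizes 4 and 2 + iso
            w[i, j] = w[j, i] = 0.2
        part = modularity_partition(network_factory(w), restarts=10)
        sizes = [np.sum(part.labels == m) for m in sorted(set(part.labels))]
        assert sizes == sorted(sizes, reverse=True)
        assert part.labels.min() == 1

    def test_best_of_monotone_in_restarts(self, network_factory, rng):
        k = 12
        w = np.triu(rng.uniform(0.05, 0.3, (k, k)) * (rng.random((k, k)) < 0.3), 1)
        w = w + w.T
        net = network_factory(w)
        q1 = modularity_partition(net, restarts=1,
                                  rng=np.random.default_rng(0)).quality
        q20 = modularity_partition(net, restarts=20,
                                   rng=np.random.default_rng(0)).quality
        assert q20 >= q1 - 1e-12


class TestNodeTable:
    def _inputs(self, network_factory):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.23
        net = network_factory(w, names=["a", "b", "c"])
        prev = PrevalenceSummary(
            variable_names=["excluded", "a", "b", "c"],
            count_present=np.array([528, 251, 113, 80]),
            percent_present=np.array([99.8, 47.4, 21.4, 15.1]),
            n_patients=529,
        )
        metrics = NodeMetrics(
            variable_names=["a", "b", "c"],
            degree=np.array([1, 1, 0]),
            strength=np.array([0.23, 0.23, 0.0]),
            betweenness=np.array([0.0, 0.0, 0.0]),
            module_id=np.array([1, 1, 2]),
            is_core=np.array([True, True, False]),
        )
        return net, prev, metrics

    def test_excluded_variable_renders_dashes(self, network_factory):
        net, prev, metrics = self._inputs(network_factory)
        table = node_metric_table(net, prev, metrics)
        row = table[table["variable"] == "excluded"].iloc[0]
        assert row["n_pct"] == "528 (99.8)"
        assert list(row[["degree", "strength", "betweenness", "module",
                         "core_periphery"]]) == ["-"] * 5

    def test_schema_and_order(self, network_factory):
        net, prev, metrics = self._inputs(network_factory)
        table = node_metric_table(net, prev, metrics)
        assert table.shape[1] == 7
        assert list(table["variable"]) == prev.variable_names

    def test_formatting_conventions(self, network_factory):
        net, prev, metrics = self._inputs(network_factory)
        table = node_metric_table(net, prev, metrics)
        row = table[table["variable"] == "a"].iloc[0]
        assert row["strength"] == "0.2"  # one decimal
        assert row["core_periphery"] == "Core"
        assert isinstance(row["betweenness"], (int, np.integer))

    def test_mismatched_variable_sets_error(self, network_factory):
        net, prev, metrics = self._inputs(network_factory)
        prev.variable_names = ["x", "y", "z", "w"]
        with pytest.raises(ValueError, match="missing from prevalence"):
            node_metric_table(net, prev, metrics)
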