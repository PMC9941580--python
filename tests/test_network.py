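"""Coexpression network construction, HITS hub scores, edge betweenness."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from plantkinome.expression import ExpressionMatrix
from plantkinome.network import (
    build_network,
    compare_networks,
    edge_betweenness,
    hub_scores,
)


def _matrix(rows, samples, conditions=None):
    values = pd.DataFrame(rows, columns=samples)
    meta = pd.DataFrame(
        {
            "tissue": ["leaf"] * len(samples),
            "genotype": ["GT1"] * len(samples),
            "condition": conditions or ["control"] * len(samples),
            "replicate_group": samples,
        },
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(values=values, metadata=meta)


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def eig_hub_oracle(graph: nx.Graph) -> dict[str, float]:
    """Per-component principal eigenvector of the adjacency, max-normalized."""
    scores = {n: 0.0 for n in graph.nodes}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            continue
        a = nx.to_numpy_array(graph.subgraph(nodes), nodelist=nodes)
        w, v = np.linalg.eigh(a)
        vec = np.abs(v[:, np.argmax(w)])
        vec /= vec.max()
        scores.update(dict(zip(nodes, vec)))
    return scores


def brute_force_edge_betweenness(graph: nx.Graph) -> dict[tuple, float]:
    """Enumerate every geodesic of every unordered pair explicitly."""
    out = {tuple(sorted(e)): 0.0 for e in graph.edges}
    for s, t in itertools.combinations(sorted(graph.nodes), 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for u, v in zip(path, path[1:]):
                out[tuple(sorted((u, v)))] += 1.0 / len(paths)
    return out


# --------------------------------------------------------------------------
# construction
# --------------------------------------------------------------------------

class TestBuildNetwork:
    def test_perfect_positive_correlation_gives_edge(self):
        matrix = _matrix([[1, 2, 3], [2, 4, 6], [5, 1, 2]], ["s1", "s2", "s3"])
        matrix.values.index = ["x", "y", "z"]
        net = build_network(matrix, "control", pcc_min=0.7)
        assert ("x", "y") in net.edges
        assert net.graph.edges["x", "y"]["weight"] == pytest.approx(1.0)

    def test_anticorrelation_is_not_an_edge(self):
        matrix = _matrix([[1, 2, 3], [3, 2, 1]], ["s1", "s2", "s3"])
        matrix.values.index = ["x", "y"]
        net = build_network(matrix, "control", pcc_min=0.7)
        assert net.edges == set()

    def test_fewer_than_three_samples_is_an_error(self):
        matrix = _matrix([[1, 2], [2, 1]], ["s1", "s2"])
        with pytest.raises(ValueError, match="need >= 3"):
            build_network(matrix, "control")

    def test_zero_variance_rows_dropped_and_flagged(self):
        matrix = _matrix([[5, 5, 5], [1, 2, 3]], ["s1", "s2", "s3"])
        matrix.values.index = ["flat", "x"]
        net = build_network(matrix, "control")
        assert net.dropped_zero_variance == ["flat"]
        assert "flat" in net.graph.nodes  # kept as an (isolated) node

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(0, 10, size=(8, 12))
        matrix = _matrix(values, [f"s{i}" for i in range(12)])
        matrix.values.index = [f"f{i}" for i in range(8)]
        previous = None
        for pcc in (0.3, 0.5, 0.7, 0.9):
            edges = build_network(matrix, "control", pcc_min=pcc).edges
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_stress_condition_selects_stress_samples(self):
        conditions = ["control", "stress:cold", "stress:drought", "stress:cold"]
        matrix = _matrix([[1, 5, 6, 7], [2, 5, 6, 7]],
                         ["s1", "s2", "s3", "s4"], conditions)
        matrix.values.index = ["x", "y"]
        net = build_network(matrix, "stress")
        assert net.graph.number_of_nodes() == 2


# --------------------------------------------------------------------------
# hub scores
# --------------------------------------------------------------------------

class TestHubScores:
    def test_triangle_is_uniform(self):
        g = nx.cycle_graph(["a", "b", "c"])
        assert hub_scores(g) == pytest.approx({"a": 1.0, "b": 1.0, "c": 1.0})

    def test_star_center_one_leaves_inverse_sqrt3(self):
        g = nx.star_graph(3)  # center 0, leaves 1..3
        scores = hub_scores(g)
        assert scores[0] == pytest.approx(1.0)
        for leaf in (1, 2, 3):
            assert scores[leaf] == pytest.approx(1 / np.sqrt(3), abs=1e-8)

    def test_edgeless_graph_scores_zero(self):
        g = nx.empty_graph(4)
        assert set(hub_scores(g).values()) == {0.0}

    def test_matches_dense_eigendecomposition_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 31))
            g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(0, 2**31)))
            scores = hub_scores(g)
            oracle = eig_hub_oracle(g)
            for node in g.nodes:
                assert scores[node] == pytest.approx(oracle[node], abs=1e-8)

    def test_invariant_under_relabeling(self):
        g = nx.path_graph(6)
        relabeled = nx.relabel_nodes(g, {i: f"n{5 - i}" for i in g.nodes})
        s1 = hub_scores(g)
        s2 = hub_scores(relabeled)
        for i in g.nodes:
            assert s1[i] == pytest.approx(s2[f"n{5 - i}"], abs=1e-10)

    def test_each_component_reaches_one(self):
        g = nx.Graph([("a", "b"), ("c", "d"), ("c", "e")])
        scores = hub_scores(g)
        assert max(scores[n] for n in ("a", "b")) == pytest.approx(1.0)
        assert max(scores[n] for n in ("c", "d", "e")) == pytest.approx(1.0)


# --------------------------------------------------------------------------
# edge betweenness
# --------------------------------------------------------------------------

class TestEdgeBetweenness:
    def test_path_graph_counts(self):
        g = nx.path_graph(["a", "b", "c", "d"])
        eb = edge_betweenness(g)
        assert eb[("a", "b")] == pytest.approx(3.0)
        assert eb[("b", "c")] == pytest.approx(4.0)
        assert eb[("c", "d")] == pytest.approx(3.0)

    def test_single_edge_is_one(self):
        g = nx.Graph([("a", "b")])
        assert edge_betweenness(g)[("a", "b")] == pytest.approx(1.0)

    def test_four_cycle_symmetric(self):
        g = nx.cycle_graph(4)
        values = set(round(v, 9) for v in edge_betweenness(g).values())
        assert len(values) == 1

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 31))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(0, 2**31)))
            mine = edge_betweenness(g)
            oracle = brute_force_edge_betweenness(g)
            for e in mine:
                assert mine[e] == pytest.approx(oracle[e], abs=1e-9)

    def test_tree_betweenness_sums_to_total_pairwise_distance(self):
        # on a tree each pair has one geodesic, contributing 1 to every edge
        # on it, so the edge sum equals the sum of pairwise distances
        g = nx.random_labeled_tree(12, seed=5)
        total = sum(edge_betweenness(g).values())
        expected = sum(
            d for _, lengths in nx.all_pairs_shortest_path_length(g)
            for d in lengths.values()
        ) / 2
        assert total == pytest.approx(expected)


# --------------------------------------------------------------------------
# comparison
# --------------------------------------------------------------------------

class TestCompare:
    def _net(self, edges, nodes, condition):
        from plantkinome.network import CoexpressionNetwork

        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_weighted_edges_from([(u, v, 0.9) for u, v in edges])
        return CoexpressionNetwork(graph=g, condition=condition)

    def test_identical_networks_zero_loss(self):
        nodes = ["a", "b", "c"]
        edges = [("a", "b"), ("b", "c")]
        result = compare_networks(
            self._net(edges, nodes, "control"), self._net(edges, nodes, "stress")
        )
        assert result["pct_edge_loss"] == pytest.approx(0.0)
        assert result["n_shared_edges"] == 2
        assert result["n_unique_control"] == result["n_unique_stress"] == 0

    def test_disjoint_edge_sets_share_nothing(self):
        nodes = ["a", "b", "c", "d"]
        result = compare_networks(
            self._net([("a", "b")], nodes, "control"),
            self._net([("c", "d")], nodes, "stress"),
        )
        assert result["n_shared_edges"] == 0
        assert result["n_unique_control"] == 1
        assert result["n_unique_stress"] == 1

    def test_mismatched_node_universe_rejected(self):
        with pytest.raises(ValueError, match="node universe"):
            compare_networks(
                self._net([], ["a", "b"], "control"),
                self._net([], ["a", "c"], "stress"),
            )

    def test_edge_loss_reproduces_published_scale(self):
        # 1,162 control vs 704 stress edges -> ~39.4% fewer, i.e. ~40%
        loss = 100.0 * (1.0 - 704 / 1162)
        assert loss == pytest.approx(39.4, abs=0.05)
        assert round(loss, -1) == 40.0
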