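import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lexnet.graph_core import (
    degree_preserving_shuffle,
    edge_permutation_null,
    giant_component,
    hop_distance_matrix,
    mean_distance,
    shortest_path_distance,
    spanning_connector,
)


def small_graphs(max_nodes: int = 8):
    """Hypothesis strategy: random simple graphs on a few integer nodes."""

    @st.composite
    def _graphs(draw):
        n = draw(st.integers(2, max_nodes))
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        mask = draw(st.lists(st.booleans(), min_size=len(pairs), max_size=len(pairs)))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(p for p, keep in zip(pairs, mask) if keep)
        return g

    return _graphs()


class TestShortestPathDistance:
    def test_chain_distance_three(self, intend_chain_net):
        assert shortest_path_distance(intend_chain_net, "intend", "invest") == 3

    def test_identity_is_zero(self, path_graph):
        assert shortest_path_distance(path_graph, "b", "b") == 0

    def test_disconnected_pair_is_infinite(self, path_graph):
        path_graph.add_node("e")
        assert shortest_path_distance(path_graph, "a", "e") == math.inf

    def test_unknown_node_raises_with_name(self, path_graph):
        with pytest.raises(KeyError, match="zzz"):
            shortest_path_distance(path_graph, "a", "zzz")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(small_graphs())
    def test_triangle_inequality(self, g):
        nodes = list(g.nodes())
        for a in nodes[:3]:
            for b in nodes[:3]:
                for c in nodes[:3]:
                    dab = shortest_path_distance(g, a, b)
                    dbc = shortest_path_distance(g, b, c)
                    dac = shortest_path_distance(g, a, c)
                    assert dac <= dab + dbc


class TestGiantComponent:
    def test_connected_graph_unchanged(self):
        tri = nx.cycle_graph(3)
        assert set(giant_component(tri).edges()) == set(tri.edges())

    def test_largest_component_wins(self):
        g = nx.cycle_graph(3)
        g.add_edge("d", "e")
        gc = giant_component(g)
        assert set(gc.nodes()) == {0, 1, 2}

    def test_tie_broken_lexicographically(self):
        g = nx.Graph()
        g.add_nodes_from(["b", "a"])
        gc = giant_component(g)
        assert set(gc.nodes()) == {"a"}

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            giant_component(nx.Graph())


class TestDegreePreservingShuffle:
    def test_triangle_is_fixed_point(self):
        tri = nx.cycle_graph(3)
        out = degree_preserving_shuffle(tri, seed=5)
        assert set(out.edges()) == set(tri.edges())

    def test_star_is_fixed_point(self):
        star = nx.star_graph(3)
        out = degree_preserving_shuffle(star, seed=7)
        assert set(map(frozenset, out.edges())) == set(map(frozenset, star.edges()))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(small_graphs(), st.integers(0, 2**16))
    def test_degree_sequence_preserved(self, g, seed):
        out = degree_preserving_shuffle(g, seed=seed)
        assert sorted(d for _, d in out.degree()) == sorted(d for _, d in g.degree())
        assert set(out.nodes()) == set(g.nodes())

    def test_same_seed_same_output(self):
        g = nx.gnm_random_graph(20, 40, seed=3)
        a = degree_preserving_shuffle(g, seed=9)
        b = degree_preserving_shuffle(g, seed=9)
        assert set(a.edges()) == set(b.edges())


class TestEdgePermutationNull:
    def test_zero_edges(self):
        g = nx.empty_graph(4)
        assert edge_permutation_null(g, seed=1).number_of_edges() == 0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(small_graphs(), st.integers(0, 2**16))
    def test_counts_preserved(self, g, seed):
        out = edge_permutation_null(g, seed=seed)
        assert out.number_of_edges() == g.number_of_edges()
        assert set(out.nodes()) == set(g.nodes())

    def test_complete_graph_is_fixed_point(self):
        k4 = nx.complete_graph(4)
        out = edge_permutation_null(k4, seed=0)
        assert set(map(frozenset, out.edges())) == set(map(frozenset, k4.edges()))


class TestSpanningConnector:
    def test_cycle_yields_tree(self):
        nodes = list(range(4))
        cycle = [(0, 1), (1, 2), (2, 3), (3, 0)]
        tree = spanning_connector(nodes, cycle, seed=2)
        assert len(tree) == 3
        g = nx.Graph(tree)
        assert nx.is_tree(g) and set(g.nodes()) == set(nodes)

    def test_tree_returned_unchanged(self):
        edges = {(0, 1), (1, 2), (1, 3)}
        assert spanning_connector(range(4), edges) == edges

    def test_per_component_edge_counts(self):
        edges = [(0, 1), (1, 2), (0, 2), (3, 4)]
        tree = spanning_connector(range(5), edges)
        assert len(tree) == 3  # sizes 3 and 2 -> 2 + 1 edges

    def test_isolated_nodes_contribute_nothing(self):
        assert spanning_connector(range(3), []) == set()

    def test_acyclic_and_connects_components(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            g = nx.gnm_random_graph(10, int(rng.integers(0, 20)), seed=int(rng.integers(2**31)))
            tree = spanning_connector(g.nodes(), g.edges())
            t = nx.Graph()
            t.add_nodes_from(g.nodes())
            t.add_edges_from(tree)
            assert nx.number_connected_components(t) == nx.number_connected_components(g)
            assert len(tree) == g.number_of_nodes() - nx.number_connected_components(g)

    def test_prefers_heavier_candidates(self):
        cands = [(0, 1, 5.0), (1, 2, 5.0), (0, 2, 1.0)]
        assert spanning_connector(range(3), cands) == {(0, 1), (1, 2)}


class TestMeanDistance:
    def test_triangle(self):
        assert mean_distance(nx.cycle_graph(3)).mean_distance == 1.0

    def test_path_three_nodes(self):
        g = nx.path_graph(3)
        assert mean_distance(g).mean_distance == pytest.approx(4 / 3)

    def test_isolate_excluded(self):
        g = nx.path_graph(3)
        g.add_node("d")
        s = mean_distance(g, policy="exclude")
        assert s.mean_distance == pytest.approx(4 / 3)
        assert s.n_pairs_used == 3

    def test_no_finite_pair_raises(self):
        g = nx.empty_graph(3)
        with pytest.raises(ValueError):
            mean_distance(g)

    def test_union_of_layers_never_longer(self):
        # brute-force check of the multiplex shortening law at summary level
        rng = np.random.default_rng(11)
        for _ in range(20):
            s1, s2 = (int(x) for x in rng.integers(0, 2**31, 2))
            g1 = nx.gnm_random_graph(8, 10, seed=s1)
            g2 = nx.gnm_random_graph(8, 10, seed=s2)
            union = nx.compose(g1, g2)
            d1 = hop_distance_matrix(g1, sorted(g1.nodes(), key=str))
            du = hop_distance_matrix(union, sorted(union.nodes(), key=str))
            both = np.isfinite(d1)
            assert np.all(du[both] <= d1[both])
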