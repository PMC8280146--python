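import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lexnet.graph_core import canonical_edge
from lexnet.semantic import (
    AssociationTable,
    build_semantic_network,
    filter_top_fraction,
    link_strength,
    sort_and_window,
    strength_groups,
)


def oracle_link_strength(counts, ci, cj, threshold):
    """Independent naive double loop over all response pairs."""
    total = 0
    for r1, n1 in counts[ci].items():
        for r2, n2 in counts[cj].items():
            if r1 == r2 and min(n1, n2) >= threshold:
                total += min(n1, n2)
    return total


@st.composite
def association_tables(draw):
    n_cues = draw(st.integers(2, 10))
    responses = [f"r{i}" for i in range(draw(st.integers(1, 20)))]
    counts = {}
    for c in range(n_cues):
        chosen = draw(
            st.lists(st.sampled_from(responses), min_size=1, max_size=len(responses), unique=True)
        )
        counts[f"c{c}"] = {r: draw(st.integers(1, 9)) for r in chosen}
    return AssociationTable.from_counts(counts)


class TestLinkStrength:
    def test_min_filter_drops_single_participant_overlap(self):
        t = AssociationTable.from_counts({"A": {"x": 3, "y": 1}, "B": {"x": 2, "y": 5}})
        assert link_strength(t, "A", "B") == 2  # min(3,2)=2 kept; min(1,5)=1 filtered

    def test_no_shared_response(self):
        t = AssociationTable.from_counts({"A": {"x": 3}, "B": {"y": 2}})
        assert link_strength(t, "A", "B") == 0

    def test_single_shared_term(self):
        t = AssociationTable.from_counts({"A": {"x": 4}, "B": {"x": 4}})
        assert link_strength(t, "A", "B") == 4

    def test_unknown_cue_raises(self):
        t = AssociationTable.from_counts({"A": {"x": 2}, "B": {"x": 2}})
        with pytest.raises(KeyError):
            link_strength(t, "A", "zzz")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(association_tables(), st.integers(1, 3))
    def test_matches_oracle_and_is_symmetric(self, table, threshold):
        cues = sorted(table.cues)
        ci, cj = cues[0], cues[1]
        got = link_strength(table, ci, cj, threshold)
        assert got == oracle_link_strength(table.counts, ci, cj, threshold)
        assert got == link_strength(table, cj, ci, threshold)
        # strength can never exceed either cue's total participant count
        assert got <= min(sum(table.counts[ci].values()), sum(table.counts[cj].values()))


class TestBuildSemanticNetwork:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(association_tables())
    def test_every_edge_matches_double_loop_oracle(self, table):
        net = build_semantic_network(table)
        cues = sorted(table.cues)
        for i, ci in enumerate(cues):
            for cj in cues[i + 1 :]:
                expected = oracle_link_strength(table.counts, ci, cj, 2)
                if expected > 0:
                    assert net[ci][cj]["weight"] == expected
                else:
                    assert not net.has_edge(ci, cj)

    def test_unique_responses_give_empty_network(self):
        t = AssociationTable.from_counts({"A": {"ra": 5}, "B": {"rb": 5}})
        assert build_semantic_network(t).number_of_edges() == 0

    def test_threshold_one_dominates_threshold_two(self):
        t = AssociationTable.from_counts(
            {"A": {"x": 3, "y": 1}, "B": {"x": 1, "y": 1}, "C": {"x": 2, "y": 2}}
        )
        loose = build_semantic_network(t, min_shared_participants=1)
        strict = build_semantic_network(t, min_shared_participants=2)
        for a, b, d in strict.edges(data=True):
            assert loose[a][b]["weight"] >= d["weight"]
        assert set(strict.edges()) <= set(loose.edges())

    def test_responses_are_not_nodes(self):
        t = AssociationTable.from_counts({"A": {"shared": 3}, "B": {"shared": 3}})
        net = build_semantic_network(t)
        assert set(net.nodes()) == {"A", "B"}


class TestFilterTopFraction:
    def _weighted(self, weights):
        g = nx.Graph()
        for i, w in enumerate(weights):
            g.add_edge(f"a{i}", f"b{i}", weight=w)
        return g

    def test_one_percent_of_200(self):
        g = self._weighted(range(1, 201))
        out = filter_top_fraction(g, 0.01)
        assert out.number_of_edges() == 2
        assert out.has_edge("a199", "b199") and out.has_edge("a198", "b198")

    def test_full_fraction_keeps_all_unweighted(self):
        g = self._weighted([3, 1, 2])
        out = filter_top_fraction(g, 1.0)
        assert out.number_of_edges() == 3
        assert all("weight" not in d for *_, d in out.edges(data=True))

    def test_boundary_tie_resolved_lexicographically(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=5)
        g.add_edge("c", "d", weight=4)
        g.add_edge("e", "f", weight=4)
        g.add_edge("g", "h", weight=1)
        out = filter_top_fraction(g, 0.5)
        assert out.number_of_edges() == 2
        assert out.has_edge("a", "b")
        # of the two weight-4 edges the lexicographically later one survives
        assert out.has_edge("e", "f") and not out.has_edge("c", "d")

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(0)
        g = self._weighted(rng.integers(1, 50, size=40))
        e1 = set(filter_top_fraction(g, 0.2).edges())
        e2 = set(filter_top_fraction(g, 0.6).edges())
        assert {canonical_edge(*e) for e in e1} <= {canonical_edge(*e) for e in e2}

    def test_bad_fraction_raises(self):
        g = self._weighted([1])
        for f in (0, -0.1, 1.5):
            with pytest.raises(ValueError):
                filter_top_fraction(g, f)


class TestStrengthGroups:
    def _weighted(self, weights):
        g = nx.Graph()
        for i, w in enumerate(weights):
            g.add_edge(f"a{i}", f"b{i}", weight=w)
        return g

    def test_terciles_of_nine(self):
        g = self._weighted(range(9))
        weak, medium, strong = strength_groups(g, "terciles")
        assert len(weak) == len(medium) == len(strong) == 3

    def test_terciles_of_ten_sizes(self):
        g = self._weighted(range(10))
        sizes = [len(grp) for grp in strength_groups(g, "terciles")]
        assert sorted(sizes) == [3, 3, 4] and sum(sizes) == 10

    def test_separated_groups_of_ten(self):
        g = self._weighted(range(10))
        weak, medium, strong = strength_groups(g, "separated")
        assert len(weak) == len(medium) == len(strong) == 2
        used = set(weak) | set(medium) | set(strong)
        assert len(used) == 6  # 4 gap links excluded

    def test_groups_ordered_by_strength(self):
        rng = np.random.default_rng(1)
        g = self._weighted(rng.integers(1, 100, size=30))
        weights = {canonical_edge(a, b): d["weight"] for a, b, d in g.edges(data=True)}
        for mode in ("terciles", "separated"):
            weak, medium, strong = strength_groups(g, mode)
            assert max(weights[e] for e in weak) <= min(weights[e] for e in medium)
            assert max(weights[e] for e in medium) <= min(weights[e] for e in strong)

    def test_too_few_edges_raise(self):
        with pytest.raises(ValueError):
            strength_groups(self._weighted([1, 2]), "terciles")


class TestSortAndWindow:
    def test_window_sizes(self):
        g = nx.Graph()
        for i in range(250):
            g.add_edge(f"a{i}", f"b{i}", weight=i)
        windows = sort_and_window(g, 100)
        assert [len(w) for w in windows] == [100, 100, 50]

    def test_windows_partition_and_ascend(self):
        rng = np.random.default_rng(2)
        g = nx.Graph()
        for i in range(57):
            g.add_edge(f"a{i}", f"b{i}", weight=int(rng.integers(1, 30)))
        windows = sort_and_window(g, 10)
        weights = {canonical_edge(a, b): d["weight"] for a, b, d in g.edges(data=True)}
        all_links = [e for w in windows for e in w.links]
        assert len(all_links) == len(set(all_links)) == g.number_of_edges()
        for w1, w2 in zip(windows, windows[1:]):
            assert max(weights[e] for e in w1.links) <= min(weights[e] for e in w2.links)
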