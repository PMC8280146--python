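"""Semantic layer estimated from free-association data.

The strength of the link between two cue words is the sum, over associative
responses generated to both cues, of the smaller participant count — the
min-participant-sum similarity. Shared responses backed by a single
participant on either side are noise-filtered out by default (the shared
count must be at least ``min_shared_participants`` on the min).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

import networkx as nx

from .graph_core import Edge, Word, canonical_edge

__all__ = [
    "AssociationTable",
    "StrengthWindow",
    "link_strength",
    "build_semantic_network",
    "filter_top_fraction",
    "strength_groups",
    "sort_and_window",
]


@dataclass
class AssociationTable:
    """Per-cue response counts: how many participants gave each response.

    ``records`` holds (cue, response, participant_count) triples with unique
    (cue, response) pairs; ``counts`` indexes them as cue -> response -> count.
    """

    records: list[tuple[Word, str, int]]
    counts: dict[Word, dict[str, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = {}
        seen: set[tuple[Word, str]] = set()
        for cue, response, count in self.records:
            if count < 1:
                raise ValueError(f"participant_count must be >= 1, got {count} for ({cue!r}, {response!r})")
            key = (cue, response)
            if key in seen:
                raise ValueError(f"duplicate (cue, response) pair {key!r}")
            seen.add(key)
            self.counts.setdefault(cue, {})[response] = count

    @property
    def cues(self) -> set[Word]:
        return set(self.counts)

    @staticmethod
    def from_counts(counts: dict[Word, dict[str, int]]) -> "AssociationTable":
        records = [(c, r, n) for c, by_resp in counts.items() for r, n in sorted(by_resp.items())]
        return AssociationTable(records)

    def normalized(self, normalize: Callable[[str], str]) -> "AssociationTable":
        """Apply a response-normalization hook (e.g. plural merging) before use.

        Counts of responses mapped to the same normal form are summed.
        """
        merged: dict[Word, dict[str, int]] = {}
        for cue, by_resp in self.counts.items():
            out = merged.setdefault(cue, defaultdict(int))
            for response, count in by_resp.items():
                out[normalize(response)] += count
        return AssociationTable.from_counts({c: dict(v) for c, v in merged.items()})


@dataclass(frozen=True)
class StrengthWindow:
    """Contiguous block of links from the strength-sorted (ascending) order."""

    rank_range: tuple[int, int]  # half-open [start, stop)
    links: tuple[Edge, ...]

    def __len__(self) -> int:
        return len(self.links)


def link_strength(
    table: AssociationTable,
    ci: Word,
    cj: Word,
    min_shared_participants: int = 2,
) -> int:
    """Min-participant-sum similarity between two cues.

    Sums ``min(count_i(k), count_j(k))`` over responses k given to both
    cues, keeping only terms whose min is at least
    ``min_shared_participants`` (default 2: an overlap attributable to a
    single participant is treated as noise).
    """
    for c in (ci, cj):
        if c not in table.counts:
            raise KeyError(f"unknown cue {c!r}")
    if ci == cj:
        raise ValueError("link strength is defined for distinct cues")
    a, b = table.counts[ci], table.counts[cj]
    if len(b) < len(a):
        a, b = b, a
    total = 0
    for response, ca in a.items():
        cb = b.get(response)
        if cb is None:
            continue
        m = min(ca, cb)
        if m >= min_shared_participants:
            total += m
    return total


def build_semantic_network(
    table: AssociationTable,
    min_shared_participants: int = 2,
) -> nx.Graph:
    """Weighted undirected network over the cue words.

    An edge links every cue pair with positive :func:`link_strength`; the
    weight is that strength. Responses that are not themselves cues
    contribute to weights but are not nodes. Uses an inverted
    response -> cues index so only cue pairs actually sharing a response are
    visited.
    """
    cues = sorted(table.cues, key=str)
    if len(cues) < 2:
        raise ValueError("at least two cues are required")
    net = nx.Graph()
    net.add_nodes_from(cues)
    by_response: dict[str, list[tuple[Word, int]]] = defaultdict(list)
    for cue in cues:
        for response, count in table.counts[cue].items():
            if count >= min_shared_participants:
                by_response[response].append((cue, count))
    weights: dict[Edge, int] = defaultdict(int)
    for sharers in by_response.values():
        if len(sharers) < 2:
            continue
        for i, (ci, ni) in enumerate(sharers):
            for cj, nj in sharers[i + 1 :]:
                weights[canonical_edge(ci, cj)] += min(ni, nj)
    for (a, b), w in weights.items():
        net.add_edge(a, b, weight=w)
    return net


def _sorted_edges_ascending(net: nx.Graph) -> list[tuple[Edge, float]]:
    """Edges sorted ascending by weight, ties by lexicographic edge order."""
    edges = [(canonical_edge(a, b), float(d.get("weight", 1.0))) for a, b, d in net.edges(data=True)]
    edges.sort(key=lambda t: (t[1], str(t[0])))
    return edges


def filter_top_fraction(net: nx.Graph, fraction: float) -> nx.Graph:
    """Keep the strongest ``ceil(fraction * |edges|)`` links, unweighted.

    Boundary ties are broken lexicographically so the result is
    deterministic. Nodes are preserved (some may become isolates).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if net.number_of_edges() < 1:
        raise ValueError("network has no edges to filter")
    edges = _sorted_edges_ascending(net)
    k = -(-net.number_of_edges() * fraction // 1)  # ceil
    keep = [e for e, _ in edges[-int(k):]]
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(keep)
    return out


def strength_groups(
    net: nx.Graph,
    mode: Literal["terciles", "separated"] = "terciles",
) -> tuple[list[Edge], list[Edge], list[Edge]]:
    """Split links into (weak, medium, strong) groups by ascending strength.

    ``terciles``: three contiguous groups whose sizes differ by at most one.
    ``separated``: three equal groups of size ``|edges| // 5`` taken from the
    bottom, middle and top of the sorted order, with the remaining links
    split evenly into two gaps — a concrete reading of "maximally separable"
    strength groups.
    """
    edges = [e for e, _ in _sorted_edges_ascending(net)]
    m = len(edges)
    if m < 3:
        raise ValueError("need at least 3 links to form strength groups")
    if mode == "terciles":
        base, extra = divmod(m, 3)
        sizes = [base + (1 if i < extra else 0) for i in range(3)]
        weak = edges[: sizes[0]]
        medium = edges[sizes[0] : sizes[0] + sizes[1]]
        strong = edges[sizes[0] + sizes[1] :]
        return weak, medium, strong
    if mode == "separated":
        g = m // 5
        if g < 1:
            raise ValueError("need at least 5 links for separated groups")
        gap_total = m - 3 * g
        gap1 = gap_total // 2
        weak = edges[:g]
        medium = edges[g + gap1 : g + gap1 + g]
        strong = edges[m - g :]
        return weak, medium, strong
    raise ValueError(f"unknown mode {mode!r}")


def sort_and_window(net: nx.Graph, window_size: int) -> list[StrengthWindow]:
    """Partition links into ascending-strength windows of ``window_size``.

    The last window may be smaller. Ties in strength are ordered
    lexicographically so the partition is deterministic.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    edges = [e for e, _ in _sorted_edges_ascending(net)]
    windows = []
    for start in range(0, len(edges), window_size):
        stop = min(start + window_size, len(edges))
        windows.append(StrengthWindow(rank_range=(start, stop), links=tuple(edges[start:stop])))
    return windows
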