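"""Graph primitives shared by every analysis stage.

Lexical networks are plain undirected :class:`networkx.Graph` objects whose
nodes are words. Semantic layers carry a positive ``weight`` attribute on
every edge (association strength); phonological layers are unweighted. All
distances are hop counts — weighted layers are treated as unweighted when
paths are measured, matching the convention of converting the semantic layer
to unweighted before any distance comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Literal

import networkx as nx
import numpy as np
from networkx.utils import UnionFind
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

Word = Hashable
Edge = tuple[Word, Word]

DisconnectedPolicy = Literal["exclude", "giant_component_only"]

__all__ = [
    "DistanceSummary",
    "canonical_edge",
    "shortest_path_distance",
    "giant_component",
    "degree_preserving_shuffle",
    "edge_permutation_null",
    "spanning_connector",
    "mean_distance",
    "hop_distance_matrix",
    "spawn_seeds",
]


@dataclass(frozen=True)
class DistanceSummary:
    """Average hop distance of a network over admitted node pairs."""

    network_label: str
    mean_distance: float
    n_pairs_used: int
    disconnected_policy: DisconnectedPolicy


def canonical_edge(a: Word, b: Word) -> Edge:
    """Unordered pair in canonical (sorted) order."""
    return (a, b) if str(a) <= str(b) else (b, a)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent per-iteration seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def shortest_path_distance(net: nx.Graph, a: Word, b: Word) -> float:
    """Hop count of a shortest path between ``a`` and ``b``.

    Returns ``math.inf`` when the two words lie in different components and
    0 when ``a == b``.
    """
    for w in (a, b):
        if w not in net:
            raise KeyError(f"word {w!r} is not a node of the network")
    if a == b:
        return 0
    try:
        return nx.shortest_path_length(net, a, b)
    except nx.NetworkXNoPath:
        return float("inf")


def giant_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member node, so
    the result is deterministic.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot take the giant component of an empty network")
    components = [sorted(c, key=str) for c in nx.connected_components(net)]
    best = sorted(components, key=lambda c: (-len(c), str(c[0])))[0]
    return net.subgraph(best).copy()


def degree_preserving_shuffle(net: nx.Graph, n_swaps: int | None = None, seed: int = 0) -> nx.Graph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Each proposal picks two distinct edges (a, b) and (c, d) and rewires to
    (a, d), (c, b); proposals creating self-loops or duplicate edges are
    rejected. A graph admitting no valid swap (triangle, star) is returned
    unchanged. ``n_swaps`` defaults to ``10 * |edges|`` (mixing heuristic).
    """
    if n_swaps is None:
        n_swaps = 10 * net.number_of_edges()
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    rng = np.random.default_rng(seed)
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(net.edges())  # weights dropped: the null is unweighted
    edges = [tuple(e) for e in out.edges()]
    m = len(edges)
    if m < 2:
        return out
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if out.has_edge(a, d) or out.has_edge(c, b):
            continue
        out.remove_edge(a, b)
        out.remove_edge(c, d)
        out.add_edge(a, d)
        out.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return out


def edge_permutation_null(net: nx.Graph, seed: int = 0) -> nx.Graph:
    """Random graph on the same node set with the same edge count.

    Endpoints are drawn uniformly (no self-loops, no duplicates); the degree
    sequence is *not* preserved. This is the "permute the links, keep node
    and edge counts" null.
    """
    nodes = sorted(net.nodes(), key=str)
    n = len(nodes)
    m = net.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ValueError("edge count exceeds the number of possible pairs")
    rng = np.random.default_rng(seed)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    while out.number_of_edges() < m:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        a, b = nodes[i], nodes[j]
        if not out.has_edge(a, b):
            out.add_edge(a, b)
    return out


def spanning_connector(
    nodes: Iterable[Word],
    candidate_edges: Iterable[Edge | tuple[Word, Word, float]],
    seed: int | None = None,
) -> set[Edge]:
    """Spanning forest of the candidate graph over ``nodes``.

    For each connected component of (nodes, candidate_edges) a spanning tree
    is returned (``|component| - 1`` edges). Candidates may carry a third
    element, a weight; heavier candidates are preferred (Kruskal on
    descending weight), so when the candidates are semantic links the tree
    keeps the strongest available ones. Ties are broken lexicographically, or
    by a seeded shuffle when ``seed`` is given. Isolated nodes contribute no
    edges.
    """
    node_list = sorted(set(nodes), key=str)
    weighted: list[tuple[float, Edge]] = []
    for cand in candidate_edges:
        if len(cand) == 3:
            a, b, w = cand  # type: ignore[misc]
        else:
            a, b = cand  # type: ignore[misc]
            w = 1.0
        if a == b:
            continue
        weighted.append((float(w), canonical_edge(a, b)))
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(weighted)
        weighted.sort(key=lambda t: -t[0])  # stable: seeded order within ties
    else:
        weighted.sort(key=lambda t: (-t[0], str(t[1])))
    uf = UnionFind(node_list)
    tree: set[Edge] = set()
    for _, (a, b) in weighted:
        if a not in uf.parents or b not in uf.parents:
            continue
        if uf[a] != uf[b]:
            uf.union(a, b)
            tree.add((a, b))
    return tree


def hop_distance_matrix(net: nx.Graph, nodelist: list[Word] | None = None) -> np.ndarray:
    """All-pairs hop distances as a dense matrix (inf for disconnected pairs)."""
    if nodelist is None:
        nodelist = sorted(net.nodes(), key=str)
    if len(nodelist) == 0:
        return np.zeros((0, 0))
    adj = nx.to_scipy_sparse_array(net, nodelist=nodelist, weight=None, format="csr")
    return _csgraph_shortest_path(adj, method="D", unweighted=True, directed=False)


def mean_distance(
    net: nx.Graph,
    policy: DisconnectedPolicy = "exclude",
    label: str = "",
) -> DistanceSummary:
    """Average hop distance over all unordered node pairs admitted by ``policy``.

    ``exclude`` drops pairs in different components; ``giant_component_only``
    restricts the network to its giant component first.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot average distances of an empty network")
    g = giant_component(net) if policy == "giant_component_only" else net
    dist = hop_distance_matrix(g)
    iu = np.triu_indices(dist.shape[0], k=1)
    vals = dist[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("no finite node pair under the given policy")
    return DistanceSummary(
        network_label=label,
        mean_distance=float(finite.mean()),
        n_pairs_used=int(finite.size),
        disconnected_policy=policy,
    )
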