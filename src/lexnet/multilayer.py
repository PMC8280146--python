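"""Multilayer architecture: merged layers, degree-matched comparisons,
community structure, and the semantic-fraction sweep.

The central comparison holds node set, edge count and mean degree fixed and
asks which wiring — semantic only, phonological only, a semantic +
phonological multilayer, or fully random — yields the shortest average hop
distance, and how the answer moves as weaker semantic links are admitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .graph_core import (
    DistanceSummary,
    Edge,
    Word,
    canonical_edge,
    edge_permutation_null,
    giant_component,
    mean_distance,
    spanning_connector,
    spawn_seeds,
)

__all__ = [
    "MatchedQuadruple",
    "CommunityPartition",
    "merge_layers",
    "build_matched_quadruple",
    "distance_sweep",
    "detect_communities",
    "interlink_fraction",
    "fraction_sweep",
]

Origin = Literal["semantic", "phonological", "both"]


@dataclass(frozen=True)
class CommunityPartition:
    """Node -> community assignment from modularity maximization."""

    assignment: dict[Word, int]
    gamma: float


@dataclass(frozen=True)
class MatchedQuadruple:
    """Four networks on one node set with matched edge counts.

    ``semantic``: spanning connector plus windowed semantic links;
    ``phonological``: the phonological layer on the shared nodes;
    ``multilayer``: half/half refilled merge; ``random``: edge-permutation
    null of matching size.
    """

    semantic: nx.Graph
    phonological: nx.Graph
    multilayer: nx.Graph
    random: nx.Graph
    window_percentile: float
    target_mean_degree: float


def merge_layers(
    sem: nx.Graph,
    phono: nx.Graph,
    nodes: Literal["shared", "union"] = "shared",
) -> nx.Graph:
    """Union multiplex of the two layers with edges tagged by origin.

    Each edge carries an ``origin`` attribute: ``semantic``,
    ``phonological``, or ``both`` for overlapping links. With
    ``nodes="shared"`` only words present in both layers are kept (the
    multilayer of the common vocabulary); ``"union"`` keeps everything.
    """
    if nodes == "shared":
        node_set = set(sem.nodes()) & set(phono.nodes())
        if not node_set:
            raise ValueError("the two layers share no nodes")
    else:
        node_set = set(sem.nodes()) | set(phono.nodes())
    out = nx.Graph()
    out.add_nodes_from(node_set)
    for a, b in sem.edges():
        if a in node_set and b in node_set:
            out.add_edge(a, b, origin="semantic")
    for a, b in phono.edges():
        if a in node_set and b in node_set:
            if out.has_edge(a, b):
                out[a][b]["origin"] = "both"
            else:
                out.add_edge(a, b, origin="phonological")
    return out


def _weighted_edges_desc(net: nx.Graph, nodes: set[Word]) -> list[tuple[Word, Word, float]]:
    """Edges among ``nodes`` sorted by descending weight, ties lexicographic."""
    edges = [
        (*canonical_edge(a, b), float(d.get("weight", 1.0)))
        for a, b, d in net.edges(data=True)
        if a in nodes and b in nodes
    ]
    edges.sort(key=lambda t: (-t[2], str((t[0], t[1]))))
    return edges


def build_matched_quadruple(
    sem: nx.Graph,
    phono: nx.Graph,
    window_percentile: float = 1.0,
    seed: int = 0,
) -> MatchedQuadruple:
    """Degree-matched semantic / phonological / multilayer / random networks.

    Node set: the words shared by the giant components of both layers. The
    phonological network (restricted to those words) fixes the target edge
    count and hence the mean degree. The semantic network keeps a spanning
    connector built from the strongest available links, then adds links from
    the strength window downward until the edge counts match.
    ``window_percentile`` = 1.0 starts at the very strongest link; 0.99
    skips the top 1% and starts from the 99th percentile of strength. The
    multilayer merges the windowed semantic links with the phonological
    ones, prunes to a spanning connector, then refills alternately with the
    strongest remaining semantic link and a seeded-random phonological link
    until the target count is reached. The random network is an
    edge-permutation null of matching size.
    """
    if not (0 < window_percentile <= 1):
        raise ValueError("window_percentile must be in (0, 1]")
    sem_g = giant_component(sem)
    phono_g = giant_component(phono)
    shared = set(sem_g.nodes()) & set(phono_g.nodes())
    if len(shared) < 3:
        raise ValueError("layers share fewer than 3 giant-component nodes")
    phono_m = nx.Graph()
    phono_m.add_nodes_from(sorted(shared, key=str))
    phono_m.add_edges_from(
        (a, b) for a, b in phono_g.edges() if a in shared and b in shared
    )
    e_target = phono_m.number_of_edges()
    sem_edges = _weighted_edges_desc(sem_g, shared)
    start = int(round((1.0 - window_percentile) * len(sem_edges)))
    window = sem_edges[start:]

    seeds = spawn_seeds(seed, 3)

    # semantic network: strongest-preferring spanning connector + window fill
    s_net = nx.Graph()
    s_net.add_nodes_from(sorted(shared, key=str))
    s_net.add_edges_from(spanning_connector(shared, sem_edges))
    for a, b, _w in window:
        if s_net.number_of_edges() >= e_target:
            break
        if not s_net.has_edge(a, b):
            s_net.add_edge(a, b)
    if s_net.number_of_edges() < e_target:
        raise ValueError(
            f"window at percentile {window_percentile} cannot reach {e_target} links "
            f"(achievable: {s_net.number_of_edges()})"
        )

    # multilayer: merge windowed semantic + phonological, prune, refill half/half
    window_edges = {canonical_edge(a, b) for a, b, _ in window}
    phono_edges = {canonical_edge(a, b) for a, b in phono_m.edges()}
    merged_cands = [(a, b, w) for a, b, w in window] + [
        (a, b, 1.0) for a, b in sorted(phono_edges - window_edges, key=str)
    ]
    m_net = nx.Graph()
    m_net.add_nodes_from(sorted(shared, key=str))
    m_net.add_edges_from(spanning_connector(shared, merged_cands))
    rng = np.random.default_rng(seeds[0])
    sem_queue = [(a, b) for a, b, _ in window if not m_net.has_edge(a, b)]
    phono_queue = sorted(e for e in phono_edges if not m_net.has_edge(*e))
    rng.shuffle(phono_queue)
    turn = 0  # alternate: even = semantic, odd = phonological
    si = pi = 0
    while m_net.number_of_edges() < e_target and (si < len(sem_queue) or pi < len(phono_queue)):
        if (turn % 2 == 0 and si < len(sem_queue)) or pi >= len(phono_queue):
            a, b = sem_queue[si]
            si += 1
        else:
            a, b = phono_queue[pi]
            pi += 1
        turn += 1
        if not m_net.has_edge(a, b):
            m_net.add_edge(a, b)
    if m_net.number_of_edges() < e_target:
        raise ValueError(
            f"multilayer refill cannot reach {e_target} links "
            f"(achievable: {m_net.number_of_edges()})"
        )

    r_net = edge_permutation_null(phono_m, seed=seeds[1])
    target_degree = 2 * e_target / len(shared)
    return MatchedQuadruple(
        semantic=s_net,
        phonological=phono_m,
        multilayer=m_net,
        random=r_net,
        window_percentile=window_percentile,
        target_mean_degree=target_degree,
    )


def distance_sweep(
    sem: nx.Graph,
    phono: nx.Graph,
    percentile_resolution: float = 0.005,
    seed: int = 0,
    min_percentile: float = 0.0,
) -> list[dict[str, object]]:
    """Mean distances of the matched quadruple across strength windows.

    Windows start at the strongest links (percentile 1.0) and step down by
    ``percentile_resolution`` until links run out (or ``min_percentile``).
    The phonological value is constant across rows by construction. Each row
    is ``{"window_percentile", "semantic", "phonological", "multilayer",
    "random"}`` with mean hop distances (disconnected pairs excluded).
    """
    if not (0 < percentile_resolution < 1):
        raise ValueError("percentile_resolution must be in (0, 1)")
    rows: list[dict[str, object]] = []
    seeds = spawn_seeds(seed, int(np.ceil(1 / percentile_resolution)) + 1)
    p = 1.0
    step = 0
    phono_distance: float | None = None
    while p > min_percentile + 1e-12:
        try:
            quad = build_matched_quadruple(sem, phono, window_percentile=p, seed=seeds[step])
        except ValueError:
            break
        if phono_distance is None:
            phono_distance = mean_distance(quad.phonological, "exclude", "P").mean_distance
        rows.append(
            {
                "window_percentile": round(p, 10),
                "semantic": mean_distance(quad.semantic, "exclude", "S").mean_distance,
                "phonological": phono_distance,
                "multilayer": mean_distance(quad.multilayer, "exclude", "M").mean_distance,
                "random": mean_distance(quad.random, "exclude", "R").mean_distance,
            }
        )
        p -= percentile_resolution
        step += 1
    return rows


def detect_communities(
    net: nx.Graph,
    gamma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 5,
) -> CommunityPartition:
    """Louvain modularity communities at resolution ``gamma``.

    Louvain is order-dependent, so the procedure is restarted
    ``n_restarts`` times with derived seeds and the highest-modularity
    partition is kept.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot detect communities of an empty network")
    best: list[set[Word]] | None = None
    best_q = -np.inf
    for s in spawn_seeds(seed, n_restarts):
        comms = nx.community.louvain_communities(net, resolution=gamma, seed=s)
        q = nx.community.modularity(net, comms, resolution=gamma)
        if q > best_q:
            best_q = q
            best = comms
    assignment = {node: cid for cid, comm in enumerate(best) for node in comm}
    return CommunityPartition(assignment=assignment, gamma=gamma)


def interlink_fraction(partition: CommunityPartition, edges: Iterable[Edge]) -> float:
    """Fraction of edges whose endpoints lie in different communities."""
    edges = list(edges)
    if not edges:
        raise ValueError("interlink fraction of an empty edge set is undefined")
    missing = [w for e in edges for w in e if w not in partition.assignment]
    if missing:
        raise KeyError(f"unassigned words in edge set: {missing[:5]}")
    inter = sum(partition.assignment[a] != partition.assignment[b] for a, b in edges)
    return inter / len(edges)


def fraction_sweep(
    sem_window: Iterable[Edge],
    phono: nx.Graph,
    fractions: Sequence[float],
    seed: int = 0,
) -> dict[float, float]:
    """Mean distance of fixed-size multilayers across semantic-link fractions.

    For each semantic fraction f the multilayer keeps the phonological
    network's node set and edge count E, wired with floor(f*E) semantic
    links from ``sem_window`` and E - floor(f*E) phonological links. A
    quota-aware spanning connector runs first (a seeded shuffle of the
    merged candidates, accepting tree edges only while the edge's layer
    quota lasts — connectivity never spends more of a layer than the
    mixture allows), then a seeded top-up fills each quota. Fractions that
    cannot be realized (a layer pool smaller than its quota) are skipped
    with a warning. Links present in both layers can fill either quota.
    """
    from networkx.utils import UnionFind

    nodes = set(phono.nodes())
    sem_all = {canonical_edge(a, b) for a, b in sem_window if a in nodes and b in nodes}
    phono_all = {canonical_edge(a, b) for a, b in phono.edges()}
    both = sem_all & phono_all
    sem_only = sem_all - both
    phono_only = phono_all - both
    e_total = len(phono_all)
    out: dict[float, float] = {}
    seeds = spawn_seeds(seed, len(fractions))
    for f, s in zip(fractions, seeds):
        f = float(f)
        if not (0 < f < 1):
            raise ValueError(f"fractions must lie in (0, 1), got {f}")
        q = {"sem": int(f * e_total), "phono": e_total - int(f * e_total)}
        if q["sem"] > len(sem_all) or q["phono"] > len(phono_all) or q["sem"] + q["phono"] > len(
            sem_only
        ) + len(phono_only) + len(both):
            warnings.warn(f"semantic fraction {f} is unrealizable; skipped", stacklevel=2)
            continue
        rng = np.random.default_rng(s)
        stream = (
            [("sem", e) for e in sorted(sem_only, key=str)]
            + [("phono", e) for e in sorted(phono_only, key=str)]
            + [("both", e) for e in sorted(both, key=str)]
        )
        rng.shuffle(stream)
        taken = {"sem": 0, "phono": 0}

        def _charge(layer: str) -> str | None:
            # which quota does this edge consume? "both" takes whichever is open
            if layer == "both":
                if taken["sem"] < q["sem"]:
                    return "sem"
                if taken["phono"] < q["phono"]:
                    return "phono"
                return None
            return layer if taken[layer] < q[layer] else None

        uf = UnionFind(nodes)
        net = nx.Graph()
        net.add_nodes_from(sorted(nodes, key=str))
        for layer, (a, b) in stream:  # tree pass: connectivity within quotas
            charge = _charge(layer)
            if charge is not None and uf[a] != uf[b]:
                uf.union(a, b)
                net.add_edge(a, b)
                taken[charge] += 1
        for layer, (a, b) in stream:  # fill pass
            if net.has_edge(a, b):
                continue
            charge = _charge(layer)
            if charge is not None:
                net.add_edge(a, b)
                taken[charge] += 1
        if taken["sem"] + taken["phono"] < e_total:
            warnings.warn(f"semantic fraction {f} is unrealizable; skipped", stacklevel=2)
            continue
        out[f] = mean_distance(net, "exclude", f"f={f}").mean_distance
    return out
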