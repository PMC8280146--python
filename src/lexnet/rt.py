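"""Reaction times for relatedness judgments versus network path length.

Word pairs from a relatedness-judgment experiment are bucketed by their
shortest-path length (1-4) in a candidate network; the per-length mean RT
says how well that network's geometry tracks behavior. Networks are
degree-matched before comparison so that density differences cannot drive
the result, and the bucketing is repeated over independently rebuilt
network variants to get a dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .graph_core import Edge, Word, canonical_edge, spanning_connector, spawn_seeds

__all__ = [
    "RTTable",
    "match_degree",
    "match_degree_mixture",
    "rt_by_path_length",
    "subsample_network_replicates",
]


@dataclass
class RTTable:
    """Unordered word pairs with a reaction time in milliseconds."""

    records: list[tuple[Word, Word, float]]

    def __post_init__(self) -> None:
        for a, b, rt in self.records:
            if rt <= 0:
                raise ValueError(f"rt_ms must be positive, got {rt} for ({a!r}, {b!r})")

    def pairs(self) -> list[tuple[Edge, float]]:
        return [(canonical_edge(a, b), rt) for a, b, rt in self.records]


def match_degree(
    net: nx.Graph,
    target_mean_degree: float,
    candidate_links: Iterable[Edge],
    seed: int = 0,
    tolerance: float = 0.05,
) -> nx.Graph:
    """Grow a network to a target mean degree from candidate links.

    Keeps a spanning connector of the existing edges (connectivity is never
    sacrificed), then adds seeded-random candidates until the mean degree is
    within ``tolerance`` of the target. Returns the network unchanged if it
    already meets the target.
    """
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("cannot degree-match an empty network")
    current = 2 * net.number_of_edges() / n
    if abs(current - target_mean_degree) <= tolerance:
        return net.copy()
    if current > target_mean_degree:
        raise ValueError(
            f"network mean degree {current:.3f} already exceeds target {target_mean_degree}"
        )
    out = nx.Graph()
    out.add_nodes_from(net.nodes())
    out.add_edges_from(net.edges())
    pool = sorted(
        {
            canonical_edge(a, b)
            for a, b in candidate_links
            if a in out and b in out and a != b and not out.has_edge(a, b)
        },
        key=str,
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(pool)
    for a, b in pool:
        if 2 * out.number_of_edges() / n >= target_mean_degree - tolerance:
            break
        out.add_edge(a, b)
    achieved = 2 * out.number_of_edges() / n
    if achieved < target_mean_degree - tolerance:
        raise ValueError(
            f"candidates exhausted at mean degree {achieved:.3f} (target {target_mean_degree})"
        )
    return out


def match_degree_mixture(
    nodes: Iterable[Word],
    sem_candidates: Iterable[Edge],
    phono_candidates: Iterable[Edge],
    target_mean_degree: float,
    sem_fraction: float = 0.8,
    seed: int = 0,
    tolerance: float = 0.05,
) -> nx.Graph:
    """Degree-matched multilayer from two candidate pools at a fixed ratio.

    Builds a spanning connector over the merged candidates, then adds
    semantic and phonological links at the ``sem_fraction`` :
    ``1 - sem_fraction`` ratio (e.g. 80%/20%) until the mean degree reaches
    the target; the realized ratio is honored within one link.
    """
    node_set = set(nodes)
    n = len(node_set)
    phono = {
        canonical_edge(a, b) for a, b in phono_candidates if a in node_set and b in node_set
    }
    # overlapping links count as phonological so the denser layer cannot
    # swallow the sparser one's pool
    sem = {
        canonical_edge(a, b) for a, b in sem_candidates if a in node_set and b in node_set
    } - phono
    tree = spanning_connector(node_set, sorted(sem | phono, key=str), seed=seed)
    out = nx.Graph()
    out.add_nodes_from(sorted(node_set, key=str))
    out.add_edges_from(tree)
    e_target = int(round(target_mean_degree * n / 2))
    need = e_target - out.number_of_edges()
    if need < 0:
        raise ValueError("spanning connector alone exceeds the target degree")
    q_sem = int(round(need * sem_fraction))
    q_phono = need - q_sem
    rng = np.random.default_rng(seed)
    sem_pool = sorted(sem - tree, key=str)
    phono_pool = sorted(phono - tree, key=str)
    rng.shuffle(sem_pool)
    rng.shuffle(phono_pool)
    if q_sem > len(sem_pool) or q_phono > len(phono_pool):
        raise ValueError("candidate pools too small for the requested ratio and degree")
    for a, b in sem_pool[:q_sem]:
        out.add_edge(a, b, origin="semantic")
    for a, b in phono_pool[:q_phono]:
        out.add_edge(a, b, origin="phonological")
    achieved = 2 * out.number_of_edges() / n
    if abs(achieved - target_mean_degree) > max(tolerance, 2.0 / n):
        raise ValueError(f"achieved mean degree {achieved:.3f}, target {target_mean_degree}")
    return out


def rt_by_path_length(
    net: nx.Graph | Sequence[nx.Graph] | Callable[[int], nx.Graph],
    rts: RTTable,
    max_length: int = 4,
    n_network_iterations: int = 5,
    seed: int = 0,
) -> dict[int, tuple[float, float, int]]:
    """Mean RT per shortest-path length 1..max_length, over network rebuilds.

    ``net`` may be a single network (every iteration reuses it), a sequence
    of variants, or a callable mapping a derived seed to a freshly rebuilt
    network. Each iteration buckets the RT pairs by that network's hop
    distance; per-length means are then averaged across iterations, with
    the SD taken across iterations. Pairs beyond ``max_length``,
    disconnected, or with a missing word are excluded from that iteration.
    Lengths with no pair in any iteration are reported as missing. Returns
    length -> (mean_rt, sd_over_iterations, n_pairs_in_last_iteration).
    """
    if callable(net) and not isinstance(net, nx.Graph):
        seeds = spawn_seeds(seed, n_network_iterations)
        networks = [net(s) for s in seeds]
    elif isinstance(net, nx.Graph):
        networks = [net] * n_network_iterations
    else:
        networks = list(net)
    pairs = rts.pairs()
    per_iter_means: dict[int, list[float]] = {}
    last_counts: dict[int, int] = {}
    for g in networks:
        buckets: dict[int, list[float]] = {}
        by_source: dict[Word, list[int]] = {}
        for idx, ((a, b), _rt) in enumerate(pairs):
            if a in g and b in g:
                by_source.setdefault(a, []).append(idx)
        for source, idxs in by_source.items():
            lengths = nx.single_source_shortest_path_length(g, source, cutoff=max_length)
            for idx in idxs:
                (a, b), rt = pairs[idx]
                d = lengths.get(b)
                if d is not None and 1 <= d <= max_length:
                    buckets.setdefault(int(d), []).append(rt)
        for d, vals in buckets.items():
            per_iter_means.setdefault(d, []).append(float(np.mean(vals)))
        last_counts = {d: len(vals) for d, vals in buckets.items()}
    out: dict[int, tuple[float, float, int]] = {}
    for d in sorted(per_iter_means):
        means = np.array(per_iter_means[d])
        sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
        out[d] = (float(means.mean()), sd, last_counts.get(d, 0))
    return out


def subsample_network_replicates(
    net: nx.Graph,
    keep_fraction: float,
    n_replicates: int,
    seed: int = 0,
) -> list[nx.Graph]:
    """Seeded edge subsamples, each keeping ``floor(keep_fraction * E)`` edges."""
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    edges = sorted((canonical_edge(a, b) for a, b in net.edges()), key=str)
    k = int(keep_fraction * len(edges))
    replicates = []
    for s in spawn_seeds(seed, n_replicates):
        rng = np.random.default_rng(s)
        idx = rng.choice(len(edges), size=k, replace=False)
        g = nx.Graph()
        g.add_nodes_from(net.nodes())
        g.add_edges_from(edges[i] for i in idx)
        replicates.append(g)
    return replicates
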