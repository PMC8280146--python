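"""Distance reduction from adding non-overlapping links across layers.

Adding links from one layer to the other can only shorten hop distances.
The effect of a class of links (phonological pairs at a given distance, or
a semantic strength group) is measured as the total distance reduction it
causes, relative to adding the same number of uniformly random non-existing
pairs. The Ratio of Path Shortening (RPS) resolves the effect by the
original distance of the pairs that were reduced all the way to distance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .graph_core import Edge, Word, canonical_edge, hop_distance_matrix, spawn_seeds

__all__ = [
    "ReductionResult",
    "nonoverlapping_links",
    "nonoverlapping_links_from_pairs",
    "measure_reduction",
    "reduction_ratio_experiment",
    "rps_table",
    "random_absent_pairs",
]


@dataclass
class ReductionResult:
    """Distance bookkeeping for one link-addition event."""

    condition: str
    total_reduction: float
    direct_reduction_counts: dict[int, int] = field(default_factory=dict)
    n_links_added: int = 0


def nonoverlapping_links(source: nx.Graph, target: nx.Graph) -> set[Edge]:
    """Edges of ``source`` whose endpoints are in ``target`` but which are
    not ``target`` edges (links present in exactly one layer)."""
    shared = set(source.nodes()) & set(target.nodes())
    if not shared:
        raise ValueError("the two layers share no nodes")
    return {
        canonical_edge(a, b)
        for a, b in source.edges()
        if a in shared and b in shared and not target.has_edge(a, b)
    }


def nonoverlapping_links_from_pairs(pairs: Iterable[Edge], target: nx.Graph) -> set[Edge]:
    """Like :func:`nonoverlapping_links` but for a bare pair set (e.g. a
    phonological distance class or a semantic strength group)."""
    return {
        canonical_edge(a, b)
        for a, b in pairs
        if a in target and b in target and not target.has_edge(a, b)
    }


def _reduction_from_matrices(
    before: np.ndarray, after: np.ndarray, condition: str, n_added: int
) -> ReductionResult:
    iu = np.triu_indices(before.shape[0], k=1)
    b, a = before[iu], after[iu]
    finite = np.isfinite(b)
    diff = b[finite] - a[finite]
    total = float(np.sum(np.maximum(diff, 0.0)))
    direct: dict[int, int] = {}
    mask = finite & (a == 1) & (b > 1)
    for k in np.unique(b[mask]).astype(int):
        direct[int(k)] = int(np.sum(b[mask] == k))
    return ReductionResult(condition, total, direct, n_added)


def measure_reduction(
    target: nx.Graph,
    added: Iterable[Edge],
    condition: str = "",
    before: np.ndarray | None = None,
    nodelist: list[Word] | None = None,
) -> ReductionResult:
    """All-pairs distance change from adding ``added`` edges to ``target``.

    ``total_reduction`` sums d_before - d_after over pairs finite before
    (direct and indirect shortenings both count);
    ``direct_reduction_counts[k]`` counts pairs whose distance dropped from
    k straight to 1, i.e. the added edges themselves, keyed by their
    original distance. ``before``/``nodelist`` let callers reuse a
    precomputed distance matrix across many additions.
    """
    added = [canonical_edge(a, b) for a, b in added]
    for a, b in added:
        if target.has_edge(a, b):
            raise ValueError(f"edge ({a!r}, {b!r}) is already present in the target layer")
        if a not in target or b not in target:
            raise ValueError(f"edge ({a!r}, {b!r}) has an endpoint outside the target layer")
    if nodelist is None:
        nodelist = sorted(target.nodes(), key=str)
    if before is None:
        before = hop_distance_matrix(target, nodelist)
    augmented = target.copy()
    augmented.add_edges_from(added)
    after = hop_distance_matrix(augmented, nodelist)
    return _reduction_from_matrices(before, after, condition, len(added))


def random_absent_pairs(
    target: nx.Graph,
    n: int,
    excluded: set[Edge] | None = None,
    seed: int = 0,
) -> list[Edge]:
    """``n`` uniform pairs absent from ``target`` (rejection sampling).

    ``excluded`` pairs (e.g. the link classes under study) are never drawn,
    so the random baseline draws from the theoretical fully connected layer
    minus existing and candidate links.
    """
    nodes = sorted(target.nodes(), key=str)
    n_nodes = len(nodes)
    excluded = excluded or set()
    possible = n_nodes * (n_nodes - 1) // 2 - target.number_of_edges() - len(excluded)
    if n > possible:
        raise ValueError(f"requested {n} absent pairs but only {possible} exist")
    rng = np.random.default_rng(seed)
    chosen: set[Edge] = set()
    while len(chosen) < n:
        i, j = rng.integers(0, n_nodes, size=2)
        if i == j:
            continue
        e = canonical_edge(nodes[i], nodes[j])
        if target.has_edge(*e) or e in excluded or e in chosen:
            continue
        chosen.add(e)
    return sorted(chosen, key=str)


def _run_additions(
    target: nx.Graph,
    link_classes: Mapping[str, Sequence[Edge]],
    n_add: int,
    n_iterations: int,
    seed: int,
) -> tuple[dict[str, list[ReductionResult]], list[ReductionResult]]:
    """Shared engine: per-class and random-baseline additions, all iterations."""
    classes = {name: sorted({canonical_edge(a, b) for a, b in links}, key=str) for name, links in link_classes.items()}
    for name, links in classes.items():
        if len(links) < n_add:
            raise ValueError(f"class {name!r} has {len(links)} links, fewer than n_add={n_add}")
    all_class_links = {e for links in classes.values() for e in links}
    nodelist = sorted(target.nodes(), key=str)
    before = hop_distance_matrix(target, nodelist)
    names = sorted(classes)
    seeds = spawn_seeds(seed, (len(names) + 1) * n_iterations)
    per_class: dict[str, list[ReductionResult]] = {name: [] for name in names}
    for c_idx, name in enumerate(names):
        links = classes[name]
        for it in range(n_iterations):
            rng = np.random.default_rng(seeds[c_idx * n_iterations + it])
            idx = rng.choice(len(links), size=n_add, replace=False)
            sample = [links[i] for i in idx]
            per_class[name].append(
                measure_reduction(target, sample, condition=name, before=before, nodelist=nodelist)
            )
    random_results: list[ReductionResult] = []
    for it in range(n_iterations):
        s = seeds[len(names) * n_iterations + it]
        sample = random_absent_pairs(target, n_add, excluded=all_class_links, seed=s)
        random_results.append(
            measure_reduction(target, sample, condition="random", before=before, nodelist=nodelist)
        )
    return per_class, random_results


def reduction_ratio_experiment(
    target: nx.Graph,
    link_classes: Mapping[str, Sequence[Edge]],
    n_add: int,
    n_iterations: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-class distributions of total reduction relative to random links.

    Each iteration adds ``n_add`` links sampled from the class and records
    the total distance reduction; the per-iteration value is divided by the
    pooled mean reduction of adding ``n_add`` random absent pairs (same
    number of random iterations). Returns class -> array of per-iteration
    ratios, plus a ``"random"`` entry of the baseline's own normalized
    distribution (its mean is 1 by construction).
    """
    per_class, random_results = _run_additions(target, link_classes, n_add, n_iterations, seed)
    random_totals = np.array([r.total_reduction for r in random_results])
    baseline = float(random_totals.mean())
    if baseline == 0:
        raise ValueError("random additions produced no distance reduction; target too dense or n_add too small")
    out = {
        name: np.array([r.total_reduction for r in results]) / baseline
        for name, results in per_class.items()
    }
    out["random"] = random_totals / baseline
    return out


def rps_table(
    target: nx.Graph,
    link_classes: Mapping[str, Sequence[Edge]],
    n_add: int,
    n_iterations: int = 100,
    seed: int = 0,
) -> dict[tuple[str, int], float]:
    """Ratio of Path Shortening: (class, original distance) -> ratio.

    RPS(class, k) = mean count of pairs reduced from distance k to 1 under
    the class, divided by the same mean under random additions. Cells with a
    zero random denominator are reported as NaN (undefined).
    """
    per_class, random_results = _run_additions(target, link_classes, n_add, n_iterations, seed)
    ks = sorted({k for r in random_results for k in r.direct_reduction_counts})
    for results in per_class.values():
        ks = sorted(set(ks) | {k for r in results for k in r.direct_reduction_counts})
    rand_mean = {
        k: float(np.mean([r.direct_reduction_counts.get(k, 0) for r in random_results])) for k in ks
    }
    table: dict[tuple[str, int], float] = {}
    for name, results in per_class.items():
        for k in ks:
            num = float(np.mean([r.direct_reduction_counts.get(k, 0) for r in results]))
            table[(name, k)] = num / rand_mean[k] if rand_mean[k] > 0 else float("nan")
    return table
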