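"""Link overlap between the semantic and phonological layers, against nulls.

Two complementary resampling analyses:

* :func:`window_overlap_ratio` — per ascending-strength semantic window, how
  often sampled semantic links coincide with phonological pairs at distance
  d, relative to the same count on a freshly randomized phonological network
  (degree-preserving shuffle by default).
* :func:`distance_class_overlap` — per phonological distance class, the
  fraction of sampled phonological pairs that are semantic links of each
  strength group, with an edge-permutation null of the semantic layer as the
  fourth series.

A fresh null network is drawn for every iteration, so the reported
dispersion reflects both sampling and null variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .graph_core import (
    Edge,
    canonical_edge,
    degree_preserving_shuffle,
    edge_permutation_null,
    spawn_seeds,
)
from .semantic import StrengthWindow

__all__ = ["OverlapResult", "window_overlap_ratio", "distance_class_overlap"]

NullModel = Literal["degree_preserving", "edge_permutation", "identity"]


@dataclass(frozen=True)
class OverlapResult:
    """Mean/SD over iterations of one overlap series.

    ``window_or_class`` identifies the semantic window (or phonological
    distance class); ``distance_or_group`` the phonological distance (or
    strength group). ``empty`` flags a window with no usable pair.
    """

    window_or_class: str
    distance_or_group: str
    ratio_mean: float
    ratio_sd: float
    n_iterations: int
    sample_size: int
    empty: bool = False


def _pair_distances_on(net: nx.Graph, pairs: Sequence[Edge], max_distance: int) -> np.ndarray:
    """Hop distance in ``net`` for each pair, capped BFS; inf beyond cutoff."""
    out = np.full(len(pairs), np.inf)
    by_source: dict[object, list[int]] = {}
    for idx, (a, b) in enumerate(pairs):
        by_source.setdefault(a, []).append(idx)
    for source, idxs in by_source.items():
        lengths = nx.single_source_shortest_path_length(net, source, cutoff=max_distance)
        for idx in idxs:
            b = pairs[idx][1]
            if b in lengths:
                out[idx] = lengths[b]
    return out


def _distance_class_sizes(net: nx.Graph, max_distance: int) -> np.ndarray:
    """Number of unordered pairs at each hop distance 1..max_distance."""
    sizes = np.zeros(max_distance + 1)
    for source in net.nodes():
        lengths = nx.single_source_shortest_path_length(net, source, cutoff=max_distance)
        for d in lengths.values():
            if 1 <= d <= max_distance:
                sizes[d] += 1
    return sizes / 2.0  # each unordered pair counted from both endpoints


def _make_null(net: nx.Graph, null: NullModel, seed: int) -> nx.Graph:
    if null == "degree_preserving":
        return degree_preserving_shuffle(net, seed=seed)
    if null == "edge_permutation":
        return edge_permutation_null(net, seed=seed)
    if null == "identity":  # degenerate null for sanity checks: ratio must be 1
        return net
    raise ValueError(f"unknown null model {null!r}")


def window_overlap_ratio(
    sem_windows: Iterable[StrengthWindow],
    phono_net: nx.Graph,
    distances: Iterable[int] = (1, 2, 3),
    sample_size: int = 10_000,
    n_iterations: int = 100,
    seed: int = 0,
    null: NullModel = "degree_preserving",
    normalize_by_class_size: bool = True,
) -> list[OverlapResult]:
    """Overlap ratio of semantic windows with phonological distance classes.

    Per window and distance d, each iteration samples ``sample_size``
    semantic links (restricted to pairs whose endpoints are both in
    ``phono_net``) and counts the fraction at phonological distance d, both
    on the real network and on a freshly drawn null network. The reported
    ratio is the iteration *average* of the real fraction divided by the
    iteration average of the null fraction — a ratio of means, which stays
    well defined and unbiased even when single-iteration null counts are
    zero (overlap events are rare in small samples). ``ratio_sd`` is the
    dispersion of the per-iteration real fraction on the ratio scale
    (sd of real fractions divided by the mean null fraction). When
    ``normalize_by_class_size`` each fraction is further divided by the
    size of that network's distance-d class (the per-distance normalization
    by number of links); the normalization cancels only approximately in
    the ratio because the null's class sizes differ from the real ones.
    """
    distances = sorted(set(distances))
    if not distances or min(distances) < 1:
        raise ValueError("distances must be positive integers")
    dmax = max(distances)
    phono_nodes = set(phono_net.nodes())
    real_sizes = _distance_class_sizes(phono_net, dmax) if normalize_by_class_size else None
    results: list[OverlapResult] = []
    windows = list(sem_windows)
    seeds = spawn_seeds(seed, len(windows) * n_iterations)
    for w_idx, window in enumerate(windows):
        label = f"window[{window.rank_range[0]}:{window.rank_range[1]}]"
        usable = [canonical_edge(a, b) for a, b in window.links if a in phono_nodes and b in phono_nodes]
        if not usable:
            for d in distances:
                results.append(
                    OverlapResult(label, f"d={d}", float("nan"), float("nan"), 0, 0, empty=True)
                )
            continue
        k = min(sample_size, len(usable))
        f_real: dict[int, list[float]] = {d: [] for d in distances}
        f_null: dict[int, list[float]] = {d: [] for d in distances}
        for it in range(n_iterations):
            it_seed = seeds[w_idx * n_iterations + it]
            rng = np.random.default_rng(it_seed)
            idx = rng.choice(len(usable), size=k, replace=False)
            sample = [usable[i] for i in idx]
            null_net = _make_null(phono_net, null, seed=it_seed)
            d_real = _pair_distances_on(phono_net, sample, dmax)
            d_null = _pair_distances_on(null_net, sample, dmax)
            null_sizes = _distance_class_sizes(null_net, dmax) if normalize_by_class_size else None
            for d in distances:
                fr = float(np.sum(d_real == d)) / k
                fn = float(np.sum(d_null == d)) / k
                if normalize_by_class_size:
                    fr = fr / real_sizes[d] if real_sizes[d] > 0 else 0.0
                    fn = fn / null_sizes[d] if null_sizes[d] > 0 else 0.0
                f_real[d].append(fr)
                f_null[d].append(fn)
        for d in distances:
            real_arr = np.array(f_real[d])
            null_mean = float(np.mean(f_null[d]))
            if null_mean == 0.0:
                results.append(OverlapResult(label, f"d={d}", float("nan"), float("nan"), 0, k, empty=True))
                continue
            results.append(
                OverlapResult(
                    label,
                    f"d={d}",
                    float(real_arr.mean()) / null_mean,
                    float(real_arr.std(ddof=1)) / null_mean if real_arr.size > 1 else 0.0,
                    int(real_arr.size),
                    k,
                )
            )
    return results


def distance_class_overlap(
    phono_classes: Mapping[int, set[Edge]],
    sem_groups: Mapping[str, Iterable[Edge]],
    sem_net: nx.Graph,
    sample_size: int = 3_000,
    n_iterations: int = 100,
    seed: int = 0,
    null: NullModel = "edge_permutation",
) -> list[OverlapResult]:
    """Fraction of sampled phonological pairs that are semantic links per group.

    For each phonological distance class d and strength group g, each
    iteration samples ``sample_size`` distance-d pairs (capped at the class
    size) and measures the fraction that are edges of g. A fourth series,
    ``"null"``, uses the edges of a freshly permuted semantic network in
    place of g. ``sem_net`` is the (unweighted view of the) semantic layer
    the null permutes.
    """
    groups = {name: {canonical_edge(a, b) for a, b in edges} for name, edges in sem_groups.items()}
    for name, edges in groups.items():
        if not edges:
            raise ValueError(f"strength group {name!r} is empty")
    classes = {d: sorted(pairs, key=str) for d, pairs in phono_classes.items()}
    for d, pairs in classes.items():
        if not pairs:
            raise ValueError(f"phonological distance class {d} is empty")
    results: list[OverlapResult] = []
    class_keys = sorted(classes)
    seeds = spawn_seeds(seed, len(class_keys) * n_iterations)
    for c_idx, d in enumerate(class_keys):
        pairs = classes[d]
        k = min(sample_size, len(pairs))
        fracs: dict[str, list[float]] = {name: [] for name in groups}
        fracs["null"] = []
        for it in range(n_iterations):
            it_seed = seeds[c_idx * n_iterations + it]
            rng = np.random.default_rng(it_seed)
            idx = rng.choice(len(pairs), size=k, replace=False)
            sample = [pairs[i] for i in idx]
            for name, edge_set in groups.items():
                fracs[name].append(sum(p in edge_set for p in sample) / k)
            null_net = _make_null(sem_net, null, seed=it_seed)
            null_edges = {canonical_edge(a, b) for a, b in null_net.edges()}
            fracs["null"].append(sum(p in null_edges for p in sample) / k)
        for name, vals_list in fracs.items():
            vals = np.array(vals_list)
            results.append(
                OverlapResult(
                    f"d={d}",
                    name,
                    float(vals.mean()),
                    float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    int(vals.size),
                    k,
                )
            )
    return results
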