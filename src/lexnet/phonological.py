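"""Phonological layer: neighborhood network at phoneme edit distance 1.

Words are linked when one can be turned into the other by adding, deleting,
or substituting a single phoneme (Levenshtein distance 1 over phoneme
tokens). The transcription format is deliberately unconstrained: any
whitespace-separated token counts as one phoneme, so ARPAbet, IPA, or
synthetic alphabets all work, and orthographic letters can stand in for
phonemes when no transcription is available.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .graph_core import Edge, Word, canonical_edge, hop_distance_matrix

__all__ = [
    "PhonemeTranscription",
    "phoneme_edit_distance",
    "build_phonological_network",
    "distance_class_pairs",
]


@dataclass(frozen=True)
class PhonemeTranscription:
    """One word with its ordered phoneme sequence."""

    word: Word
    phonemes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.phonemes) < 1:
            raise ValueError(f"transcription of {self.word!r} is empty")
        for p in self.phonemes:
            if not p or any(ch.isspace() for ch in p):
                raise ValueError(f"invalid phoneme token {p!r} in {self.word!r}")


def phoneme_edit_distance(t1: PhonemeTranscription, t2: PhonemeTranscription) -> int:
    """Levenshtein distance over phoneme tokens (unit edit costs)."""
    a, b = t1.phonemes, t2.phonemes
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, pa in enumerate(a, start=1):
        cur = [i]
        for j, pb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (pa != pb)))
        prev = cur
    return prev[-1]


def _within_one_edit(a: Sequence[str], b: Sequence[str]) -> bool:
    """True iff the sequences are at Levenshtein distance exactly 0 or 1.

    O(len) check used as the pairwise fast path; equivalent to
    ``phoneme_edit_distance(...) <= 1``.
    """
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) <= 1
    if la < lb:
        a, b, la, lb = b, a, lb, la
    # la == lb + 1: b must equal a with one token removed
    i = 0
    while i < lb and a[i] == b[i]:
        i += 1
    return tuple(a[i + 1 :]) == tuple(b[i:])


def build_phonological_network(
    transcriptions: Iterable[PhonemeTranscription],
) -> nx.Graph:
    """Unweighted network linking word pairs at phoneme edit distance 1.

    Nodes are all input words (isolates included — downstream analyses take
    the giant component). Homophones (edit distance 0 between distinct
    words) get no edge. A length-bucketing prefilter skips pairs whose
    lengths differ by 2 or more; it never changes the result.
    """
    items: list[PhonemeTranscription] = []
    seen: dict[Word, tuple[str, ...]] = {}
    for t in transcriptions:
        if t.word in seen:
            if seen[t.word] != t.phonemes:
                raise ValueError(f"conflicting transcriptions for {t.word!r}")
            continue
        seen[t.word] = t.phonemes
        items.append(t)
    if not items:
        raise ValueError("at least one transcription is required")
    net = nx.Graph()
    net.add_nodes_from(t.word for t in items)
    by_length: dict[int, list[PhonemeTranscription]] = defaultdict(list)
    for t in items:
        by_length[len(t.phonemes)].append(t)
    for length, bucket in by_length.items():
        # same-length pairs (substitution candidates)
        for i, t1 in enumerate(bucket):
            for t2 in bucket[i + 1 :]:
                if t1.phonemes != t2.phonemes and _within_one_edit(t1.phonemes, t2.phonemes):
                    net.add_edge(t1.word, t2.word)
        # length + 1 pairs (insertion/deletion candidates)
        for t1 in bucket:
            for t2 in by_length.get(length + 1, ()):
                if _within_one_edit(t1.phonemes, t2.phonemes):
                    net.add_edge(t1.word, t2.word)
    return net


def distance_class_pairs(net: nx.Graph, max_distance: int) -> Mapping[int, set[Edge]]:
    """Unordered node pairs at each exact shortest-path distance 1..max_distance.

    The classes are disjoint and, up to the network diameter, partition the
    connected pairs. The network should be connected (apply the giant
    component first); disconnected pairs are simply never classified.
    """
    if max_distance < 1:
        raise ValueError("max_distance must be >= 1")
    nodelist = sorted(net.nodes(), key=str)
    dist = hop_distance_matrix(net, nodelist)
    classes: dict[int, set[Edge]] = {d: set() for d in range(1, max_distance + 1)}
    n = len(nodelist)
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if 1 <= d <= max_distance:
                classes[int(d)].add(canonical_edge(nodelist[i], nodelist[j]))
    return classes
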