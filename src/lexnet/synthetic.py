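"""Synthetic lexicons with controllable phonology-semantics coupling.

The generator emulates the statistical structure the analyses assume,
without any real behavioral data:

* a phoneme-level word inventory whose edit-distance-1 graph has a
  nontrivial giant component (new words are, with some probability, single
  edits of existing words — a crude stand-in for the morphological and
  phonotactic regularities that make real lexicons phonologically clumpy);
* a free-association table in which each cue's simulated participants draw
  responses from topic pools (planted semantic communities) and, with
  probability ``coupling_rho``, from signature pools shared with the cue's
  phonological neighbors. The coupling therefore reaches the semantic layer
  only through the min-participant-sum link estimator, never by wiring the
  semantic graph directly;
* reaction times that increase linearly with path length in a reference
  network, with Gaussian noise.

With ``coupling_rho = 0`` the semantic layer is independent of phonology
(null calibration); at high ``coupling_rho`` phonological neighbors share
strong semantic links (planted signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .graph_core import Word, canonical_edge
from .phonological import PhonemeTranscription, build_phonological_network, distance_class_pairs
from .rt import RTTable
from .semantic import AssociationTable

__all__ = [
    "SyntheticConfig",
    "generate_lexicon",
    "generate_associations",
    "generate_rts",
    "planted_topics",
]


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic lexicon.

    ``n_responses_per_participant`` defaults to 3 (each simulated
    participant gives three associative responses per cue, matching the
    standard free-association collection design).
    ``mutation_prob`` is the probability that a new word is a single edit
    of an existing one rather than a fresh random string; it controls the
    density of the phonological neighborhood graph.
    ``intra_community_boost`` multiplies the odds of drawing a response
    from the cue's own topic pool relative to each other topic.
    """

    n_words: int = 500
    phoneme_alphabet_size: int = 8
    word_length_range: tuple[int, int] = (3, 6)
    n_participants_per_cue: int = 50
    n_responses_per_participant: int = 3
    coupling_rho: float = 0.0
    n_communities: int = 4
    intra_community_boost: float = 6.0
    topic_pool_size: int = 30
    mutation_prob: float = 0.7
    rt_intercept_ms: float = 650.0
    rt_slope_ms: float = 40.0
    rt_noise_sd_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_rho <= 1.0):
            raise ValueError("coupling_rho must lie in [0, 1]")
        lo, hi = self.word_length_range
        if lo < 1 or hi < lo:
            raise ValueError("word_length_range must be a nonempty positive interval")
        for name in (
            "n_words",
            "phoneme_alphabet_size",
            "n_participants_per_cue",
            "n_responses_per_participant",
            "n_communities",
            "topic_pool_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.intra_community_boost < 1:
            raise ValueError("intra_community_boost must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["word_length_range"] = list(self.word_length_range)
        return d

    @staticmethod
    def from_dict(d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "word_length_range" in d:
            d["word_length_range"] = tuple(d["word_length_range"])
        return SyntheticConfig(**d)


def _alphabet(size: int) -> list[str]:
    # single printable symbols; beyond 26 fall back to indexed tokens
    letters = "abcdefghijklmnopqrstuvwxyz"
    if size <= len(letters):
        return list(letters[:size])
    return [f"p{i}" for i in range(size)]


def generate_lexicon(config: SyntheticConfig) -> list[PhonemeTranscription]:
    """Seeded inventory of ``n_words`` unique pseudo-words.

    Each new word is, with probability ``mutation_prob``, one random edit
    (substitution, insertion, or deletion, kept within the length range) of
    a previously generated word — creating phonological neighborhoods —
    and otherwise a uniform random string. Word identifiers are the joined
    phoneme symbols, so homophones cannot arise.
    """
    if config.phoneme_alphabet_size < 2:
        raise ValueError("need an alphabet of at least 2 phonemes")
    rng = np.random.default_rng(config.seed)
    alphabet = _alphabet(config.phoneme_alphabet_size)
    lo, hi = config.word_length_range
    words: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    max_tries = 500 * config.n_words
    tries = 0
    while len(words) < config.n_words:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not generate {config.n_words} unique words within the length range"
            )
        if words and rng.random() < config.mutation_prob:
            base = list(words[rng.integers(len(words))])
            move = rng.integers(3)
            if move == 0 or (move == 2 and len(base) <= lo) or (move == 1 and len(base) >= hi):
                pos = rng.integers(len(base))
                base[pos] = alphabet[rng.integers(len(alphabet))]
            elif move == 1:  # insertion
                pos = rng.integers(len(base) + 1)
                base.insert(pos, alphabet[rng.integers(len(alphabet))])
            else:  # deletion
                pos = rng.integers(len(base))
                del base[pos]
            candidate = tuple(base)
        else:
            length = int(rng.integers(lo, hi + 1))
            candidate = tuple(alphabet[i] for i in rng.integers(len(alphabet), size=length))
        if candidate in seen:
            continue
        seen.add(candidate)
        words.append(candidate)
    return [PhonemeTranscription(word="".join(w) if all(len(p) == 1 for p in w) else "-".join(w), phonemes=w) for w in words]


def planted_topics(
    config: SyntheticConfig,
    lexicon: list[PhonemeTranscription],
) -> dict[Word, int]:
    """The planted community assignment used by :func:`generate_associations`.

    Words are shuffled (seeded independently of phonology) and dealt
    round-robin into ``n_communities`` equal topics.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    order = [t.word for t in lexicon]
    rng.shuffle(order)
    return {w: i % config.n_communities for i, w in enumerate(order)}


def generate_associations(
    config: SyntheticConfig,
    lexicon: list[PhonemeTranscription],
) -> AssociationTable:
    """Simulated free-association counts with planted structure.

    Words are partitioned into ``n_communities`` equal topics (shuffled, so
    topics are independent of phonology). For every cue,
    ``n_participants_per_cue * n_responses_per_participant`` responses are
    drawn: with probability ``coupling_rho`` a *signature* response keyed to
    a uniformly chosen member of the cue's closed phonological neighborhood
    (cue plus edit-distance-1 neighbors) — so phonological neighbors end up
    sharing high-count responses — and otherwise a response from a topic
    pool, favoring the cue's own topic by ``intra_community_boost``.
    Per-(cue, response) counts are aggregated; the total count per cue is
    exactly the number of draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    words = [t.word for t in lexicon]
    phono = build_phonological_network(lexicon)
    neighbors = {w: sorted(phono.neighbors(w), key=str) for w in words}

    topic_of = planted_topics(config, lexicon)

    k = config.n_communities
    boost = config.intra_community_boost
    # topic sampling probabilities for a cue in topic t
    topic_probs = {}
    for t in range(k):
        p = np.full(k, 1.0)
        p[t] = boost
        topic_probs[t] = p / p.sum()

    n_draws = config.n_participants_per_cue * config.n_responses_per_participant
    pool = config.topic_pool_size
    counts: dict[Word, dict[str, int]] = {}
    for cue in words:
        by_resp: dict[str, int] = {}
        hood = [cue] + neighbors[cue]
        coupled = rng.random(n_draws) < config.coupling_rho
        n_coupled = int(coupled.sum())
        if n_coupled:
            picks = rng.integers(len(hood), size=n_coupled)
            for i in picks:
                r = f"sig:{hood[i]}"
                by_resp[r] = by_resp.get(r, 0) + 1
        n_topic = n_draws - n_coupled
        if n_topic:
            topics = rng.choice(k, size=n_topic, p=topic_probs[topic_of[cue]])
            slots = rng.integers(pool, size=n_topic)
            for t, s in zip(topics, slots):
                r = f"t{t}:r{s}"
                by_resp[r] = by_resp.get(r, 0) + 1
        counts[cue] = by_resp
    return AssociationTable.from_counts(counts)


def generate_rts(
    config: SyntheticConfig,
    net: nx.Graph,
    n_pairs: int,
    max_length: int = 4,
) -> RTTable:
    """RT table with a linear path-length effect in ``net``.

    Samples ``n_pairs`` word pairs balanced over hop distances
    1..``max_length`` in ``net`` (classes smaller than their share are
    capped; empty classes are skipped with a warning) and assigns
    ``rt = intercept + slope * distance + N(0, noise_sd)``, floored at 1 ms.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    classes = distance_class_pairs(net, max_length)
    per_class = max(1, n_pairs // max_length)
    records: list[tuple[Word, Word, float]] = []
    for d in range(1, max_length + 1):
        pairs = sorted(classes.get(d, ()), key=str)
        if not pairs:
            warnings.warn(f"no pairs at distance {d}; class skipped", stacklevel=2)
            continue
        take = min(per_class, len(pairs))
        idx = rng.choice(len(pairs), size=take, replace=False)
        for i in idx:
            a, b = pairs[i]
            rt = config.rt_intercept_ms + config.rt_slope_ms * d
            if config.rt_noise_sd_ms > 0:
                rt += rng.normal(0.0, config.rt_noise_sd_ms)
            records.append((a, b, max(rt, 1.0)))
    return RTTable(records)
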