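"""Shared fixtures: small worked-example graphs and session-scoped
synthetic pipelines at the desk-scale study conditions (500 words, 50
participants per cue, 25 resampling iterations)."""

from __future__ import annotations

import networkx as nx
import pytest

from lexnet import graph_core, phonological, semantic, synthetic

# orthographic stand-in transcriptions: letters as phonemes; the four words
# form a substitution chain intend - intent - invent - invest
INTEND_CHAIN = {
    "intend": tuple("intend"),
    "intent": tuple("intent"),
    "invent": tuple("invent"),
    "invest": tuple("invest"),
}


@pytest.fixture
def intend_chain_net() -> nx.Graph:
    trans = [phonological.PhonemeTranscription(w, p) for w, p in INTEND_CHAIN.items()]
    return phonological.build_phonological_network(trans)


@pytest.fixture
def path_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d")])
    return g


def _pipeline(seed: int, rho: float) -> dict:
    cfg = synthetic.SyntheticConfig(seed=seed, coupling_rho=rho)
    lexicon = synthetic.generate_lexicon(cfg)
    table = synthetic.generate_associations(cfg, lexicon)
    sem = semantic.build_semantic_network(table)
    phono = graph_core.giant_component(phonological.build_phonological_network(lexicon))
    sem_shared = sem.subgraph(set(phono.nodes())).copy()
    return {
        "config": cfg,
        "lexicon": lexicon,
        "table": table,
        "sem": sem,
        "phono": phono,
        "sem_shared": sem_shared,
    }


@pytest.fixture(scope="session")
def rho0_pipeline() -> dict:
    """Uncoupled lexicon: semantic layer independent of phonology."""
    return _pipeline(seed=1, rho=0.0)


@pytest.fixture(scope="session")
def rho04_pipeline() -> dict:
    """Moderately coupled lexicon used by the multilayer and RT analyses."""
    return _pipeline(seed=1, rho=0.4)


@pytest.fixture(scope="session")
def rho08_pipeline() -> dict:
    """Strongly coupled lexicon: planted phonology-semantics signal."""
    return _pipeline(seed=1, rho=0.8)
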