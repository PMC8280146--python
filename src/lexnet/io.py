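"""TSV readers and writers for the pipeline's plain-text formats.

Edge lists: ``word_a<TAB>word_b[<TAB>weight]`` with a ``#source\ttarget\tweight``
header; transcriptions: ``word<TAB>phoneme phoneme ...``; associations:
``cue<TAB>response<TAB>participant_count``; reaction times:
``word_a<TAB>word_b<TAB>rt_ms``. Everything is UTF-8.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .phonological import PhonemeTranscription
from .rt import RTTable
from .semantic import AssociationTable
from .synthetic import SyntheticConfig

__all__ = [
    "write_edgelist",
    "read_edgelist",
    "write_transcriptions",
    "read_transcriptions",
    "write_associations",
    "read_associations",
    "write_rts",
    "read_rts",
    "write_config",
    "read_config",
]

_EDGE_HEADER = "#source\ttarget\tweight"


def write_edgelist(net: nx.Graph, path: str | Path) -> None:
    weighted = any("weight" in d for _, _, d in net.edges(data=True))
    lines = [_EDGE_HEADER]
    for a, b, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        if weighted:
            lines.append(f"{a}\t{b}\t{d.get('weight', 1)}")
        else:
            lines.append(f"{a}\t{b}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edgelist(path: str | Path) -> nx.Graph:
    net = nx.Graph()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 2:
            net.add_edge(parts[0], parts[1])
        else:
            net.add_edge(parts[0], parts[1], weight=float(parts[2]))
    return net


def write_transcriptions(transcriptions: list[PhonemeTranscription], path: str | Path) -> None:
    lines = [f"{t.word}\t{' '.join(t.phonemes)}" for t in transcriptions]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_transcriptions(path: str | Path) -> list[PhonemeTranscription]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        word, phonemes = line.split("\t", 1)
        out.append(PhonemeTranscription(word=word, phonemes=tuple(phonemes.split())))
    return out


def write_associations(table: AssociationTable, path: str | Path) -> None:
    df = pd.DataFrame(table.records, columns=["cue", "response", "participant_count"])
    df.to_csv(path, sep="\t", index=False)


def read_associations(path: str | Path) -> AssociationTable:
    df = pd.read_csv(path, sep="\t", dtype={"cue": str, "response": str, "participant_count": int})
    return AssociationTable([tuple(r) for r in df.itertuples(index=False)])


def write_rts(table: RTTable, path: str | Path) -> None:
    df = pd.DataFrame(table.records, columns=["word_a", "word_b", "rt_ms"])
    df.to_csv(path, sep="\t", index=False)


def read_rts(path: str | Path) -> RTTable:
    df = pd.read_csv(path, sep="\t", dtype={"word_a": str, "word_b": str, "rt_ms": float})
    return RTTable([tuple(r) for r in df.itertuples(index=False)])


def write_config(config: SyntheticConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8")


def read_config(path: str | Path) -> SyntheticConfig:
    return SyntheticConfig.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
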