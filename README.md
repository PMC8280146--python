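# lexnet

Multilayer network analysis of the mental lexicon: how the *sound* of words
(phonology) and their *meaning* (semantics) jointly shape the distances a
lexical search has to cover.

`lexnet` is aimed at cognitive network scientists and psycholinguists. It
builds two layers over one vocabulary of cue words:

* a **semantic layer**, estimated from free-association data. For cues
  $C_i, C_j$ the link weight is the min-participant-sum similarity

  $$\mathrm{Link}(C_i, C_j) = \sum_k \min\bigl(\#P_{C_i}A(k),\, \#P_{C_j}A(k)\bigr),$$

  summing over associative responses $k$ produced to both cues, where
  $\#P_{C}A(k)$ is the number of participants giving response $k$ to cue
  $C$; terms whose min is below 2 are dropped as single-participant noise;
* a **phonological layer**, linking word pairs at phoneme Levenshtein
  distance 1 (one addition, deletion, or substitution), e.g. the chain
  *intend – intent – invent – invest*.

On top of the layers the package quantifies

1. **link overlap** between layers per semantic-strength window and
   phonological distance class, against degree-preserving or
   edge-permutation null models (ratio of iteration means);
2. **distance reduction** from adding non-overlapping links of one layer to
   the other versus adding random absent pairs, including the Ratio of Path
   Shortening, $\mathrm{RPS}(k)$ = (pairs reduced from distance $k$ to 1 by
   class links) / (same count for random links);
3. **degree-matched architecture comparison**: semantic-only,
   phonological-only, multilayer, and random networks with identical node
   sets, edge counts and mean degree, swept across semantic-strength
   windows, plus community inter-link fractions (Louvain, $\gamma = 1$) and
   the optimal semantic/phonological mixing fraction;
4. **reaction-time comparison**: relatedness-judgment RTs bucketed by a
   network's path length (1–4) on degree-matched variants.

A fully seeded synthetic-lexicon generator with a tunable
phonology–semantics coupling $\rho$ and planted semantic communities makes
every analysis testable without any behavioral data collection.

## Worked example

```python
from lexnet import graph_core, multilayer, overlap, phonological, semantic, synthetic

cfg = synthetic.SyntheticConfig(n_words=500, coupling_rho=0.8, seed=1)
lexicon = synthetic.generate_lexicon(cfg)
table = synthetic.generate_associations(cfg, lexicon)

sem = semantic.build_semantic_network(table)            # weighted
phono = graph_core.giant_component(
    phonological.build_phonological_network(lexicon)
)
print(f"phonological layer: {phono.number_of_nodes()} nodes, "
      f"{phono.number_of_edges()} links")

sem_shared = sem.subgraph(phono.nodes()).copy()
windows = semantic.sort_and_window(sem_shared, 5000)
results = overlap.window_overlap_ratio(
    windows[-1:], phono, distances=(1,), sample_size=100,
    n_iterations=25, seed=7,
)
r = results[0]
print(f"strongest-window overlap ratio at distance 1: "
      f"{r.ratio_mean:.1f} (sd {r.ratio_sd:.1f})")
```

prints

```
phonological layer: 364 nodes, 667 links
strongest-window overlap ratio at distance 1: 13.7 (sd 1.8)
```

At coupling 0.8 the strongest semantic links overlap phonological neighbors
almost 14 times more often than a degree-preserving shuffle of the
phonological layer — the planted coupling is recovered. With
`coupling_rho=0` the same ratio is statistically indistinguishable from 1.

The degree-matched architecture comparison (here at coupling 0.4, strongest
semantic window):

```python
quad = multilayer.build_matched_quadruple(sem, phono, 1.0, seed=0)
for name in ("phonological", "semantic", "multilayer", "random"):
    d = graph_core.mean_distance(getattr(quad, name)).mean_distance
    print(f"mean distance, {name:12s}: {d:.2f}")
```

```
mean distance, phonological: 6.49
mean distance, semantic    : 5.73
mean distance, multilayer  : 4.92
mean distance, random      : 4.54
```

All four networks share nodes, edge count and mean degree; only the wiring
differs. The multilayer sits between the single layers and the random
bound: combining layers shortens lexical distances beyond either layer
alone.

A `lexnet` command exposes the pipeline stages for shell use
(`lexnet simulate`, `build-phono`, `build-sem`, `overlap`, `add-links`,
`multilayer`, `rt`); every subcommand reads and writes plain TSV.

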