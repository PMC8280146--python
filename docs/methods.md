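# Methods

## Layers

**Semantic layer.** Input is a free-association table of (cue, response,
participant count) records. The link weight between two cues is the
min-participant-sum similarity: over responses produced to both cues, the
smaller of the two participant counts is summed. A shared response counts
only when that smaller count is at least `min_shared_participants`
(default 2): an overlap that a single participant could have produced on
either side is treated as noise. This threshold semantics — the filter sits
on the *min*, not on each cue's count separately — is a deliberate reading
of "more than one participant contributed to the overlapping association";
the parameter reaches both readings. Responses are matched by exact string
equality; a normalization hook (`AssociationTable.normalized`) can merge
plural forms or case variants before table construction but is off by
default. The network is undirected; the cue→response direction is not
retained. Responses that are not cues contribute to weights but never
become nodes.

**Phonological layer.** Words are linked iff their phoneme sequences are at
Levenshtein distance exactly 1 (unit-cost addition, deletion,
substitution). Any whitespace-separated token counts as one phoneme, so
ARPAbet, IPA, synthetic alphabets, or plain orthography all work; stress
or boundary markers, if present, are ordinary tokens. Homophones (distance
0) get no edge. Pair enumeration is bucketed by sequence length (pairs
differing by ≥ 2 in length cannot be at distance 1), which changes nothing
about the result. Analyses consume the giant component; isolates are
reported, not silently dropped.

## Distances and null models

All distances are hop counts; the semantic layer is converted to
unweighted before any distance computation. All-pairs distances go through
`scipy.sparse.csgraph` BFS; disconnected pairs are infinite and the default
averaging policy excludes them (`giant_component_only` is available).

Two nulls are implemented and each analysis names which one it uses:

* `degree_preserving_shuffle` — repeated double-edge swaps; proposals
  creating self-loops or duplicate edges are rejected; `10 × |E|` proposals
  by default. Graphs admitting no swap (triangle, star) are returned
  unchanged. Used by the window-overlap analysis.
* `edge_permutation_null` — same node set and edge count, endpoints redrawn
  uniformly; the degree sequence is *not* preserved. Used by the
  distance-class overlap analysis and as the random member of the matched
  quadruple.

The split follows the two different constructions the overlap analyses
describe; which null backed which original figure panel is not decidable,
so the per-stage defaults are explicit configuration.

All randomized operations take a seed; a run-level master seed spawns
per-iteration seeds through `numpy.random.SeedSequence`, so one seed fixes
the entire pipeline bit for bit.

## Overlap statistics

The window-overlap ratio is a **ratio of iteration means**: the average
(over iterations) fraction of sampled semantic links at phonological
distance d, divided by the same average on freshly drawn null networks
(one per iteration), each fraction optionally normalized by the network's
distance-d class size. The mean-of-ratios alternative is biased at small
samples — single-iteration null counts of zero would have to be discarded,
conditioning the estimate toward 0 — whereas the ratio of means stays
defined and centers on 1 under the null. The reported `ratio_sd` is the
dispersion of the per-iteration numerator on the ratio scale.

Semantic links whose endpoints fall outside the phonological giant
component are excluded before sampling; a window with no usable pair is
flagged empty rather than raising.

## Link addition

`measure_reduction` recomputes exact all-pairs distances before and after
the addition; `total_reduction` sums direct and indirect shortenings over
pairs finite before, and `direct_reduction_counts[k]` counts pairs whose
distance fell from k straight to 1 (necessarily the added edges). The
random baseline draws uniformly from absent pairs (rejection sampling;
existing edges and all candidate-class links excluded) and the per-class
ratio divides each iteration's total by the pooled mean of the random
totals — pooled rather than paired, since no pairing is defined between
class draws and random draws. RPS divides mean direct counts; cells with a
zero random denominator are NaN.

The distance-reduction target is the giant component of the top-fraction
filtered semantic network. At the package's desk scale (500 words) the
top-1% network has on the order of a hundred links and a degenerate giant
component, so the analyses default to the top 5–10% — the same
construction at a density where distances are informative. Boundary ties in
the top-fraction filter are broken lexicographically; the filter is
monotone in the fraction under that fixed rule.

Strength groups come in two modes: `terciles` (three contiguous
equal-thirds of the ascending strength order) and `separated` (equal groups
of `|E| // 5` links from the bottom, middle and top, with the remaining
links split evenly into two excluded gaps). The latter is this package's
concrete rendering of "maximally separable" groups — a declared convention,
not a reconstruction.

## Degree-matched architectures

`build_matched_quadruple` holds the node set (words shared by both giant
components) and edge count (the phonological network's, restricted to
those nodes) fixed across four networks. The semantic member keeps a
spanning connector built from the strongest available links, then fills
from the strength window downward; `window_percentile` = 1.0 starts at the
strongest link, 0.99 skips the top 1%. The multilayer member merges the
windowed semantic links with the phonological layer, prunes to a spanning
connector, then refills alternately with the strongest remaining semantic
link and a seeded-random phonological link — a fixed resolution of a
refill order that admits several readings. The random member is an
edge-permutation null of matching size. Equal node and edge counts make
mean degrees equal by construction (tolerance 0.05 is asserted, ±1 edge).

Spanning connectors are Kruskal forests preferring heavier candidates
(strong semantic links first), ties lexicographic or seeded; on an
unweighted candidate set this is a plain spanning forest per component.

The mixing-fraction sweep builds fixed-size multilayers with
`floor(f·E)` semantic and the rest phonological links. Its spanning
connector is quota-aware: tree edges are accepted from a seeded shuffle of
the merged candidates only while the edge's layer quota lasts, so
connectivity can never spend more of a layer than the mixture allows;
links present in both layers may fill either quota. Unrealizable fractions
are skipped with a warning.

Communities come from networkx's Louvain implementation at resolution
γ (default 1), restarted 5 times with derived seeds, keeping the
highest-modularity partition (Louvain is order-dependent). The inter-link
fraction of an edge set is the share of edges crossing communities; for
uniformly random edges it converges to 1 − Σ_c (n_c/n)².

## Reaction times

`rt_by_path_length` buckets RT word pairs by a network's shortest-path
length 1–4 (longer or disconnected pairs are excluded per iteration) and
averages per-length means over independently rebuilt network variants
(default 5), reporting the across-iteration SD. Degree matching keeps a
spanning connector and adds seeded-random candidates to the target mean
degree (tolerance 0.05); the multilayer variant draws from two pools at a
fixed semantic:phonological ratio (default 80:20), honored within one
link. Only the mean degree is matched — matching full degree distributions
is deliberately out of scope.

The packaged RT comparison is built so that the contrast is identifiable:
reaction times are generated from a ground-truth multiplex (strong
semantic plus phonological links), while the comparison networks are
*estimates* — the semantic estimate dilutes the truth with random semantic
links of any strength (mostly weak and unreliable), the multilayer
estimate swaps 20% of those for phonological links that are part of the
truth. Under a monotone RT–distance relation the network whose length-2
bucket contains truly closer pairs shows the smaller mean RT; if both
comparison networks were exact subgraphs of the truth the inequality would
reverse, so the dilution step is essential, mirroring the random-addition
matching procedure the analysis emulates.

## Synthetic lexicons

The generator produces the statistical structure the analyses assume,
not realistic English:

* **Inventory** — `n_words` (default 500) unique phoneme strings; each new
  word is with probability `mutation_prob` (0.7) a single edit of an
  existing word, otherwise a fresh random string of length 3–6 over an
  8-symbol alphabet. The mutation moves make the edit-distance-1 graph
  clumpy enough to carry a giant component of a few hundred words,
  standing in for real phonotactic regularity.
* **Associations** — every cue receives `50 participants × 3 responses`
  draws. With probability `coupling_rho` a draw is a *signature* response
  keyed to a uniformly chosen member of the cue's closed phonological
  neighborhood — phonological neighbors thereby share high-count responses
  and acquire strong semantic links *through the link estimator itself*,
  never by wiring the semantic graph directly. Otherwise the draw comes
  from one of `n_communities` (4) topic pools of 30 responses, the cue's
  own topic favored by `intra_community_boost` (6): planted semantic
  communities whose internal links are strong. Topics are assigned
  independently of phonology, so `coupling_rho = 0` is an exact null.
* **Reaction times** — pairs balanced over hop distances 1–4 in a
  reference network, RT = 650 + 40·d + N(0, 10²) ms.

What passing tests show, and what they do not: the suite demonstrates that
the estimators recover planted structure (coupling, communities, RT slope)
and stay calibrated under the null at these desk-scale conditions; it does
not certify effect sizes on real association norms, where response
distributions are Zipfian, transcription conventions matter, and the
semantic layer is orders of magnitude larger. Headline quantities from the
full-scale behavioral datasets (e.g. specific mean distances or
millisecond RT differences) are not reproducible from synthetic data and
are not targeted; the pipeline reproduces the *patterns* those quantities
exhibit.

## Problem sizes and defaults

Desk-scale defaults throughout: 500-word lexicons, strength windows of
5,000 links, samples of 100–500 links, 25 resampling iterations, 15–25
link-addition iterations, 5 RT network rebuilds. Full-scale values
(windows of 100,000, samples of 10,000/3,000, 100 iterations) remain
ordinary parameters of the same functions. The acceptance script completes
in well under a minute on one CPU; the test suite in about two minutes.

## Known limitations

* Directed association structure is discarded; multigraphs and weighted
  shortest paths are out of scope.
* The "maximally separable" strength-group layout and the multilayer
  refill order are declared conventions where the construction is
  underdetermined.
* Grapheme-to-phoneme conversion is not provided; transcriptions are an
  input.
* Louvain restarts make partitions reproducible, not canonical — a
  different restart count can pick a different near-optimal partition.
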