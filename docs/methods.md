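# Methods

## Scoring model

`dtifuse` treats DTI prediction as evidence fusion over three independent
channels, each normalized to [0, 1].

**Knowledge-graph channel.** The interaction graph is undirected: curated
drug–gene interaction tables record association, not direction, and
explanatory paths freely alternate drug → gene → drug. Identifiers are
matched exactly after trimming whitespace and case-folding; no synonym
resolution is attempted, because name normalization (trade names, gene
aliases) is a data-preparation concern with no single right answer.
Duplicate edges collapse to one, merging their source-database tags;
self-loops are rejected (dropped with a warning by default, an error on
request). Paths are *simple* paths — cycles would make the path set
infinite — of 1 to `max_hops` edges, default 4; the hop cap is the main
cost/coverage dial and is CLI-overridable. A path is weighted by the mean,
over its edges, of (deg(u) + deg(v)) / (2|V|): paths through well-connected
hub nodes weigh more. The pair score is the maximum over paths of
w(p)/ln(1+|p|) — division, so the score strictly decreases with length at
equal weight — clamped to [0, 1]. A direct edge is special-cased to exactly
1.0, the defined meaning of "direct interaction"; 0 means no endpoint or no
path within the hop budget. Ties among equal-scoring paths resolve to the
fewest hops, then lexicographic node order, so output is deterministic and
seed-free.

Enumeration uses `networkx.all_simple_paths` with a configurable cap
(default 10,000 paths). When the cap is hit the score is a lower bound (the
maximum over a subset) and the evidence record carries a `truncated` flag;
a direct edge is still detected and scored 1.0 because adjacency is checked
independently of the enumeration.

**Literature channel.** The query is the two names joined with the literal
token `interaction`. Indicator matching is case-insensitive plain substring
over title + content (links carry no prose). Substring semantics are
deliberately loose — "strong" matches "strongly" — and both keyword lists
are configurable where that misfires. The pair indicator requires *both*
names. D = round(T/3n, 2) is computed with decimal arithmetic and
round-half-to-even, so the two-decimal grid is exact and platform-stable;
n counts *returned* results, not requested ones. Scoring is pure text
arithmetic: the summary backend can fail (the summary degrades to
"summary unavailable") without touching D.

**ML channel.** The predictor is a pluggable backend. The mock default maps
SHA-256(seed, drug, target) to uniform [0, 1) — a pure, process-stable
function giving a realistic score spread for exercising downstream code.
The lookup backend serves user-supplied scores. The structure-based adapter
wraps a pre-trained binding classifier taking SMILES + protein sequence and
passes its probability-like output through unchanged (no recalibration);
it raises a typed error when the optional dependency is absent and is never
needed offline. Every backend's output is range-checked before it enters
the pipeline.

**Fusion.** The final score is the mean of the channels present, rounded
to five decimals (half to even). Per-channel weights are supported
(default 1, 1, 1); the plain mean is the standard configuration, and
ablations simply drop a channel from the mean. The reasoning trace records
ANALYZE_EVIDENCE (channel scores), EVALUATE_MECHANISMS (only when the
graph channel found an actual path — that is the only mechanistic evidence
available), and CALCULATE_SCORES rendering the arithmetic actually
performed. The prose reasoning is produced by a deterministic template
backend by default; live LLM backends are config labels behind the same
interface and are never exercised in tests.

**Contracts and orchestration.** Inter-stage payloads are validated against
the triple `[drug, target, score]` and the seven-field
`[drug, target, ai, kg, search, final, reasoning]` contracts: arity, types,
finiteness and [0, 1] range, with errors naming the offending position.
Absent channels render as the empty string in the list/CSV form. Batches
are processed in consecutive chunks of `batch_size` (default 10) — the
chunking affects progress and logging only, since no shared-prompt effects
exist offline. Channel failure policy is `skip` (drop the channel, log,
fuse the rest) by default or `fail`; a pair with no surviving channel
becomes an error row with empty scores rather than aborting the batch.
Output CSV is RFC 4180, UTF-8, header
`drug,target,ai_score,kg_score,search_score,final_score,reasoning`, with
`\n` line endings so repeated runs are byte-identical.

## Evaluation

Scores are binarized at a threshold (default 0.5; ≥ counts positive — the
binarization rule is a user choice, not part of the model). Precision is
defined as 0 when nothing is called positive; recall, specificity, AUROC
and AUPRC are NaN when their denominators are empty (single-class labels).
AUROC is the rank statistic and AUPRC the step-wise precision–recall
integral (no interpolation), both via scikit-learn; the test suite checks
AUROC against an O(n²) concordant-pair oracle with half credit for ties.
The repeated-subset harness samples `n_subsets` subsets of `subset_size`
labeled pairs without replacement from a seeded generator and reports
mean ± SD (population SD, so one subset gives SD 0).

## Synthetic fixtures

The fixture generator emulates the two external inputs — a curated
interaction graph and a web-search backend — as pure functions of a seeded
spec, so every test runs offline and byte-reproducibly.

Graphs: pools of `n_drugs` × `n_genes` nodes with background drug–gene
edges at `edge_density` (default 0.15–0.3 in the tests, sparse like real
interaction tables), plus planted relations built exactly: a `direct` pair
gets its edge, a `k_hop:k` pair gets a node-disjoint chain of exactly k
edges, a `none` pair stays disconnected. Background edges never touch
planted nodes, which guarantees the planted shortest-path length and keeps
`none` pairs unreachable — a construction convenience that also means
planted-pair degrees are lower than hub degrees in real graphs.

Search fixtures: for a planted profile (pair_hits, positive_hits,
strong_hits) over n results (default 10, the standard query size), result
i carries both names iff i < pair_hits, one positive keyword iff
i < positive_hits, one strong keyword iff i < strong_hits, embedded in
neutral filler free of names and keywords; T and D are therefore known in
advance. The D = 0.3 fixture uses profile (9, 0, 0); any profile with
T = 9 is equivalent.

What the fixtures do *not* emulate: realistic biomedical prose, the
heavy-tailed degree distributions of curated interaction graphs, synonym
ambiguity, or search-engine ranking noise. Passing tests demonstrate the
arithmetic, contracts and determinism of the pipeline, not predictive
performance on real kinase panels — performance claims require real
graphs, real search results and a real predictor.

The pinned worked example (Vandetanib–MARK2) fixes the three channel
scores at 7.260064194269944e-06 (lookup), 0.7213475204444817 (graph-score
override) and 0.3 (search fixture) and checks the fused output 0.34045.
The graph value cannot be realized by any small constructed graph, so it
enters through an explicit override hook that the configuration layer
refuses outside `test`/`simulate` modes — pinned scores never masquerade
as computed evidence in normal runs.

## Known limitations

- Path enumeration is exponential in dense graphs; the cap turns the score
  into a flagged lower bound rather than an error.
- Substring keyword matching has no tokenization or negation handling
  ("does not bind" still matches "bind").
- The score-fusion mean is not calibrated against labels; the evaluation
  threshold is a user choice.
- Case-insensitive exact identifier matching means unmapped synonyms
  silently score 0 on the graph channel (the reason string says the entry
  was not found).
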