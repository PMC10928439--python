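# Methods

## Pipeline overview

The package implements a supervised complex-detection pipeline on
protein-interaction networks (PINs): (1) augment sparse interactomes
with predicted interactions, (2) integrate networks, (3) featurize
protein pairs, (4) classify edges as within-complex (c-edge) or not
(nc-edge) and use the class probability as the edge weight, producing
the labeled-edge PIN (LE-PIN), (5) detect complexes by a seeded
density+modularity search, (6) evaluate and make downstream calls.

## Interactome augmentation

**WMM.** For a pair observed together `k` times, with per-protein
interaction totals `n` and `m` in a network of `N` interactions, the
score is the hypergeometric upper tail
`P(X ≥ k) = Σ_{i=k}^{min(n,m)} C(n,i)·C(N−n,m−i)/C(N,m)`,
computed via `scipy.stats.hypergeom.sf` (log-space internally, stable at
genome scale). On a simple graph `k ∈ {0,1}`; the evidence container
accepts larger `k` so replicated AP-MS purifications can be scored
(`evidence_from_cooccurrence` builds such evidence from co-occurrence
groups). The selection threshold can be calibrated as the largest
p-value among predicted pairs confirmed by a reference network; when no
prediction is confirmed, a configurable fallback (default 0.05) is used
— the fallback value is a convention, chosen as the usual significance
level.

**L3.** For each non-adjacent pair (X, Y), the score sums
`1/sqrt(deg(U)·deg(V))` over length-3 paths X–U–V–Y. The degree
normalisation follows the original length-3-path formulation;
unnormalised path counts are available via a flag. The operating point
keeps only the strongest few thousand predictions (default `top_k`
6000).

Predicted edges enter the integrated network with a provisional weight
of 1.0. This placeholder is intentional: the LE-PIN step re-weights
every edge, and the CLI workflow orders the steps so detection never
runs on provisional weights.

## Edge features and scaling

Four localization features (overlap, equality, Jaccard, inclusion), five
domain features (overlap, DDI-supported interaction count, union size,
and the two ratios), the absolute chain-length difference, and a GO
semantic-similarity scalar behind a pluggable provider (built-in
fallback: Jaccard over term sets; ontology-aware measures plug in
through the same two-set callable). An optional externally precomputed
sequence-profile block (420 summed profile dimensions plus a Euclidean
distance) is ingested, never computed.

Empty-set conventions: two empty sets are equal (equality = 1) and
mutually inclusive (inclusion = 1); their Jaccard is 0. Missing
annotation blocks are carried as NaN and imputed to 0 after scaling; the
classifier contract receives plain arrays, so imputation is the default
missing-data treatment.

Min–max scaling is fit on the training partition only (to avoid
leakage), transforms clamp to [0, 1], and constant columns map to 0.

## Edge classification

c-edge: both endpoints co-occur in ≥ 1 gold complex. nc-edge: both
endpoints are in the gold universe but never co-occur. Everything else
is unlabeled — excluded from training and metrics but always receiving a
predicted weight.

Because nc-edges dominate, cross-validation uses sub-sampling: c-edges
and nc-edges are split into 10 subsets each; each round trains on the
other nine c-edge subsets plus an equal-size draw from the other nine
nc-edge subsets (exactly 1:1), and tests on all remaining edges. Each
edge's held-out probability is the one from the round in which its own
subset was held out, so aggregate metrics use one prediction per edge.

The default classifier is a LightGBM gradient-boosted tree ensemble
(200 trees, single-threaded, deterministic mode, seeded). Any object
with `fit` / `predict_probability` satisfies the contract; calibrated
probabilities are all the detection stage needs. AUC uses the rank-sum
(Mann–Whitney) formulation with midranks for ties. Degenerate
denominators (no predicted positives; zero MCC denominator) yield 0 with
a warning.

By default the LE-PIN takes model probabilities for every edge,
including training edges, so all edges are treated uniformly; pinning
training edges to 1/0 is available via an argument.

## Complex detection

Score: `F = 1/(1/D + 1/M) + (D + M)/2`, with `M = 1` when d_out = 0 and
d_in > 0 (the limit of the ratio) and `F = 0` for singletons or
zero-internal-weight subgraphs (the search's initialisation value).
F ∈ [0, 1.5] and reaches 1.5 only on an isolated clique of weight-1
edges.

Seeds are ordered by k-shell (topological; weights ignored), ties broken
by ascending node id. Inflate admits a neighbor only if (1) some
incident edge into the subgraph exceeds the c-edge threshold (default
0.5, strict), (2) its link count into the subgraph is at least
`F(SG)·|V_SG|` evaluated on the current subgraph, and (3) F strictly
increases; among the admissible it takes the F-maximising node,
tie-breaking lexicographically. Shrink mirrors this for boundary nodes.

Two deliberate readings of the expected-edges criterion are worth
stating. First, the inequality is `≥` (not strict). Second, the same
criterion applies to shrink removals by default (evaluated against the
remaining subgraph), with a flag (`shrink_requires_eq29=False`) to waive
it; under the default a sparsely linked member can be protected from
removal, which is the literal reading of the criterion.

A structural consequence of the criterion: since a candidate has at most
`|V_SG|` links into the subgraph, no addition can pass once `F > 1` —
growth of very-high-scoring subgraphs self-limits (a unit-weight
5-clique grown from one seed stops at 4 members). On probabilistic edge
weights F rarely exceeds 1 mid-growth, and recovery of planted
complexes at the standard 0.2 matching threshold is unaffected; the
behavior is asserted in the tests rather than smoothed over.

The outer loop alternates inflate and shrink while F improves; nodes
removed by shrink may be re-added in the next round (the candidate pool
is rebuilt). Termination follows from strict F increase and the 1.5
bound. `workers` splits seeds into batches (one–two high-shell seeds, or
larger batches of low-shell seeds, default high-shell cut 20) over a
thread pool; the final canonical sort (descending F, then lexicographic
member list) makes output scheduler-independent. Candidates below
`min_size` (default 2) are dropped and exact duplicates (identical
member sets) removed.

## Evaluation

Matching rate `|P∩G|²/(|P|·|G|)`; threshold 0.2 for a successful match,
1.0 for exact. Recall/Precision/F-measure count matched gold/predicted
complexes; MMR solves the maximum-weight bipartite matching exactly
(`scipy.optimize.linear_sum_assignment`, not greedy) and normalises by
the gold count, with every positive-rate pair as an edge; GACC is the
geometric mean of protein-level sensitivity and positive predictive
value. An empty prediction set gives Precision 0 with a warning.

## Downstream calls

Complexes with score ≥ 0.5 are treated as real (threshold calibratable
as the minimum score among predictions exactly matching an independent
complex set). The limited-overlap set is built greedily in descending
score order, keeping a candidate only if both directional sub-complex
indices (`|CP_i∩CP_j|/|CP_i|`) against every kept complex are strictly
below 0.5 — the symmetric-max rule removes containment in either
direction and is order-deterministic. Proteins in ≥ 2 kept complexes are
called multifunctional. Affected-complex reports flag complexes with ≥ 1
member in an interactor list, note when all members interact, and
annotate drug-target members.

## Synthetic fixtures

The planted-network generator emulates LE-PIN structure: complexes are
cliques with weights from Beta(18, 2) (mean 0.9; below 0.5 with
probability < 1%), background edges appear between complexes with
probability 0.01 and weights from Beta(2, 18) (mean 0.1). Sizes default
to 2–10 weighted toward 2–3-member complexes, matching the small-complex
dominance seen in real atlases. The generator warns when the weight
means fail to straddle the 0.5 threshold (the instance is then
unresolvable by construction). What the fixtures do **not** emulate:
realistic degree distributions, spoke-model bait–prey bias, annotation
sparsity patterns, or overlapping complex architecture beyond a simple
shared-member option — so passing tests demonstrate algorithmic
correctness on separable instances, not performance on real
interactomes.

The feature generator draws class-conditional Gaussians in [0, 1]
(noise SD 0.1) whose means differ by `separation` noise-SDs in a few
informative slots; `separation=0` is an exact null, `separation≥5` is
near-separable.

## Problem sizes

The bundled checks use networks of roughly 80–100 proteins (20 planted
complexes), 2000 labeled edges for cross-validation, and exhaustive
hypergeometric enumeration up to N = 12 — sizes chosen so the entire
suite re-runs in seconds while still exercising every code path at
scales where brute-force oracles are feasible. All generators and the
classifier are seeded; repeated runs are bit-identical.

## Known limitations

- The sequence-profile feature block is ingest-only; producing it
  requires an external profile search pipeline.
- GO similarity defaults to set Jaccard; ontology-graph measures require
  a user-supplied provider.
- Duplicate removal is exact-match only; near-duplicate merging is out
  of scope.
- The expected-edges growth cap discussed above means maximal cliques of
  near-unit weight may be reported slightly short of complete.
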