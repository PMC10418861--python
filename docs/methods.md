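# Methods

## Scope and model

hetepath implements relevance ranking on a *heterogeneous information
network* whose nodes are typed biomedical concepts and whose edges are
directed predications with aggregated sentence-support counts. Three layers
sit on top of the graph: metapath machinery (enumeration, path counting,
degree-weighted path counts), HeteSim scoring, and the layered
simulation/hub-analysis pipeline that produces a final ranked candidate
table.

## HeteSim: definition and conventions

For a metapath `P = s_0 -r_1- s_1 - ... -r_L- s_L`, each step contributes a
row-stochastic transition operator: unweighted by default (uniform over
out-neighbors along the step's predicate and direction), optionally
weighted by support counts. The score between `s` (type `s_0`) and `t`
(type `s_L`) is the cosine similarity of the two probability distributions
obtained by propagating a unit mass from `s` through the first `⌊L/2⌋`
operators and from `t` through the reversed (transposed, re-normalized)
last operators. For odd `L` the middle step's edges are materialized as
instance nodes and each side takes a final half-step onto them.

Conventions fixed here:

* **Walk semantics.** The matrix formulation counts walks, not simple
  paths; the brute-force oracle therefore also enumerates walks. The path
  counting and DWPC operations default to *simple-path* semantics (an
  `allow_revisits` flag switches to walks, which is what the vectorized
  simulation scoring uses) because back-and-forth revisits inflate
  length-3+ counts meaninglessly.
* **Zero-vector rule.** If either side cannot reach the midpoint the score
  is 0, not undefined — ranking needs a total order. Both endpoints of the
  [0, 1] interval are attainable (0 unreachable, 1 identical midpoint
  distributions).
* **Aggregation.** A candidate's score against a target is the arithmetic
  mean of its per-metapath scores over *all* enumerated metapaths, with 0
  for metapaths whose source type does not match the candidate; every
  candidate of a simulation therefore shares one denominator and the mean
  is comparable across candidates. Multi-target scores average the
  per-target means.
* **Tolerances.** Row-stochastic rows sum to 1 within 1e−12; the matrix and
  walk-oracle implementations must agree within 1e−9 (tested on hundreds of
  seeded random graphs).
* **Determinism.** All node and metapath orderings are lexicographic; ties
  in every ranking break lexicographically by CUI. Identical inputs give
  byte-identical outputs.

## DWPC

`dwpc(s, t, P, w)` sums over path instances the product of
`degree(v)^(−w)` over all nodes on the instance, *endpoints included* —
including the endpoints penalizes promiscuous candidate drugs, the very
confound the decoy analysis targets. `w = 0` reduces exactly to the path
count. The simulation layer exposes `scoring="dwpc"` (default damping
`w = 0.4`, a mid-range value between no damping and the aggressive
`w = 1`), computed with damped adjacency products so whole candidate sets
score in one pass.

## Simulations, hubs and the final ranking

A simulation fixes targets, allowed source types, and a maximum metapath
length (default 3, hard cap 4 — short metapaths carry the interpretable
semantics and keep enumeration exact at desk scale). Scores are min-max
normalized per simulation (all-equal scores map to 1.0), which is the only
thing that makes scores comparable across simulations run on different
targets.

The layered pipeline: (1) preliminary simulations against the primary
targets; (2) hub selection — sources with normalized score ≥ 0.2 (the
threshold also used for all later passing tests), capped at 14, optionally
restricted by semantic type; "highly ranked" is operationalized as
threshold + cap rather than per-type quotas; (3) one simulation per hub
with the hub as target; (4) cross-evaluation: the candidate × hub matrix of
passing normalized scores, with per-candidate recurrence and mean; (5)
back-evaluation of a designated candidate (in which hubs does it pass?);
(6) final ranking of drug-like candidates (PHSU/CLND by default) sorted by
recurrence across all layers first and mean passing score second —
recurrence dominates because reappearance across independent searches is
stronger evidence than a single high score. Two layers are the default;
the orchestration composes for deeper designs.

Rank aggregation is available in two forms: transparent mean-rank (absent
candidates imputed at list length + 1) and an unsupervised iteratively
reweighted scheme — ranker weights start uniform, the consensus is the
weighted mean of normalized ranks, and each ranker's weight is reset to the
inverse of its mean squared deviation from the consensus until convergence
(1e−6, max 100 iterations). With one ranker it reduces to that ranker;
a single adversarially inverted ranker is down-weighted.

## The synthetic generator

Real predication databases are licensed and orders of magnitude beyond desk
scale, so the generator emulates the features that matter to the method:

* ~520 typed nodes (PHSU 200, GNGM 100, AAPP 100, CLND 50, DSYN 40,
  TOPP 30) with synthetic CUIs in the reserved C9xxxxxx range;
* a schema-constrained background of 800 predications sampled with
  preferential attachment (skew exponent 1.0), giving a long-tailed degree
  distribution (max degree ≥ 3× median);
* one disease target, one standard-of-care drug (TREATS the target), and 3
  planted adjuvant drugs, each connected to the target through 4 concrete
  instances across 3 metapath families: shared disease genes
  (AFFECTS→GNGM→ASSOCIATED_WITH), interaction with the standard drug
  (INTERACTS_WITH→PHSU→TREATS), and a comorbidity
  (TREATS→DSYN→COEXISTS_WITH). Planted hub genes carry both
  ASSOCIATED_WITH and CAUSES edges to the target, like well-studied disease
  genes;
* 5 popular decoy drugs wired to ≥ 95th-percentile degree while avoiding
  every planted-family endpoint (their planted-family instance count is 0).

Planted drugs, decoys and planted hubs are excluded from the background
edge pool so the planted signal is exactly what was planted. The background
density was chosen to reproduce the sparsity regime the method actually
operates in: at desk scale a dense background (e.g. 2500 edges on 520
nodes) makes every disease share treating drugs with every other, score
distributions flatten, half the candidates pass the 0.2 threshold in every
hub simulation, and recurrence — the pipeline's main signal — saturates.
At 800 background edges most candidate–hub pairs share no short metapath
and score 0, which is how a realistically sparse predication graph behaves.

What passing tests show — and what they do not: the recovery experiment
(20 seeds, two-layer pipeline, targets = disease + standard drug)
demonstrates that the pipeline retrieves *planted* multi-family literature
signal and resists high-degree decoys; it says nothing about extraction
noise, synonymy/CUI normalization errors, citation bias, or negation —
none of which the generator models. Generation is at the predication
level; no text is simulated.

## Numerical and degenerate-input choices

* Empty score lists, empty metapath lists, zero rankings, sub-2 hub sets
  for cross-evaluation: precondition errors.
* Relations with zero edges produce all-zero operators plus a logged
  warning; missing semtypes are errors.
* The brute-force oracle refuses graphs needing more than 10⁶ walk
  extensions rather than silently grinding.
* All-equal raw scores normalize to 1.0 (everything is equally, maximally
  relevant relative to this simulation).
* A hub simulation whose hub is missing from the graph is recorded and
  skipped; the other hubs proceed.

## Problem sizes used by the test suite and acceptance script

Oracle agreement: 200 random graphs of ≤ 50 nodes. Property suites: seeded
random graphs of 15–30 nodes. Recovery: 20 seeds at the default generator
config (plus 20 DWPC-corrected and 5 negative-control runs). These sizes
keep enumeration exact while exercising every code path; the pipeline
itself has no size-dependent switches.

## Known limitations

* Exact enumeration only; no sampling or approximation, so metapath length
  is capped at 4 and very dense graphs are out of scope by design.
* Support-count weighting is implemented but off by default: all sources
  are treated equally, and no quality or citation weighting exists.
* The final ranking's recurrence criterion is threshold-sensitive;
  monotonicity in the threshold is tested, but the 0.2 default is a
  convention, not an estimate.
* Literature validation of ranked candidates is human work; the package
  ranks, it does not read.
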