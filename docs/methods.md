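# Methods

## Problem and model

`nwsteiner` solves the node-weighted Steiner tree problem on protein–protein
interaction (PPI) networks: given a connected undirected graph
`G = (V, E, w, c)` with positive edge costs, real node weights and a
compulsory terminal set `T`, find a tree `G′ ⊇ T` minimizing
`Σ c(e) − Σ w(v)` over its edges and vertices. Terminals carry a `REQUIRED`
sentinel rather than a floating `+∞`: the infinite reward of a compulsory
protein is a constraint, not a number, so no arithmetic is ever performed on
it and the reported objective (which drops terminal weights — every compared
solution contains `T`, so rankings are unaffected) stays finite.

Instances are generated from confidence-scored interaction records.
Self-loops are dropped, duplicate edges collapse to the minimum cost (the
most confident evidence wins), and vertex degrees for the node-weight formula
are taken on the full cleaned network, never after reductions — a protein's
penalty reflects its connectivity in the data, not in a shrunken artifact.
If the network is disconnected, the instance is restricted to the component
holding the terminals; terminals spanning components are infeasible.

## Parameters

| parameter | default | meaning |
|---|---|---|
| α | 2·10⁶ | edge-cost numerator; pure scale, chosen so costs from typical experimental scores (≈80–140) land around 100–300 |
| β | 2 | edge-cost exponent; larger β spreads costs apart, expressing more trust in score differences |
| γ | 5 | node-penalty scale; non-terminal `i` costs `γ/degree(i)` to include, balancing exclusion of unrelated proteins against discovery of new ones |
| boost | 0.5 | fractional confidence increase for interactions already inside the annotated pathway, applied before the cost transform and without clamping the score to any nominal maximum |
| s | 2 | edge splitting ratio; the edge's slack is shared 1:(s−1) between its two parts (ordered lexicographically by protein identifier), s = 2 giving the even split |
| μ | 10⁻⁶ × mean edge cost | merge tolerance of the growing phase; a remaining partner slack below μ triggers the merge instead of another re-split, bounding the re-splitting cascade that cluster activity flips can cause |
| threshold | max(\|S∩V′\|, \|T′∩V′\|) | automatic selection cutoff for betweenness degrees; selection is strict (`B > threshold`) |

`s` and `μ` have no published values; the even split is the symmetric default
and μ is small enough (six orders below a typical cost) that it only resolves
degenerate re-split loops, never ordinary merges.

## Preprocessing

Two degree-1 tests shrink instances while preserving the optimum. With
`|T| ≥ 2`, the single edge at a degree-1 terminal is forced into the optimum;
the terminal is removed and its neighbor inherits terminal status (standard
Steiner contraction; what happens after forcing is a design choice — the
alternative of leaving the terminal in place forgoes further reductions).
With `|T| ≥ 1`, a degree-1 non-terminal `i` with `w(i) ≤ c(i,j)` can never
pay for its own attachment and is deleted. Both tests run to a fixpoint by
default because each removal can expose new degree-1 vertices; fixpointing
strictly dominates a single sweep in reduction power at negligible cost, and
`single_pass=True` preserves the literal one-sweep behaviour for comparison.
The ledger records forced edges, removals and promotions; its
`objective_offset` (forced edge costs minus the finite weights of promoted
vertices) relates reduced and original optima exactly, which the test suite
verifies against an exhaustive oracle.

## Growing phase

Each vertex starts as a cluster with slack equal to its node weight; clusters
with nonpositive slack are born inactive (this is the modification that
admits negative weights), and terminal clusters never deactivate. Each edge
is split into two parts holding `c/s` and `(s−1)c/s` of its cost. A global
clock advances from event to event: a cluster event deactivates a cluster
whose slack ran out; an edge event fires when an active part's slack is
exhausted. With `r` the partner part's remaining slack: `r < μ` merges the
two clusters (slacks add, so a merged cluster can be born inactive — its
deactivation time is then the merge time); otherwise the times re-split —
evenly when the partner's cluster is active, or the full `r` onto the active
side when the partner is frozen (the partner part's time is pinned to its
cluster's deactivation time, encoding zero remaining slack). Parts of a
frozen cluster that joins an active one have their event times shifted by
the time spent frozen. The loop ends with at most one active cluster; the
merge edges inside it (or inside the latest-deactivated cluster when none
remains — the tie-break the zero-active case needs but the construction does
not dictate) form the raw tree. Event queues break ties by insertion order,
and edge events are processed before cluster events at equal times, so runs
are deterministic.

## Pruning and reassembly

Strong pruning roots the raw tree at a compulsory terminal chosen by a seeded
RNG (the only randomness in the pipeline) and processes vertices leaves-in:
a subtree whose accumulated reward `nw(i)` cannot pay for its connecting edge
(`c(i,j) > nw(i)`) is cut, otherwise the parent absorbs `nw(i) − c(i,j)`.
Terminal-bearing branches hold `nw = +∞` (safe here: only `∞ ± finite`
arises) and are never cut, so when every non-terminal weight is negative —
as in any instance built with γ > 0 — every leaf of the final tree is a
compulsory terminal. Finally the forced edges recorded by preprocessing are
re-attached in reverse forcing order, restoring every original terminal.

## Betweenness degrees and selection

On the identified tree the path between any two vertices is unique, so
betweenness degrees are integer counts: protein `m` (interaction `e`) scores
one for every ordered pair `(i, j) ∈ S × T′`, `i ≠ j`, whose path contains it,
endpoints included — endpoint inclusion is the only reading consistent with
leaf terminals scoring exactly `|S|`. A protein that is both source and
terminal contributes its `(i, i)` pair to the vertex only. The main
implementation counts combinatorially (deleting an element and multiplying
source/terminal counts across the resulting components); an independent
per-pair path-walking oracle cross-checks it on random trees and on the
shipped subnetwork. `B(m) ≥ B(e_mn)` holds for every incident pair since a
path through an edge visits both endpoints. When the tree misses some
sources or terminals, only those present are counted.

## Shipped subnetwork and its labeling

The package ships the published 29-protein, 28-interaction PI3K/Akt + MAPK
subnetwork with its betweenness tables. The 8-source/14-terminal labeling
(receptor tyrosine kinases PDGFRα/β, IGF1R, ERBB2, INSRR, FGFR1/2, HER1 as
sources; p53, RELA, NF-κB, p27, p21, LEF1, TCF7L1/TCF7/TCF7L2, AR, BAD,
Caspase9, mTOR, FOXO1 as terminals) is shipped as data and verified by a
regeneration test that recomputes all 57 betweenness values from it.
Identifiers are ASCII-safe (`beta-catenin`, `IkBa`, `NF-kB`, `PDGFRa/b`) with
a display-name map restoring the Greek typography. The confidence scores in
`fixture_as_inputs` are synthetic placeholders (no scores are published for
these edges); they exist so the full pipeline can run on the fixture.

## Synthetic generator

`synth_instance` emulates small PPI-like inputs: a preferential-attachment
spanning tree plus degree-biased extra edges (connected, right-skewed degree
distribution), confidence scores from a normal distribution (mean 110,
sd 25, clipped to [30, 400]) so default-parameter costs land around 100–300,
and a planted connected pathway whose edges are flagged as members and whose
vertices supply the sources and terminals (about a third each by default).
It does not emulate assortativity, clustering coefficients, score–degree
correlations or the heavy multi-evidence structure of real interaction
databases, so passing tests demonstrate algorithmic correctness on
realistic scales and score ranges, not biological fidelity.

Test and acceptance suites use 9-vertex/14-edge instances (where exhaustive
enumeration over all vertex subsets is exact and instant) and the 29-protein
subnetwork; the CLI tests use 40-vertex instances.

## Numerical choices

Edge keys are canonical lexicographic pairs; the `i < j` of the splitting
rule is lexicographic on protein identifiers. Event-time comparisons are
exact float comparisons against stored values (stale heap entries are
recognized by value change, not tolerance). The brute-force Steiner oracle
breaks objective ties by first discovery over a deterministic enumeration
order and refuses instances above 12 vertices. With no terminals the solver
warns and returns the empty tree, matching the oracle's "best
nonnegative-reward subtree or nothing" convention of value 0.

## Known limitations

- The growing phase is blind to interior node weights on routes between two
  always-active terminal clusters: weights enter only through cluster
  activity, and a terminal cluster's activity dominates any negative summand
  at a merge. A heavily penalized junction protein on a short route is
  therefore not avoided (strong pruning cannot remove interior vertices), and
  the heuristic can return objectives above the optimum — on the shipped
  random suite it attains the exhaustive optimum on most but not all
  instances, and the test suite asserts exactly that behaviour. With the
  default γ = 5 against costs of order 100–300, penalties are small and the
  effect on realistic instances is minor.
- The approximation-factor band (≤ 2× the optimum) is asserted on the random
  suite as an empirical sanity band, not proven for this node-weighted
  variant.
- No sophisticated reductions (bottleneck Steiner distances, special-vertex
  tests) and no exact solver beyond the 12-vertex oracle; no rooted variant.
- Full-database clients (interaction/pathway download, gene→protein mapping)
  are out of scope; generic delimited-text readers stand in.
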