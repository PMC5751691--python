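# nwsteiner

Identification of important elements of cancer-related signaling pathways in
protein–protein interaction (PPI) networks by the node-weighted Steiner tree
approach.

## The problem

Signaling pathways such as PI3K/Akt and MAPK drive tumorigenesis, but the
curated pathway maps are incomplete: evidence for unknown members may exist in
large interaction databases without being recorded in any pathway. Given a
confidence-scored PPI network and a set of proteins known to be important to
cancer signal transduction (receptor tyrosine kinases where the signal enters,
downstream effectors where it ends), the task is to extract a small, credible
subnetwork connecting all of them — fast enough to run on networks with
millions of interactions — and then to rank its proteins and interactions by
how central they are to source→terminal signal flow.

`nwsteiner` is for computational biologists who want this pipeline on their own
interaction data, and for algorithm developers who want a tested, readable
implementation of the underlying node-weighted Steiner machinery.

## The model

A node-weighted PPI network is a connected graph `G = (V, E, w, c)` with a
compulsory terminal set `T ⊆ V`. For an interaction with experimental
confidence score `con`,

```
c(i,j) = α / con^β                 (α = 2·10⁶, β = 2 by default)
```

so credible interactions are cheap; interactions already inside the pathway of
interest get their score boosted by 50 % before the transform. Node weights are

```
w(i) = −γ / degree(i)   if i ∉ T   (γ = 5 by default)
w(i) = +∞               if i ∈ T   (the REQUIRED sentinel)
```

— a connectivity-scaled penalty for junction proteins, a hard inclusion
constraint for terminals. The identified subnetwork is a tree `G′` containing
`T` that (approximately) minimizes

```
c(G′) = Σ_{e∈E′} c(e) − Σ_{v∈V′} w(v).
```

The solver is a modified unrooted Goemans–Williamson moat-growing algorithm
with dynamic edge splitting (split ratio `1:(s−1)`, merge tolerance `μ`),
adapted to negative node weights (merged clusters may be born inactive),
followed by strong pruning. Two optimum-preserving degree-1 reduction tests
shrink the instance first. On the identified tree, the **betweenness degree**
of a protein `m` (interaction `e`) counts the source–terminal pairs
`(i,j) ∈ S × T′` whose unique tree path contains `m` (`e`); elements scoring
strictly above `max(|S|, |T′|)` are selected as important. See
`docs/methods.md` for the full account.

## Worked example

The package ships the published 29-protein PI3K/Akt + MAPK subnetwork as a
ready-made input set:

```
$ nwsteiner fixture --outdir demo
$ nwsteiner run --interactions demo/interactions.tsv \
                --annotation demo/annotation.yaml --outdir demo/out --seed 1
[build] 29 vertices, 28 edges, 22 terminals
[preprocess] 29->1 vertices, 28->0 edges
[solve] tree with 29 vertices, objective 2499.0972
[metrics] threshold 14: 9 proteins, 8 interactions selected
```

The build stage turns the edge list into a node-weighted instance with the 22
compulsory terminals (8 sources + 14 terminal effectors). Because every leaf
of this input is compulsory, the degree-1 tests contract the whole instance to
a single vertex — the solver's reassembly then restores the full 29-vertex
tree, whose objective is the summed edge costs minus the junction-protein
weights. The metrics stage scores every element:

```
$ head -6 demo/out/node_betweenness.tsv
protein	betweenness	selected
AKT1	112	1
PIK3R1	112	1
MDM2	64	1
p53	64	1
EP300	56	1
```

AKT1 and PIK3R1 lie on every one of the 8 × 14 = 112 source→terminal paths —
the maximum attainable — marking them as the core relay of the pathway. With
the automatic threshold `max(8, 14) = 14`, 9 proteins and 8 interactions are
selected (receptors scoring exactly 14 are deliberately excluded by the strict
inequality). Subcommands `build`, `preprocess`, `solve`, `metrics`, `sweep`
and the library API (`nwsteiner.build_instance`, `solve`, `betweenness`, …)
expose each stage separately; `nwsteiner.fixtures.synth_instance` generates
synthetic PPI-like instances for experimentation.

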