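# Methods

## Model

The package treats a mixed directed/undirected gene interaction graph as a
Markov chain whose transition probabilities are biased by per-gene data.
For node *i* with downstream neighbor set *N_i* (undirected edges are
bidirectional), the walker moves to *j* ∈ *N_i* with probability
`p_ij = w_j / Σ_{k∈N_i} w_k`, where `w` holds strictly positive ratio
values (1 = no change). A node with no downstream neighbors is *dangling*
and jumps uniformly to any of the *n* nodes. With per-step restart
probability `q` and restart distribution `r`, the stationary visitation
vector solves

    g = (1 − q) · g P + q · r ,        r_i = w_i / Σ_k w_k  (biased restart)

For `q > 0` and `r > 0` everywhere the chain is ergodic and the fixed point
unique. Visitation mixes three signals: a node's own value (via the restart
and its neighbors' transitions into it), its neighbors' values, and local
connectivity — which is the point: genes with moderate values embedded in a
coherent neighborhood outscore isolated extreme genes.

Raw `g` still correlates strongly with degree on hub-rich (scale-free)
interactomes. A background run with `w ≡ 1` and the same `q` isolates that
topological component as `g_r`; the reported node score is `g′ = g / g_r`.
Because the background is computed by the identical code path, uniform
input data reproduces it exactly (`g′ ≡ 1` to machine precision).

Interactions are scored by the stationary flux `e_ij = g_i · p_ij` (for an
undirected edge both arc fluxes are computed and summed for reporting;
per-arc values are retained in the table). The flux of the background run
normalizes it:

    s_ij = log2(e_ij / e_r,ij)

`s` is centered at 0; the log base is configurable but base 2 follows
gene-expression convention. Flux leaving dangling rows corresponds to no
real interaction; it is excluded from the edge table but tracked so that
total flux (edges + dangling mass) sums to 1 exactly.

Transcription factor→target edges are reversed before the walk so that
target-gene expression feeds the regulator's score (mRNA changes of targets
are evidence about TF activity, not vice versa). The reversal is applied
once, inside the pipeline entry point.

## Preprocessing

* **Winsorization** (on by default): values above the 99.9th percentile of
  the observed data are clipped to it, likewise below the 0.1th percentile.
  Percentiles use linear interpolation between order statistics and are
  computed before imputation so imputed 1s cannot distort the tails.
* **Imputation**: network genes absent from the data vector get exactly 1;
  data genes absent from the network are dropped with a logged count.
* Non-positive input values are rejected (the transition model requires
  `w > 0`); a permissive reader flag downgrades them to missing.

## Functional-similarity edges

Two genes are linked (undirected, type FS) when their annotation overlap is
unlikely by chance. For shared term set *N*, with *G_k* the carriers of
term *k* and *n* the gene universe,

    s_ij = Π_{k∈N} |G_k| (|G_k| − 1) / ( n (n − 1) )

— under independence across terms, the probability that a uniformly random
ordered gene pair carries every shared term. A term carried by all genes
contributes factor 1 (uninformative); the edge rule is `s_ij < 0.001`.
This overlap score is distinct from the Edge Flux score despite the shared
letter. Additionally, any two genes co-annotated to the same *metabolic*
pathway are linked directly (signaling pathways are excluded — they are
already present as directed interactions). The universe size defaults to
the number of annotated genes and is configurable, since the right universe
depends on the annotation source. Annotations are used flat, as supplied;
no ontology-graph propagation is performed.

## Numerical choices

* Power iteration from the uniform start, L1 stopping tolerance `1e-12`,
  cap 10,000 iterations; non-convergence returns a flagged result with a
  warning rather than raising. The returned vector is renormalized to sum
  exactly 1 to absorb accumulated round-off.
* The sparse matrix stores only real arcs; dangling rows are a rank-one
  correction applied during each multiply, so memory stays O(arcs).
* `q = 0` is allowed but warned about when the graph is not strongly
  connected (the limit may then depend on the start).
* A dense direct solve of `g (I − (1−q)P) = q·r` is shipped as an
  independent reference for small problems and is used by the tests to
  verify the iterative solver to 1e-10 in sup norm.
* Subnetwork extraction sorts by score with lexicographic
  (source, target, itype) tie-breaking, so results are reproducible and
  independent of table row order.
* Ward clustering (scipy, Euclidean) operates on raw `s` profiles of the
  union of per-condition top-k and bottom-k edges; no standardization is
  applied. "Extreme edges per condition" is a deliberate formalization of
  selecting each condition's highest and lowest scores; k is a parameter.

## Synthetic data

The generators exist so every claim is testable without proprietary
interactome snapshots or microarray raw data.

* **Toy network** (`make_toy_network`): 12 nodes, 28 undirected PPI edges
  kept in a single constant: a high-value pendant node A (w=5), a value-1
  background mesh B–F, and a 6-cycle cluster G–L (w=2) bridged to the mesh.
  Tests against it assert rankings, never exact values, so the particular
  wiring cannot anchor wrong numbers.
* **Planted benchmark** (`make_planted_fixture`): a Barabási–Albert
  background (hub-rich, as real interactomes are — defaults n = 1000,
  attachment m = 2) with two disjoint 25-node cliques planted on it.
  Log2 ratios are Normal(log2 4, 0.25) in the high module, Normal(log2 0.25,
  0.25) in the low module, Normal(0, 0.25) in the background, exponentiated
  to ratios. Modules can be switched off per condition for clustering
  experiments. Effect size 4× with 0.25 log2-noise is a strong but
  realistic coherent expression program; cliques emulate densely
  interconnected processes.
* **Annotation fixture**: planted functional modules share 3 exclusive
  terms each; background terms are carried by roughly half the universe so
  they stay individually and jointly uninformative at the 0.001 threshold.

What the generators do **not** emulate: measurement noise structure of real
microarrays (probe effects, intensity-dependent variance), incomplete and
biased interactome coverage, correlated expression outside planted modules,
and literature-driven degree bias coupled to data. Passing recovery tests
therefore demonstrates correctness of the algorithm under its own model of
coherent modules, not performance guarantees on real data.

## Robustness experiments

Perturb one input, rerun, and compare to the unperturbed run: data deletion
(values reset to 1, i.e. made missing), node deletion, edge deletion, edge
addition, and data-range re-expansion `σ_i = f^(log2 w_i)` (f = 2 is the
identity; f = 1.25 compresses, f = 5 stretches the dynamic range while
preserving ranks). Agreement is Spearman's ρ of `g′` over nodes present in
both runs — rank correlation, since the scores' use is ordinal — except for
the range transform, where the reported quantity is the node overlap of the
top-k edge networks. All replicates are seeded from (seed, kind, level,
replicate), so tables regenerate exactly.

Problem sizes: the robustness and recovery experiments run on the n = 1000
planted fixture; the sparsity demonstration runs a 14,506-node, ~190,000-
edge network (attachment m = 13), which converges in a few seconds on one
CPU.

## Known limitations

* No significance calibration of `s`: scores are relative, and cutoffs are
  a user choice by design.
* The stationary solver assumes `q > 0` in practice; exotic chains at
  `q = 0` (periodic, reducible) only get a warning.
* Edge records of different interaction types between the same pair share
  one transition probability — the walker sees adjacency, while reporting
  stays per typed record.
* Identifier mapping between annotation sources is out of scope; gene IDs
  are opaque strings and must already agree across inputs.
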