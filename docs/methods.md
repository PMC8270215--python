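# Methods

## Model and assumptions

The package rests on two network-medicine premises: genes whose products
interact tend to participate in the same biological processes, and disease
genes cluster into connected modules of the interactome. A drug target's
therapeutic reach is therefore approximated by the *target subnetwork* —
the region of the interactome most strongly coupled to the target — and a
disease by its *disease module*; a disease is a plausible indication when
the two node sets overlap more than chance allows.

All statistics treat the interactome as a fixed, undirected, unweighted
graph: edge confidences are used only to filter edges (strictly greater
than the threshold, 0.7 by default on STRING's [0,1] scale), never as
distances or propagation weights, because the degree normalisation and the
hypergeometric tests are defined on the binary adjacency. The whole
filtered graph is kept — there is no largest-component restriction;
propagation assigns exactly zero flow to components without a seed and the
proximity measures exclude unreachable pairs with a logged count.

## Target subnetwork (flow propagation)

`F^t = α·A′·F^{t−1} + (1−α)·F^0`, with `A′ = D^{−1/2} A D^{−1/2}`.
The symmetric degree normalisation is one concrete reading of
"normalised by the degrees of the source and target nodes"; it is chosen
because it bounds the spectral radius of `A′` by 1 (guaranteeing a unique
fixed point for any α < 1) and makes the uniform vector a fixed point on
regular graphs, which the tests exploit.

Parameters:

* **α (retention), default 0.5, range (0,1).** The fraction of flow that
  keeps diffusing each step; 1−α is re-injected at the targets. Larger α
  extends the smoothing radius. No standard value attaches to this
  workflow, so the middle of the admissible range is the default and the
  value is exposed everywhere. Sensitivity is mild at desk scale: the
  top-k membership, not the exact scores, is what downstream stages use.
* **tolerance, default 10⁻⁶ (L1).** The iterate is then within
  α/(1−α)·10⁻⁶ of the fixed point. The oracle-equivalence test tightens
  this to 10⁻⁹ so the comparison against the closed-form solve is bounded
  by 10⁻⁶.
* **top_k, default 200** non-target nodes, after which (by default) all
  direct neighbors of the selection are added ("their direct
  interactomes"); the neighbor closure reads "neighbors of targets and of
  the top-k", the superset interpretation. Ties at the cutoff break
  lexicographically so runs are deterministic.

`propagate_exact` solves `(I − αA′)F = (1−α)F^0` densely (guarded to
≤ 2,000 nodes) and exists purely as an independent oracle.

Multiple targets are first-class: every target gets `F^0 = 1`, which is
how target combinations are analysed.

A note on determinism: the computation is fully deterministic, so
repeating a run and averaging — sometimes done with propagation tooling —
is a no-op here.

## Disease modules (connectivity expansion)

Growth starts from the disease's associated genes present in the network
(absent seeds are dropped with a warning, matching the catalog policy).
Each round, for every outside node with at least one edge into the module,
the upper-tail hypergeometric probability of its `k_s` links into the
current set is computed with population = all nodes except the candidate,
successes = current set, draws = candidate degree; the smallest-p node is
added, ties broken lexicographically. This is the plain hypergeometric
form without the seed-weighting extension of the original module-detection
literature. Iterations default to 200 — the putative size of a complete
disease module at interactome scale — and are configurable (the classical
sweep {100, 150, 200, 250, 300} is one flag away). Candidate link counts
are updated incrementally; tests verify the trace equals a naive
rescan-everything implementation.

## Enrichment, adjustment, metric

The overlap universe is the full filtered network's node count — both
subnetworks are drawn from it. Holm's step-down adjustment (via
statsmodels) is reported in the `fdr` column; by default the *raw*
p-value feeds the metric `Pval/log₂(N+1)` (the adjusted value is an
option), because the metric's N-adjustment and the familywise correction
serve different purposes and stacking them double-penalises small
families. `N` is the disease's surviving seed-gene count. The `Pval = 1`
branch returns exactly 1 so completely unenriched diseases share the
bottom of the list regardless of N. Final ties (equal metric) break by
raw p, then disease id. MeSH deduplication — keep the best-ranked entry
per MeSH id, re-rank densely, recompute 1/rank — runs last.

The weighted variant implements "each disease associated gene is
considered as two nodes" concretely: disease draw += |seeds|, overlap +=
|target ∩ seeds|, universe += |seeds|. This is one reading of the
duplication; it reduces exactly to the plain test when a disease has no
designated seeds and is isolated behind the `variant` switch so
alternative readings are one function away.

## Baselines

* **Genetic association:** diseases sorted by their association score for
  the target, descending; absent associations score 0. Combinations use
  the max over targets (only single-target use is classically described;
  max is the natural "any target is genetically implicated" reading).
* **Proximity:** closest, shortest, and kernel distances on unweighted
  hop counts; the kernel uses the Guney et al. form
  `−(1/|T|) Σ_t ln[(1/|S|) Σ_s e^{−(d(s,t)+1)}]`. Significance is a
  z-score against `n_random` (default 1,000) random gene sets matched to
  the disease genes' degrees by degree-binned sampling (bins widened to a
  minimum of 100 candidates, following the proximity literature); ranking
  is by z ascending, with raw distances reported alongside.

## Evaluation

AUROC is the rank-based probability that a random positive outranks a
random negative (midrank ties), equivalent to sweeping a threshold down
the ranking; it is validated against exhaustive pair counting and
scikit-learn. Sensitivity at a top-k% threshold uses a ceiling cut so
small lists keep a non-empty top bin; the six conventional thresholds
5–30% are reported, and a recommended shortlist flag marks the top 15%.
An optional FDR < 0.05 filter restricts which recovered positives count.
The random-target background reruns the entire ranking pipeline for
targets sampled from a druggable pool (default: all nodes, since curated
druggable-gene lists are licensed) and reports their AUROCs.

## Synthetic benchmarks

The generator emulates the *structural* features the method relies on and
nothing more: scale-free topology (preferential attachment, heavy-tailed
degrees), connected disease modules denser than the background
(random-walk node sets densified with extra intra-module edges at
probability 0.3), genetic seeds forming each module's first-discovered
core with scores uniform(0.3, 1.0), and a target whose true indications
have modules concentrated around it. Concretely, a positive disease's
module is grown by a random walk rooted at the target with restart
probability equal to the `overlap` parameter (0.8 by default), so higher
overlap plants the module tighter around the target; `overlap = 0`
plants positives exactly like negatives — rooted at nodes ≥ 3 hops from
the target, never touching the target or its direct neighbors — which
removes the signal and is the null construction. A positive disease lists
the target itself among its associated genes with probability 0.5
(`target_seed_prob`), because in reality approved indications often lack
a direct genetic link to the target; this keeps the genetic baseline
informative but imperfect.

Defaults: 500 nodes, attachment 3, 10 diseases (1 positive), module size
20, seed fraction 0.5. What the benchmarks do **not** emulate: STRING's
empirical degree distribution, DisGeNET's disease-size spectrum,
annotation noise, and ascertainment bias. Passing tests therefore show
the pipeline recovers planted topological signal and that its statistics
are exact — not that real-data performance will match.

At this scale the analysis settings are scaled analogues of the
interactome-scale defaults: top_k = 50 (10% of nodes) with the neighbor
closure off (on a 500-node scale-free graph the 1-hop closure of 50 nodes
covers most of the graph and washes out specificity), module iterations =
20 (one planted-module-size of growth beyond the seeds), and a
random-target background of 10 targets per replicate. These sizes — and
the 10-replicate studies in the tests and the acceptance script — are the
package's chosen problem sizes for seconds-scale, fully reproducible
runs; the null-band check uses 20 replicates because the per-replicate
AUROC of a 1-positive/9-negative ranking is highly discrete and the
20-replicate mean halves the Monte Carlo error.

## Numerical and degenerate-input choices

* Strictly-greater confidence filtering; scores auto-detected as 0–1000
  when any exceeds 1 (overridable).
* All ties anywhere (propagation cutoff, module addition, final ranking,
  genetic sort) break lexicographically — runs are bit-reproducible and
  ranking files byte-identical across reruns.
* Non-convergence of propagation within `max_iterations` (default
  10,000) is reported via a flag, not fatal.
* Hypergeometric tails come from scipy (`sf(k−1, …)`); tests verify them
  against exhaustive enumeration for every configuration with universe
  ≤ 30.
* Empty seed sets, seeds missing from the network, empty catalogs,
  degenerate pools, and out-of-range probabilities raise `ValueError`
  with the offending names.

## Known limitations

* No identifier mapping: gene symbols are opaque case-sensitive strings.
* MeSH handling is key-based deduplication only; no ontology traversal.
* The weighted variant is one concrete reading of seed duplication.
* Proximity backgrounds recompute BFS per random draw; fine at desk
  scale, worth caching at interactome scale.
* α and the universe choice for the overlap test are conventions, not
  fitted values; both are exposed and documented rather than optimised.
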