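# netindic — network-based indication expansion for drug targets

`netindic` ranks candidate disease indications for a drug target (or a
target combination) using only a protein–protein interaction network and
gene–disease association data. It is aimed at computational biologists and
translational researchers who want a transparent, reproducible network
baseline for indication expansion / drug repositioning, together with the
standard comparison methods and evaluation metrics.

## The method

Given an interactome `G` (e.g. STRING filtered to confidence > 0.7) and a
target gene set `S`:

1. **Target subnetwork.** Flow propagation scores every node by iterating

   `F^t = α · A′ · F^{t−1} + (1 − α) · F^0`

   where `A′_{ij} = A_{ij} / √(deg_i · deg_j)` is the degree-normalised
   adjacency and `F^0` is 1 on the targets and 0 elsewhere; iteration stops
   when `‖F^t − F^{t−1}‖₁ < 10⁻⁶`. The target subnetwork is the targets,
   the top-k ranked nodes (k = 200 at interactome scale), and their direct
   interactors.

2. **Disease subnetworks.** For each disease, a module is grown from its
   genetically associated genes by DIAMOnD-style expansion: each round the
   outside node with the smallest hypergeometric connectivity p-value
   (links into the module vs its degree) is added, for a fixed number of
   iterations (200 at interactome scale).

3. **Enrichment and ranking.** Each target–disease pair is scored by the
   hypergeometric upper-tail probability of the node overlap of the two
   subnetworks in the universe of all network nodes; p-values are
   Holm-adjusted across diseases, and the ranking metric

   `Metric = Pval / log₂(N + 1)` (if `Pval < 1`, else 1)

   adjusts for the disease's number of associated genes `N`. Diseases are
   sorted by the metric ascending; the inverse of a disease's rank is its
   association score. A *weighted* variant counts each genetically
   associated gene as two nodes in the disease subnetwork, rewarding
   target subnetworks that hit the genetic core of a module.

The package also implements the standard comparison methods — ranking by
genetic-association score, and closest / shortest / kernel network
proximity with degree-matched random backgrounds — plus AUROC and
top-k% sensitivity evaluation against approved-indication ground truth and
a random-target background. A synthetic-benchmark generator builds
scale-free interactomes with planted, densified disease modules and known
positives so the whole pipeline is testable without any external download.

## Worked example

```sh
python examples/rank_indications_for_target.py
```

```
target gene: G0285;  true indication(s): ['D06']

 rank disease_id  n_seeds       pvalue          fdr       metric    score
    1        D06       10 9.660423e-20 9.660423e-19 2.792488e-20 1.000000
    2        D08       10 2.448543e-12 2.203688e-11 7.077876e-13 0.500000
    3        D01       10 3.663682e-01 1.000000e+00 1.059041e-01 0.333333
    ...
   10        D10       10 9.642314e-01 1.000000e+00 2.787254e-01 0.100000
```

The benchmark plants ten 20-gene disease modules into a 500-node
scale-free interactome; disease `D06` was planted around the target gene,
and the method places it at rank 1 with an overlap p-value of ~10⁻²⁰ —
its module shares far more nodes with the target subnetwork than chance
allows. The `score` column (1/rank) is the method's final per-disease
association score. Other examples build a target subnetwork, trace a
disease-module expansion, and compare all methods' AUROCs on one benchmark.

The same stages are available from a shell:

```sh
netindic simulate --n-nodes 500 --rng-seed 7 --out-dir bench/
netindic rank --network bench/network.tsv --disease-table bench/diseases.tsv \
    --targets G0285 --top-k 50 --no-include-neighbors --iterations 20 \
    --out ranking.tsv
netindic evaluate --ranking ranking.tsv --truth bench/truth.tsv --out report.json
```

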