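"""Rank candidate indications for a drug target on a synthetic benchmark.

Generates a 500-node interactome with ten planted disease modules (one of
which truly involves the target), builds the target subnetwork by flow
propagation, grows each disease subnetwork by connectivity expansion, and
ranks the diseases by hypergeometric node-overlap enrichment.
"""

import netindic
from netindic.synthetic import DESK_SETTINGS as S

bench = netindic.generate_benchmark(seed=1)
target = sorted(bench.targets)[0]
print(f"target gene: {target};  true indication(s): {sorted(bench.positives)}\n")

ranking = netindic.run_ranking(
    bench.network, bench.catalog, bench.targets,
    alpha=S["alpha"], top_k=S["top_k"],
    include_neighbors=S["include_neighbors"],
    module_iterations=S["module_iterations"],
)
print(ranking[["rank", "disease_id", "n_seeds", "pvalue", "fdr", "metric", "score"]]
      .to_string(index=False))
print(
    "\nSmaller p-values mean the disease subnetwork shares more nodes with\n"
    "the target subnetwork than chance allows; the metric divides p by\n"
    "log2(N+1) to favour diseases with more genetic evidence, and the final\n"
    "association score is the inverse of the rank."
)
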