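"""Build and inspect a propagation-ranked target subnetwork.

Flow starts at the target (F0 = 1 there, 0 elsewhere) and is smoothed over
the degree-normalised adjacency until convergence; the subnetwork collects
the top-ranked nodes around the target.
"""

import netindic
from netindic.propagation import PropagationConfig

bench = netindic.generate_benchmark(seed=2, n_nodes=300)
target = sorted(bench.targets)[0]
config = PropagationConfig(alpha=0.5, tolerance=1e-6)

flow = netindic.propagate(bench.network, {target}, config)
print(f"propagation converged after {flow.iterations_used} iterations")

sub = netindic.build_target_subnetwork(
    bench.network, {target}, config, top_k=20, include_neighbors=False
)
top = sorted(sub.nodes, key=lambda v: -flow.scores[v])[:10]
print(f"\ntarget {target}; subnetwork of {len(sub.nodes)} nodes; ten highest flows:")
for node in top:
    marker = " (target)" if node in sub.origins else ""
    print(f"  {node}  flow={flow.scores[node]:.5f}{marker}")
print(
    "\nFlow decays with network distance from the target, so these nodes are\n"
    "the processes most tightly coupled to target engagement."
)
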