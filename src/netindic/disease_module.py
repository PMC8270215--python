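"""Disease-module growth by iterative connectivity significance (DIAMOnD).

Starting from a disease's genetically associated genes, the module grows by
repeatedly adding the outside node whose links into the current set are most
hypergeometrically surprising: for a candidate with degree d and k_s links
into the current set of size s, the connectivity p-value is the upper tail
P(X >= k_s) of a hypergeometric draw of d from a population of N-1 nodes of
which s are in the set.  The smallest-p candidate joins the set each round
(ties broken by lexicographic node id); growth stops after a fixed number of
iterations (200 by default, the putative size of a complete disease module)
or when no connected candidate remains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .propagation import Subnetwork

logger = logging.getLogger(__name__)


@dataclass
class ExpansionTrace:
    """Ordered record of module growth: (node, p-value, iteration index)."""

    added: list[tuple[str, float, int]]
    subnetwork: Subnetwork


def connectivity_pvalue(node: str, current_set, network: nx.Graph) -> float:
    """Upper-tail hypergeometric probability of the node's links into the set.

    Population is all network nodes except the candidate itself; successes
    are the current set members; draws are the candidate's neighbors.
    """
    current_set = set(current_set)
    if node in current_set:
        raise ValueError(f"{node!r} is already in the current set")
    k = len(set(network.neighbors(node)) & current_set)
    population = network.number_of_nodes() - 1
    return float(hypergeom.sf(k - 1, population, len(current_set), network.degree(node)))


def diamond_expand(network: nx.Graph, seeds, n_iterations: int = 200) -> ExpansionTrace:
    """Grow a disease subnetwork from its seed genes.

    Seeds absent from the network are dropped with a warning (matching the
    catalog intersection policy); at least one must remain.  Candidate
    intersection counts are maintained incrementally, which is
    observationally identical to rescanning every candidate each round.
    """
    if n_iterations < 0:
        raise ValueError("n_iterations must be >= 0")
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    missing = seeds - set(network.nodes)
    if missing:
        logger.warning("diamond_expand: dropping %d seeds absent from network: %s",
                       len(missing), sorted(missing))
        seeds -= missing
    if not seeds:
        raise ValueError(f"no seeds present in network (missing: {sorted(missing)})")

    population = network.number_of_nodes() - 1
    current = set(seeds)
    # links into the current set, per outside node touching it
    k_in: dict[str, int] = {}
    for s in seeds:
        for u in network.neighbors(s):
            if u not in current:
                k_in[u] = k_in.get(u, 0) + 1

    added: list[tuple[str, float, int]] = []
    for iteration in range(1, n_iterations + 1):
        if not k_in:
            break
        candidates = sorted(k_in)  # lexicographic order fixes tie-breaks
        ks = np.array([k_in[c] for c in candidates])
        degs = np.array([network.degree(c) for c in candidates])
        pvals = hypergeom.sf(ks - 1, population, len(current), degs)
        # argmin returns the first minimum; candidates are in lexicographic
        # order, so ties resolve to the smallest node id
        best = int(np.argmin(pvals))
        node, p = candidates[best], float(pvals[best])
        added.append((node, p, iteration))
        current.add(node)
        del k_in[node]
        for u in network.neighbors(node):
            if u not in current:
                k_in[u] = k_in.get(u, 0) + 1

    return ExpansionTrace(
        added=added,
        subnetwork=Subnetwork(
            nodes=frozenset(current),
            origins=frozenset(seeds),
            construction="disease",
        ),
    )
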