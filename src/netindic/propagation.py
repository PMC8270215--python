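"""Flow propagation over the interactome and target-subnetwork assembly.

Node prioritisation follows the classic propagation scheme: flow starts at
the target node(s) (F^0 = 1 on targets, 0 elsewhere) and is iteratively
smoothed over the degree-normalised adjacency,

    F^t = alpha * A' * F^{t-1} + (1 - alpha) * F^0,

where A'_{ij} = A_{ij} / sqrt(deg(i) * deg(j)).  The symmetric degree
normalisation compensates for hubs picking up flow by chance and bounds the
spectral radius of A' by 1, so the iteration contracts to a unique fixed
point for any alpha < 1.  Iteration stops when the L1 difference between
consecutive flow vectors drops below the tolerance (1e-6 by default).

The target subnetwork is the target(s), the top-k propagation-ranked other
nodes (k = 200 by default), and optionally the direct network neighbors of
all of those.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg


@dataclass(frozen=True)
class PropagationConfig:
    """Parameters of the propagation iteration.

    alpha is the fraction of flow retained in the network each step (the
    remainder is re-injected at the targets); it is a smoothing radius, not
    stated by convention anywhere — 0.5 is the standard middle ground.
    """

    alpha: float = 0.5
    tolerance: float = 1e-6
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class FlowVector:
    """Per-node propagation scores plus convergence metadata."""

    scores: dict[str, float]
    iterations_used: int
    converged: bool


@dataclass(frozen=True)
class Subnetwork:
    """A node set with its origin nodes (targets or disease seeds)."""

    nodes: frozenset[str]
    origins: frozenset[str]
    construction: str  # "target" or "disease"

    def __post_init__(self) -> None:
        if not self.origins <= self.nodes:
            raise ValueError("origin nodes must be a subset of subnetwork nodes")

    def __len__(self) -> int:
        return len(self.nodes)


def _node_order(network: nx.Graph) -> list[str]:
    return sorted(network.nodes)


def normalized_adjacency(network: nx.Graph) -> tuple[sp.csr_array, list[str]]:
    """Symmetric degree-normalised adjacency A' with A'_{ij} = 1/sqrt(d_i d_j).

    Edge confidences are not used as weights: the normalisation is defined
    on degrees alone, so the adjacency is binary.  Returns the sparse matrix
    and the (sorted) node order indexing its rows.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network is empty")
    order = _node_order(network)
    adj = nx.to_scipy_sparse_array(network, nodelist=order, weight=None, format="csr")
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    assert (degrees > 0).all(), "isolated node after filtering"
    inv_sqrt = 1.0 / np.sqrt(degrees)
    d_half = sp.diags_array(inv_sqrt)
    return (d_half @ adj @ d_half).tocsr(), order


def _seed_vector(order: list[str], seeds: frozenset[str] | set[str]) -> np.ndarray:
    index = {v: i for i, v in enumerate(order)}
    f0 = np.zeros(len(order))
    for s in seeds:
        f0[index[s]] = 1.0
    return f0


def _check_seeds(network: nx.Graph, seeds) -> set[str]:
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    missing = seeds - set(network.nodes)
    if missing:
        raise ValueError(f"seeds not in network: {sorted(missing)}")
    return seeds


def propagate(
    network: nx.Graph,
    seeds,
    config: PropagationConfig | None = None,
) -> FlowVector:
    """Iterate F^t = alpha A' F^{t-1} + (1-alpha) F^0 from the seed nodes.

    F^0 assigns flow 1 to each seed and 0 elsewhere.  Stops when the L1
    norm of the step difference drops below the configured tolerance, or at
    max_iterations (reported via the ``converged`` flag, not fatal).
    """
    config = config or PropagationConfig()
    seeds = _check_seeds(network, seeds)
    a_norm, order = normalized_adjacency(network)
    f0 = _seed_vector(order, seeds)
    f = f0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        f_next = config.alpha * (a_norm @ f) + (1.0 - config.alpha) * f0
        if np.abs(f_next - f).sum() < config.tolerance:
            f = f_next
            converged = True
            break
        f = f_next
    return FlowVector(
        scores=dict(zip(order, f.tolist())),
        iterations_used=iterations,
        converged=converged,
    )


def propagate_exact(network: nx.Graph, seeds, alpha: float = 0.5) -> FlowVector:
    """Closed-form fixed point F = (1-alpha) (I - alpha A')^{-1} F^0.

    Direct dense solve; guarded to networks of at most 2,000 nodes.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if network.number_of_nodes() > 2000:
        raise ValueError("propagate_exact is limited to networks of <= 2000 nodes")
    seeds = _check_seeds(network, seeds)
    a_norm, order = normalized_adjacency(network)
    f0 = _seed_vector(order, seeds)
    n = len(order)
    system = np.eye(n) - alpha * a_norm.toarray()
    f = (1.0 - alpha) * np.linalg.solve(system, f0)
    return FlowVector(scores=dict(zip(order, f.tolist())), iterations_used=0, converged=True)


def build_target_subnetwork(
    network: nx.Graph,
    targets,
    config: PropagationConfig | None = None,
    top_k: int = 200,
    include_neighbors: bool = True,
) -> Subnetwork:
    """Assemble the target subnetwork from propagation ranks.

    Non-target nodes are ranked by descending flow (ties at the cutoff are
    broken by lexicographic node id for determinism); the subnetwork is the
    targets, the top-k ranked nodes, and — if ``include_neighbors`` — every
    direct neighbor of any of those.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    targets = _check_seeds(network, targets)
    flow = propagate(network, targets, config)
    others = sorted(
        (v for v in network.nodes if v not in targets),
        key=lambda v: (-flow.scores[v], v),
    )
    selected = set(targets) | set(others[:top_k])
    if include_neighbors:
        neighbors = {u for v in selected for u in network.neighbors(v)}
        selected |= neighbors
    return Subnetwork(
        nodes=frozenset(selected),
        origins=frozenset(targets),
        construction="target",
    )
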