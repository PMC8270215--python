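"""Synthetic benchmarks with planted disease modules and known ground truth.

Real inputs for indication expansion — a high-confidence interactome, a
gene-disease association catalog, and approved-indication labels — are
large, licensed, or versioned resources.  This module builds small
stand-ins with the structural features the method relies on:

* a connected scale-free interactome (preferential attachment), because
  biomedical networks are scale-free and small-world;
* disease modules: connected node sets sampled by random walk and densified
  with extra intra-module edges, because disease genes tend to interact
  with each other;
* a target gene whose *positive* (true-indication) diseases have modules
  grown around the target itself, while negative diseases are planted away
  from the target's neighborhood;
* genetic seed genes: the first-discovered core of each module, with
  association scores drawn uniform(0.3, 1.0) so the genetic baseline is
  informative but imperfect.

Everything is reproducible byte-for-byte from (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .graph_io import DiseaseCatalog, DiseaseEntry

#: Analysis settings matched to the default benchmark scale (hundreds of
#: nodes): the target subnetwork takes the top 10% of nodes without the
#: neighbor closure (which would saturate a small dense graph), and disease
#: modules grow by one planted-module-size worth of nodes.
DESK_SETTINGS = {
    "alpha": 0.5,
    "top_k": 50,
    "include_neighbors": False,
    "module_iterations": 20,
    "n_background": 10,
}


@dataclass(frozen=True)
class BenchmarkParams:
    """Generation parameters of a synthetic benchmark."""

    n_nodes: int = 500
    attachment: int = 3
    n_diseases: int = 10
    n_positives: int = 1
    module_size: int = 20
    extra_edge_prob: float = 0.3
    seed_fraction: float = 0.5
    overlap: float = 0.8
    #: probability that a positive disease lists the target itself among its
    #: associated genes; below 1 so the genetic baseline is imperfect, as
    #: approved indications often lack direct genetic links to the target
    target_seed_prob: float = 0.5
    seed: int = 0


@dataclass
class SyntheticBenchmark:
    """A generated interactome + catalog + target with known positives."""

    network: nx.Graph
    catalog: DiseaseCatalog
    targets: frozenset[str]
    positives: frozenset[str]
    planted: dict[str, frozenset[str]]  # disease id -> planted module nodes
    params: BenchmarkParams

    def write(self, out_dir) -> dict[str, Path]:
        """Emit the benchmark in the same dialects the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": out / "network.tsv",
            "diseases": out / "diseases.tsv",
            "targets": out / "targets.txt",
            "truth": out / "truth.tsv",
        }
        with open(paths["network"], "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for a, b, data in sorted(self.network.edges(data=True)):
                fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):g}\n")
        with open(paths["diseases"], "w") as fh:
            fh.write("geneSymbol\tdiseaseId\tdiseaseName\tmeshId\tscore\n")
            for entry in self.catalog:
                for gene in sorted(entry.seed_genes):
                    fh.write(
                        f"{gene}\t{entry.disease_id}\t{entry.name}\t"
                        f"{entry.mesh_id}\t{entry.gene_scores[gene]:.6f}\n"
                    )
        with open(paths["targets"], "w") as fh:
            for t in sorted(self.targets):
                fh.write(f"{t}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("target\tdisease_id\n")
            for t in sorted(self.targets):
                for d in sorted(self.positives):
                    fh.write(f"{t}\t{d}\n")
        return paths


def generate_network(n_nodes: int, attachment: int = 3, seed: int = 0) -> nx.Graph:
    """Connected scale-free interactome by preferential attachment.

    Node ids are G0001..; every edge carries weight 1.0.
    """
    if not n_nodes > attachment >= 1:
        raise ValueError(f"need n_nodes > attachment >= 1, got {n_nodes}, {attachment}")
    raw = nx.barabasi_albert_graph(n_nodes, attachment, seed=seed)
    width = max(4, len(str(n_nodes)))
    mapping = {i: f"G{i + 1:0{width}d}" for i in raw.nodes}
    graph = nx.relabel_nodes(raw, mapping)
    nx.set_edge_attributes(graph, 1.0, "weight")
    return graph


def _random_walk_set(
    network: nx.Graph,
    root: str,
    size: int,
    rng: np.random.Generator,
    restart: float = 0.5,
    forbidden: set[str] | None = None,
    max_steps_factor: int = 500,
) -> list[str]:
    """Connected node set of ``size`` collected by a restarting random walk.

    The walk starts at ``root``, restarts there with probability
    ``restart`` per step, and never records nodes in ``forbidden``.  Nodes
    are returned in discovery order (root first).
    """
    forbidden = forbidden or set()
    if root in forbidden:
        raise ValueError("walk root is forbidden")
    visited = [root]
    member = {root}
    current = root
    for _ in range(max_steps_factor * size):
        if len(visited) >= size:
            return visited
        if restart > 0 and rng.random() < restart:
            current = root
            continue
        neighbors = sorted(network.neighbors(current))
        current = neighbors[rng.integers(len(neighbors))]
        if current in forbidden:
            current = root
            continue
        if current not in member:
            member.add(current)
            visited.append(current)
    raise RuntimeError(
        f"random walk from {root} could not collect {size} nodes "
        f"within {max_steps_factor * size} steps"
    )


def plant_disease(
    network: nx.Graph,
    module_size: int,
    extra_edge_prob: float,
    seed_fraction: float,
    rng: np.random.Generator,
    disease_id: str = "D01",
    name: str | None = None,
    mesh_id: str | None = None,
    root: str | None = None,
    restart: float = 0.5,
    forbidden: set[str] | None = None,
    exclude_from_seeds: set[str] | None = None,
) -> tuple[DiseaseEntry, frozenset[str]]:
    """Plant one disease module into the network (mutating it).

    A connected set of ``module_size`` nodes is collected by random walk,
    densified by adding each missing intra-module edge with probability
    ``extra_edge_prob``, and its first-discovered ceil(seed_fraction *
    module_size) members become the genetic seed genes — the core the
    module was grown around, as in real disease modules.
    """
    if not 0 < module_size <= network.number_of_nodes():
        raise ValueError("module_size must be in [1, n_nodes]")
    if not 0.0 < seed_fraction <= 1.0:
        raise ValueError("seed_fraction must be in (0, 1]")
    if not 0.0 <= extra_edge_prob <= 1.0:
        raise ValueError("extra_edge_prob must be in [0, 1]")
    if root is None:
        candidates = sorted(set(network.nodes) - (forbidden or set()))
        root = candidates[rng.integers(len(candidates))]
    members = _random_walk_set(
        network, root, module_size, rng, restart=restart, forbidden=forbidden
    )
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if not network.has_edge(a, b) and rng.random() < extra_edge_prob:
                network.add_edge(a, b, weight=1.0)
    n_seeds = math.ceil(seed_fraction * module_size)
    eligible = [m for m in members if m not in (exclude_from_seeds or set())]
    seeds = eligible[:n_seeds]
    scores = {g: float(rng.uniform(0.3, 1.0)) for g in seeds}
    entry = DiseaseEntry(
        disease_id=disease_id,
        name=name or f"synthetic disease {disease_id}",
        mesh_id=mesh_id or f"M{disease_id[1:]}",
        seed_genes=frozenset(seeds),
        gene_scores=scores,
    )
    return entry, frozenset(members)


def _far_nodes(network: nx.Graph, target: str, min_distance: int = 3) -> list[str]:
    dist = nx.single_source_shortest_path_length(network, target)
    for cut in (min_distance, min_distance - 1):
        far = sorted(v for v in network.nodes if dist.get(v, np.inf) >= cut)
        if far:
            return far
    raise RuntimeError(f"no node at distance >= {min_distance - 1} from {target}")


def generate_benchmark(params: BenchmarkParams | None = None, **overrides) -> SyntheticBenchmark:
    """Build a full benchmark: network, catalog, target, and truth labels.

    Positive diseases (true indications) have modules grown by a random
    walk rooted at the target with restart probability equal to the
    ``overlap`` parameter, so higher overlap plants them tighter around the
    target; with overlap 0 they are planted like negatives, away from the
    target, and the ranking signal vanishes by construction.  Negative
    diseases are rooted at nodes at least three hops from the target and
    never include the target or its direct neighbors.
    """
    if params is None:
        params = BenchmarkParams(**overrides)
    elif overrides:
        params = BenchmarkParams(**{**asdict(params), **overrides})
    if params.n_positives > params.n_diseases:
        raise ValueError("n_positives cannot exceed n_diseases")
    rng = np.random.default_rng(params.seed)
    network = generate_network(params.n_nodes, params.attachment, seed=params.seed)

    # a typical (non-hub) protein as the drug target: middle of the degree range
    by_degree = sorted(network.nodes, key=lambda v: (network.degree(v), v))
    mid = by_degree[len(by_degree) // 4: 3 * len(by_degree) // 4]
    target = mid[rng.integers(len(mid))]

    positive_idx = set(
        rng.choice(params.n_diseases, size=params.n_positives, replace=False).tolist()
    )
    width = max(2, len(str(params.n_diseases)))

    entries: dict[str, DiseaseEntry] = {}
    planted: dict[str, frozenset[str]] = {}
    positives = []
    for i in range(params.n_diseases):
        disease_id = f"D{i + 1:0{width}d}"
        is_positive = i in positive_idx
        if is_positive and params.overlap > 0:
            target_is_seed = rng.random() < params.target_seed_prob
            entry, nodes = plant_disease(
                network, params.module_size, params.extra_edge_prob,
                params.seed_fraction, rng, disease_id=disease_id,
                root=target, restart=params.overlap,
                exclude_from_seeds=None if target_is_seed else {target},
            )
        else:
            # recomputed each time: earlier plantings may have added edges
            near_target = set(network.neighbors(target)) | {target}
            far = _far_nodes(network, target)
            root = far[rng.integers(len(far))]
            entry, nodes = plant_disease(
                network, params.module_size, params.extra_edge_prob,
                params.seed_fraction, rng, disease_id=disease_id,
                root=root, restart=0.5, forbidden=near_target,
            )
        entries[disease_id] = entry
        planted[disease_id] = nodes
        if is_positive:
            positives.append(disease_id)

    return SyntheticBenchmark(
        network=network,
        catalog=DiseaseCatalog(entries=entries),
        targets=frozenset({target}),
        positives=frozenset(positives),
        planted=planted,
        params=params,
    )
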