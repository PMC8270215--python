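"""End-to-end orchestration: read inputs, build subnetworks, rank, evaluate.

The workflow has three stages: (A) build the target subnetwork by flow
propagation and one disease subnetwork per catalog entry by DIAMOnD
expansion; (B) score each target-disease pair by hypergeometric node
overlap; (C) rank diseases by the seed-adjusted metric and, when ground
truth is supplied, evaluate the ranking.  Disease modules depend only on
the network, seeds, and iteration count, so they are cached on disk and
reused across targets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import enrichment, evaluation, graph_io, propagation
from .disease_module import ExpansionTrace
from .graph_io import DiseaseCatalog
from .propagation import PropagationConfig, Subnetwork

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one expansion run needs; serialised next to its outputs."""

    network_path: str
    disease_path: str
    targets: list[str]
    truth_path: str | None = None
    score_threshold: float = 0.7
    score_scale: str = "auto"
    min_seeds: int = 1
    alpha: float = 0.5
    tolerance: float = 1e-6
    max_iterations: int = 10_000
    top_k: int = 200
    include_neighbors: bool = True
    module_iterations: int = 200
    variant: str = "plain"
    shortlist_fraction: float = 0.15
    out_dir: str = "netindic_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def network_fingerprint(network: nx.Graph) -> str:
    """Stable hash of the edge set, for cache keys."""
    digest = hashlib.sha1()
    for a, b in sorted(tuple(sorted(e)) for e in network.edges):
        digest.update(f"{a}\t{b}\n".encode())
    return digest.hexdigest()


class DiseaseModuleCache:
    """On-disk cache of DIAMOnD traces keyed by (network, seeds, iterations).

    Behaviour is observationally identical to recomputation: the key
    includes a fingerprint of the network's edge set, so any change to the
    graph invalidates entries.
    """

    def __init__(self, cache_dir, network: nx.Graph):
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self._net_hash = network_fingerprint(network)

    def _path(self, seeds: frozenset[str], iterations: int) -> Path:
        digest = hashlib.sha1(self._net_hash.encode())
        digest.update(repr((sorted(seeds), iterations)).encode())
        return self.cache_dir / f"{digest.hexdigest()}.json"

    def __contains__(self, key) -> bool:
        seeds, iterations = key
        return self._path(seeds, iterations).exists()

    def __getitem__(self, key) -> ExpansionTrace:
        seeds, iterations = key
        with open(self._path(seeds, iterations)) as fh:
            data = json.load(fh)
        added = [(n, p, i) for n, p, i in data["added"]]
        return ExpansionTrace(
            added=added,
            subnetwork=Subnetwork(
                nodes=frozenset(data["nodes"]),
                origins=frozenset(data["origins"]),
                construction="disease",
            ),
        )

    def __setitem__(self, key, trace: ExpansionTrace) -> None:
        seeds, iterations = key
        payload = {
            "added": trace.added,
            "nodes": sorted(trace.subnetwork.nodes),
            "origins": sorted(trace.subnetwork.origins),
        }
        with open(self._path(seeds, iterations), "w") as fh:
            json.dump(payload, fh)


def run_ranking(
    network: nx.Graph,
    catalog: DiseaseCatalog,
    targets,
    alpha: float = 0.5,
    tolerance: float = 1e-6,
    max_iterations: int = 10_000,
    top_k: int = 200,
    include_neighbors: bool = True,
    module_iterations: int = 200,
    variant: str = "plain",
    modules: dict[str, ExpansionTrace] | None = None,
    module_cache=None,
) -> pd.DataFrame:
    """Propagate from the targets, grow disease modules, and rank diseases."""
    config = PropagationConfig(
        alpha=alpha, tolerance=tolerance, max_iterations=max_iterations
    )
    target_sub = propagation.build_target_subnetwork(
        network, targets, config, top_k=top_k, include_neighbors=include_neighbors
    )
    return enrichment.rank_indications(
        network, target_sub, catalog, variant=variant,
        module_iterations=module_iterations,
        modules=modules, module_cache=module_cache,
    )


def read_truth(path, targets=None) -> set[str]:
    """Read a (target, disease_id) truth table; returns the positive ids."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if "disease_id" not in table.columns:
        raise ValueError(f"{path}: missing required column 'disease_id'")
    if targets is not None and "target" in table.columns:
        table = table[table["target"].isin(set(targets))]
    return set(table["disease_id"])


def run_expansion(config: RunConfig) -> tuple[pd.DataFrame, evaluation.EvaluationReport | None]:
    """Execute the full workflow and write outputs under ``config.out_dir``.

    Writes ``ranking.tsv`` (with a shortlist column marking the recommended
    top fraction, 15% by default), a config snapshot, and a log file.
    Identical config + seed give byte-identical ranking files.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("netindic")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        stage = "graph_io"
        network = graph_io.read_interactions(
            config.network_path, config.score_threshold, config.score_scale
        )
        catalog = graph_io.read_disease_catalog(
            config.disease_path, network, config.min_seeds
        )
        stage = "disease_module"
        cache = DiseaseModuleCache(out_dir / "cache", network)
        modules = enrichment.grow_disease_modules(
            network, catalog, config.module_iterations, cache
        )
        stage = "enrichment"
        ranking = run_ranking(
            network, catalog, config.targets,
            alpha=config.alpha, tolerance=config.tolerance,
            max_iterations=config.max_iterations, top_k=config.top_k,
            include_neighbors=config.include_neighbors,
            module_iterations=config.module_iterations,
            variant=config.variant, modules=modules,
        )
        cutoff = math.ceil(len(ranking) * config.shortlist_fraction)
        ranking["shortlisted"] = ranking["rank"] <= cutoff
        ranking.to_csv(out_dir / "ranking.tsv", sep="\t", index=False, float_format="%.10g")
        with open(out_dir / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=2, sort_keys=True)

        report = None
        if config.truth_path:
            stage = "evaluation"
            positives = read_truth(config.truth_path, config.targets)
            report = evaluation.evaluate_ranking(ranking, positives)
            with open(out_dir / "report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        logger.info("run_expansion finished: %d diseases ranked", len(ranking))
        return ranking, report
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
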