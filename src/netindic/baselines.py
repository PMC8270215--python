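"""Comparison methods: genetic-association ranking and network proximity.

Three proximity measures between a target set S and a disease gene set T
(unweighted shortest-path hop counts):

* closest — mean over disease genes of the distance to the nearest target;
* shortest — mean distance over all reachable target-disease pairs;
* kernel — exponentially down-weighted distances (Guney et al. form):
  -(1/|T|) * sum_t ln[ (1/|S|) * sum_s exp(-(d(s,t)+1)) ].

Significance of an observed distance is assessed against distances to
random node sets matched to the disease genes' degrees (degree-binned
sampling), summarised as a z-score; diseases are ranked ascending by z.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import DiseaseCatalog

logger = logging.getLogger(__name__)


@dataclass
class ProximityResult:
    """Observed distance with its degree-matched random background."""

    distance: float
    background_mean: float
    background_sd: float
    zscore: float
    n_excluded: int = 0  # disease genes unreachable from every target


def _target_distances(network: nx.Graph, targets) -> dict[str, dict[str, int]]:
    return {s: nx.single_source_shortest_path_length(network, s) for s in targets}


def _restrict(network: nx.Graph, nodes) -> set[str]:
    present = set(nodes) & set(network.nodes)
    if not present:
        raise ValueError("no nodes of the set are present in the network")
    return present


def closest_distance(network: nx.Graph, targets, disease_genes) -> float:
    """Mean over disease genes of the shortest path to the nearest target."""
    targets = _restrict(network, targets)
    disease_genes = _restrict(network, disease_genes)
    dists = _target_distances(network, targets)
    values = []
    skipped = 0
    for t in disease_genes:
        reachable = [dists[s][t] for s in targets if t in dists[s]]
        if reachable:
            values.append(min(reachable))
        else:
            skipped += 1
    if skipped:
        logger.info("closest_distance: %d disease genes unreachable, excluded", skipped)
    if not values:
        raise ValueError("no disease gene is reachable from any target")
    return float(np.mean(values))


def shortest_distance(network: nx.Graph, targets, disease_genes) -> float:
    """Mean shortest-path length over all reachable target-disease pairs."""
    targets = _restrict(network, targets)
    disease_genes = _restrict(network, disease_genes)
    dists = _target_distances(network, targets)
    values = [
        dists[s][t] for s in targets for t in disease_genes if t in dists[s]
    ]
    n_pairs = len(targets) * len(disease_genes)
    if len(values) < n_pairs:
        logger.info("shortest_distance: %d unreachable pairs excluded", n_pairs - len(values))
    if not values:
        raise ValueError("no disease gene is reachable from any target")
    return float(np.mean(values))


def kernel_distance(network: nx.Graph, targets, disease_genes) -> float:
    """Exponential-penalty proximity; long paths contribute almost nothing.

    Disease genes unreachable from every target would contribute
    ln(0) = -inf and are excluded with a logged count.
    """
    targets = _restrict(network, targets)
    disease_genes = _restrict(network, disease_genes)
    dists = _target_distances(network, targets)
    terms = []
    skipped = 0
    for t in disease_genes:
        inner = np.mean([
            math.exp(-(dists[s][t] + 1)) if t in dists[s] else 0.0
            for s in targets
        ])
        if inner == 0.0:
            skipped += 1
            continue
        terms.append(math.log(inner))
    if skipped:
        logger.info("kernel_distance: %d disease genes unreachable, excluded", skipped)
    if not terms:
        raise ValueError("no disease gene is reachable from any target")
    return float(-np.mean(terms))


_MEASURES = {
    "closest": closest_distance,
    "shortest": shortest_distance,
    "kernel": kernel_distance,
}


def _degree_bins(network: nx.Graph, min_bin: int = 100) -> dict[int, list[str]]:
    """Nodes grouped by degree, each group widened to at least ``min_bin``
    members by merging adjacent degree values (capped at the network size)."""
    by_degree: dict[int, list[str]] = {}
    for v, d in network.degree():
        by_degree.setdefault(d, []).append(v)
    degrees = sorted(by_degree)
    min_bin = min(min_bin, network.number_of_nodes())
    bins: dict[int, list[str]] = {}
    for d in degrees:
        members = list(by_degree[d])
        lo, hi = d, d
        idx = degrees.index(d)
        lo_i, hi_i = idx, idx
        while len(members) < min_bin and (lo_i > 0 or hi_i < len(degrees) - 1):
            # widen toward the nearer degree value first
            widen_lo = lo_i > 0 and (
                hi_i == len(degrees) - 1 or d - degrees[lo_i - 1] <= degrees[hi_i + 1] - d
            )
            if widen_lo:
                lo_i -= 1
                members.extend(by_degree[degrees[lo_i]])
            else:
                hi_i += 1
                members.extend(by_degree[degrees[hi_i]])
        bins[d] = sorted(members)
    return bins


def _degree_matched_sample(
    network: nx.Graph, reference, rng: np.random.Generator,
    bins: dict[int, list[str]],
) -> set[str]:
    """One random node set matching the reference set's degree sequence,
    sampled without replacement within (widened) degree bins."""
    chosen: set[str] = set()
    for v in sorted(reference):
        pool = [u for u in bins[network.degree(v)] if u not in chosen]
        if not pool:  # bin exhausted by earlier picks: fall back to any node
            pool = [u for u in sorted(network.nodes) if u not in chosen]
        chosen.add(pool[rng.integers(len(pool))])
    return chosen


def proximity_zscore(
    network: nx.Graph,
    targets,
    disease_genes,
    measure: str = "closest",
    n_random: int = 1000,
    seed: int = 0,
    min_bin: int = 100,
) -> ProximityResult:
    """Observed proximity vs degree-matched random disease gene sets.

    z = (observed - background mean) / background sd; smaller (more
    negative) z means the targets sit closer to the disease genes than
    degree alone predicts.
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    fn = _MEASURES[measure]
    disease_present = _restrict(network, disease_genes)
    observed = fn(network, targets, disease_present)
    rng = np.random.default_rng(seed)
    bins = _degree_bins(network, min_bin)
    background = np.array([
        fn(network, targets, _degree_matched_sample(network, disease_present, rng, bins))
        for _ in range(n_random)
    ])
    mean, sd = float(background.mean()), float(background.std(ddof=0))
    z = (observed - mean) / sd if sd > 0 else 0.0
    return ProximityResult(
        distance=observed, background_mean=mean, background_sd=sd, zscore=float(z),
    )


def genetic_association_rank(catalog: DiseaseCatalog, targets) -> pd.DataFrame:
    """Rank diseases by their genetic-association score for the target(s).

    A disease's score is its association score for the target gene (0 when
    absent); for target combinations the maximum over targets is used.
    Sorted descending, ties broken by lexicographic disease id.
    """
    if len(catalog) == 0:
        raise ValueError("disease catalog is empty")
    if isinstance(targets, str):
        targets = [targets]
    rows = [
        {
            "disease_id": e.disease_id,
            "disease_name": e.name,
            "mesh_id": e.mesh_id,
            "assoc_score": max((e.gene_scores.get(t, 0.0) for t in targets), default=0.0),
        }
        for e in catalog
    ]
    frame = pd.DataFrame(rows).sort_values(
        ["assoc_score", "disease_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame["rank"] = range(1, len(frame) + 1)
    return frame


def rank_by_proximity(
    network: nx.Graph,
    catalog: DiseaseCatalog,
    targets,
    measure: str = "closest",
    n_random: int = 1000,
    seed: int = 0,
    min_bin: int = 100,
) -> pd.DataFrame:
    """Rank all catalog diseases by proximity z-score (ascending).

    Raw distances are reported alongside; ties broken by disease id.
    """
    rows = []
    for i, entry in enumerate(catalog):
        res = proximity_zscore(
            network, targets, entry.seed_genes, measure=measure,
            n_random=n_random, seed=seed + i, min_bin=min_bin,
        )
        rows.append({
            "disease_id": entry.disease_id,
            "disease_name": entry.name,
            "mesh_id": entry.mesh_id,
            "distance": res.distance,
            "zscore": res.zscore,
        })
    frame = pd.DataFrame(rows).sort_values(
        ["zscore", "disease_id"], kind="stable"
    ).reset_index(drop=True)
    frame["rank"] = range(1, len(frame) + 1)
    return frame
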