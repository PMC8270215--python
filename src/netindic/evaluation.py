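"""Evaluation of indication rankings against approved-indication truth.

AUROC is computed rank-based: the probability that a uniformly chosen true
indication outranks a uniformly chosen non-indication, with rank ties
counting one half.  Sensitivity at a top-k% threshold is the fraction of
true indications ranked within the top ceil(k% of the list).  A
random-target background repeats the whole ranking pipeline for randomly
drawn targets to show how much of a target's performance is specific to it
rather than to the network and catalog.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import enrichment, propagation
from .graph_io import DiseaseCatalog

#: The top-rank thresholds reported by default.
DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass
class EvaluationReport:
    auroc: float
    sensitivity: dict[float, float]
    n_positives: int
    n_ranked: int
    background_aurocs: list[float] | None = None

    def to_dict(self) -> dict:
        out = {
            "auroc": self.auroc,
            "sensitivity": {f"{k:g}": v for k, v in self.sensitivity.items()},
            "n_positives": self.n_positives,
            "n_ranked": self.n_ranked,
        }
        if self.background_aurocs is not None:
            out["background_aurocs"] = self.background_aurocs
            out["background_auroc_mean"] = float(np.mean(self.background_aurocs))
        return out


def _split_ranks(ranking: pd.DataFrame, positives) -> tuple[np.ndarray, np.ndarray]:
    positives = set(positives)
    is_pos = ranking["disease_id"].isin(positives).to_numpy()
    ranks = ranking["rank"].to_numpy(dtype=float)
    pos, neg = ranks[is_pos], ranks[~is_pos]
    if len(pos) == 0:
        raise ValueError("no positive disease appears in the ranking")
    if len(neg) == 0:
        raise ValueError("no negative disease appears in the ranking")
    return pos, neg


def auroc(ranking: pd.DataFrame, positives) -> float:
    """Probability that a random positive outranks a random negative.

    Equal to the area under the ROC curve traced by sweeping a rank
    threshold; tied ranks count 0.5.
    """
    pos, neg = _split_ranks(ranking, positives)
    # smaller rank = better; count concordant (pos before neg) pairs
    wins = (pos[:, None] < neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (len(pos) * len(neg)))


def sensitivity_at_top(
    ranking: pd.DataFrame,
    positives,
    fraction: float,
    fdr_max: float | None = None,
) -> float:
    """Fraction of positives ranked within the top ``fraction`` of the list.

    The cut is ceil(fraction * n_ranked), so a 5% cut of a short list is
    still non-empty.  If ``fdr_max`` is given, a positive only counts as
    recovered when its Holm-adjusted value is below it.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    pos, _ = _split_ranks(ranking, positives)
    cutoff = math.ceil(fraction * len(ranking))
    frame = ranking[ranking["disease_id"].isin(set(positives))]
    within = frame["rank"] <= cutoff
    if fdr_max is not None:
        within &= frame["fdr"] < fdr_max
    return float(within.sum() / len(pos))


def evaluate_ranking(
    ranking: pd.DataFrame,
    positives,
    thresholds=DEFAULT_THRESHOLDS,
    background_aurocs: list[float] | None = None,
    fdr_max: float | None = None,
) -> EvaluationReport:
    """Bundle AUROC and top-k% sensitivities into one report."""
    pos, _ = _split_ranks(ranking, positives)
    return EvaluationReport(
        auroc=auroc(ranking, positives),
        sensitivity={
            f: sensitivity_at_top(ranking, positives, f, fdr_max=fdr_max)
            for f in thresholds
        },
        n_positives=len(pos),
        n_ranked=len(ranking),
        background_aurocs=background_aurocs,
    )


def random_target_background(
    network: nx.Graph,
    catalog: DiseaseCatalog,
    positives,
    n_targets: int = 100,
    candidate_pool=None,
    seed: int = 0,
    alpha: float = 0.5,
    top_k: int = 200,
    include_neighbors: bool = True,
    module_iterations: int = 200,
    variant: str = "plain",
    modules=None,
    module_cache: dict | None = None,
) -> list[float]:
    """AUROCs of randomly sampled targets run through the same pipeline.

    The candidate pool stands in for a druggable-gene list; it defaults to
    all network nodes.  Disease modules are target-independent and are grown
    once and reused.
    """
    pool = sorted(candidate_pool) if candidate_pool is not None else sorted(network.nodes)
    missing = set(pool) - set(network.nodes)
    if missing:
        raise ValueError(f"candidate pool nodes not in network: {sorted(missing)}")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if len(pool) < n_targets:
        raise ValueError(f"candidate pool ({len(pool)}) smaller than n_targets ({n_targets})")
    rng = np.random.default_rng(seed)
    sample = [pool[i] for i in rng.choice(len(pool), size=n_targets, replace=False)]
    if modules is None:
        modules = enrichment.grow_disease_modules(
            network, catalog, module_iterations, module_cache
        )
    config = propagation.PropagationConfig(alpha=alpha)
    aurocs = []
    for target in sample:
        sub = propagation.build_target_subnetwork(
            network, {target}, config, top_k=top_k, include_neighbors=include_neighbors
        )
        ranking = enrichment.rank_indications(
            network, sub, catalog, variant=variant,
            module_iterations=module_iterations, modules=modules,
        )
        aurocs.append(auroc(ranking, positives))
    return aurocs
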