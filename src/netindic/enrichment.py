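"""Target-disease subnetwork enrichment and indication ranking.

The association between a target subnetwork T and a disease subnetwork D is
scored by the hypergeometric upper tail of their node overlap: the
probability of sharing at least |T ∩ D| nodes when |D| nodes are drawn from
a universe (all nodes of the filtered interactome) containing |T| marked
nodes.  P-values are Holm-adjusted across diseases, then converted to the
ranking metric

    Metric = Pval / log2(N + 1)   if Pval < 1
           = 1                    if Pval = 1

where N is the disease's number of genetically associated genes, so that
diseases whose modules rest on more genetic evidence are favoured at equal
significance.  Diseases are sorted by the metric ascending; the inverse of
a disease's rank is its final association score.

The weighted ("improved") variant counts every genetically associated gene
twice: the disease set, the overlap, and the universe are each enlarged by
the seed nodes before the same hypergeometric construction is applied, so a
target subnetwork that hits the genetic core of a disease module scores
more strongly than one that only grazes its periphery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .disease_module import ExpansionTrace, diamond_expand
from .graph_io import DiseaseCatalog, deduplicate_by_mesh
from .propagation import Subnetwork

#: Columns of an indication-ranking table.
RANKING_COLUMNS = (
    "rank", "disease_id", "disease_name", "mesh_id",
    "n_seeds", "pvalue", "fdr", "metric", "score",
)


def _check_sets(target_sub: Subnetwork, disease_sub: Subnetwork, universe_size: int) -> None:
    if len(target_sub.nodes) == 0:
        raise ValueError("target subnetwork is empty")
    if len(disease_sub.nodes) == 0:
        raise ValueError("disease subnetwork is empty")
    if universe_size < len(target_sub.nodes | disease_sub.nodes):
        raise ValueError("universe smaller than the union of the two subnetworks")


def overlap_pvalue(target_sub: Subnetwork, disease_sub: Subnetwork, universe_size: int) -> float:
    """Upper-tail hypergeometric probability of the observed node overlap."""
    _check_sets(target_sub, disease_sub, universe_size)
    k = len(target_sub.nodes & disease_sub.nodes)
    return float(
        hypergeom.sf(k - 1, universe_size, len(target_sub.nodes), len(disease_sub.nodes))
    )


def weighted_overlap_pvalue(
    target_sub: Subnetwork, disease_sub: Subnetwork, universe_size: int
) -> float:
    """Overlap p-value with every disease seed gene counted as two nodes.

    The virtual duplication enlarges the disease draw by the number of
    seeds, the overlap by the seeds also hit by the target subnetwork, and
    the universe by the number of duplicated nodes.  With no designated
    seeds this reduces exactly to :func:`overlap_pvalue`.
    """
    _check_sets(target_sub, disease_sub, universe_size)
    seeds = disease_sub.origins & disease_sub.nodes
    draws = len(disease_sub.nodes) + len(seeds)
    k = len(target_sub.nodes & disease_sub.nodes) + len(target_sub.nodes & seeds)
    return float(
        hypergeom.sf(k - 1, universe_size + len(seeds), len(target_sub.nodes), draws)
    )


def holm_adjust(pvalues) -> list[float]:
    """Holm step-down adjusted values, returned in the input order."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    return multipletests(pvalues, method="holm")[1].tolist()


def ranking_metric(pvalue: float, n_seeds: int) -> float:
    """Seed-count-adjusted ranking metric: Pval / log2(N + 1), or 1 at Pval = 1."""
    if not 0.0 <= pvalue <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {pvalue}")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1 (log2(N + 1) would vanish)")
    if pvalue >= 1.0:
        return 1.0
    return pvalue / math.log2(n_seeds + 1)


@dataclass
class _DiseaseResult:
    entry_id: str
    pvalue: float


def grow_disease_modules(
    network: nx.Graph,
    catalog: DiseaseCatalog,
    module_iterations: int = 200,
    cache: dict | None = None,
) -> dict[str, ExpansionTrace]:
    """Grow (or fetch from cache) the disease module of every catalog entry.

    Modules depend only on the network, the seed set, and the iteration
    count — not on any target — so they are shared across targets.
    """
    traces: dict[str, ExpansionTrace] = {}
    for entry in catalog:
        key = (frozenset(entry.seed_genes), module_iterations)
        if cache is not None and key in cache:
            traces[entry.disease_id] = cache[key]
            continue
        trace = diamond_expand(network, entry.seed_genes, module_iterations)
        traces[entry.disease_id] = trace
        if cache is not None:
            cache[key] = trace
    return traces


def rank_indications(
    network: nx.Graph,
    target_sub: Subnetwork,
    catalog: DiseaseCatalog,
    variant: str = "plain",
    module_iterations: int = 200,
    metric_on: str = "raw",
    deduplicate: bool = True,
    module_cache: dict | None = None,
    modules: dict[str, ExpansionTrace] | None = None,
) -> pd.DataFrame:
    """Rank every catalog disease for the target subnetwork.

    Parameters
    ----------
    variant:
        ``"plain"`` for the equal-weight overlap test, ``"weighted"`` to
        count genetic seed genes twice.
    metric_on:
        ``"raw"`` (default) feeds raw p-values into the metric; the
        Holm-adjusted values are reported in the ``fdr`` column either way.
        ``"adjusted"`` feeds the adjusted values instead.
    modules:
        Pre-grown disease modules (from :func:`grow_disease_modules`);
        grown on demand if omitted.

    Returns a table with one row per disease (one per MeSH id if
    ``deduplicate``), sorted by the metric ascending with dense ranks and
    inverse-rank association scores.
    """
    if variant not in {"plain", "weighted"}:
        raise ValueError(f"unknown variant {variant!r}")
    if metric_on not in {"raw", "adjusted"}:
        raise ValueError(f"unknown metric_on {metric_on!r}")
    if len(catalog) == 0:
        raise ValueError("disease catalog is empty")

    if modules is None:
        modules = grow_disease_modules(network, catalog, module_iterations, module_cache)
    universe = network.number_of_nodes()
    test = overlap_pvalue if variant == "plain" else weighted_overlap_pvalue

    rows = []
    for entry in catalog:
        disease_sub = modules[entry.disease_id].subnetwork
        p = test(target_sub, disease_sub, universe)
        rows.append({
            "disease_id": entry.disease_id,
            "disease_name": entry.name,
            "mesh_id": entry.mesh_id,
            "n_seeds": entry.n_seeds,
            "pvalue": p,
        })
    frame = pd.DataFrame(rows)
    frame["fdr"] = holm_adjust(frame["pvalue"])
    basis = frame["pvalue"] if metric_on == "raw" else frame["fdr"]
    frame["metric"] = [
        ranking_metric(p, n) for p, n in zip(basis, frame["n_seeds"])
    ]
    frame = frame.sort_values(
        ["metric", "pvalue", "disease_id"], kind="stable"
    ).reset_index(drop=True)
    frame["rank"] = range(1, len(frame) + 1)
    frame["score"] = 1.0 / frame["rank"]
    frame = frame[list(RANKING_COLUMNS)]
    if deduplicate:
        frame = deduplicate_by_mesh(frame)
    return frame
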