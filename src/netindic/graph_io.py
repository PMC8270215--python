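"""Readers and preprocessing for interaction networks and gene-disease catalogs.

The interactome is an undirected, confidence-weighted protein-interaction
graph in the STRING protein-links dialect (two node columns plus a combined
score, whitespace- or tab-delimited).  Disease seed sets come from a
DisGeNET-style export: one row per gene-disease association, with a MeSH
identifier used downstream to deduplicate redundant disease terms.

Preprocessing rules applied here:

* edges are kept only if their confidence is *strictly greater* than the
  threshold (scores on a 0-1000 scale are normalised to [0, 1] first);
* self-loops are removed and symmetric duplicates collapsed;
* disease entries are dropped if they lack a MeSH id, and their seed sets
  are intersected with the network's nodes; entries left with fewer than
  ``min_seeds`` surviving seeds are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns required in a disease-association table.
DISEASE_COLUMNS = ("geneSymbol", "diseaseId", "diseaseName", "meshId", "score")


@dataclass(frozen=True)
class DiseaseEntry:
    """One disease with its genetically associated seed genes."""

    disease_id: str
    name: str
    mesh_id: str | None
    seed_genes: frozenset[str]
    gene_scores: dict[str, float]  # gene -> association score in [0, 1]

    @property
    def n_seeds(self) -> int:
        return len(self.seed_genes)


@dataclass
class CatalogReport:
    """Bookkeeping for catalog filtering: how many entries survived and why
    the rest were dropped."""

    rows_read: int = 0
    diseases_seen: int = 0
    kept: int = 0
    dropped_no_mesh: int = 0
    dropped_few_seeds: int = 0


@dataclass
class DiseaseCatalog:
    """Per-disease seed-gene sets keyed by disease id."""

    entries: dict[str, DiseaseEntry] = field(default_factory=dict)
    report: CatalogReport | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def __getitem__(self, disease_id: str) -> DiseaseEntry:
        return self.entries[disease_id]

    def __contains__(self, disease_id: str) -> bool:
        return disease_id in self.entries


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_interactions(
    path,
    score_threshold: float = 0.7,
    score_scale: str = "auto",
) -> nx.Graph:
    """Read a STRING-dialect edge list and keep high-confidence edges.

    Parameters
    ----------
    path:
        Whitespace/tab-delimited file with two node columns and a numeric
        confidence column.  A header line is auto-detected and skipped.
    score_threshold:
        Confidence cut in [0, 1]; edges with score strictly greater than the
        cut are kept.
    score_scale:
        ``"0-1"``, ``"0-1000"``, or ``"auto"``.  STRING ships combined
        scores on 0-1000; auto-detection divides by 1000 when any score
        exceeds 1.

    Returns
    -------
    networkx.Graph
        Undirected graph with ``weight`` edge attributes in [0, 1].  Nodes
        with no surviving edge are absent.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    if score_scale not in {"auto", "0-1", "0-1000"}:
        raise ValueError(f"unknown score_scale {score_scale!r}")

    rows: list[tuple[str, str, float]] = []
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 columns, got {len(parts)}"
                )
            if lineno == 1 and not _looks_numeric(parts[2]):
                continue  # header
            if not _looks_numeric(parts[2]):
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric score {parts[2]!r}"
                )
            n_rows += 1
            rows.append((parts[0], parts[1], float(parts[2])))

    if not rows:
        raise ValueError(f"{path}: no interaction rows found")

    if score_scale == "auto":
        scale = 1000.0 if any(s > 1.0 for _, _, s in rows) else 1.0
    else:
        scale = 1000.0 if score_scale == "0-1000" else 1.0

    graph = nx.Graph()
    for a, b, score in rows:
        if a == b:
            continue
        w = score / scale
        if w > score_threshold:
            # symmetric duplicates collapse; keep the larger confidence
            if graph.has_edge(a, b):
                graph[a][b]["weight"] = max(graph[a][b]["weight"], w)
            else:
                graph.add_edge(a, b, weight=w)

    if graph.number_of_edges() == 0:
        raise ValueError(
            f"{path}: no edges survive threshold {score_threshold} — empty network"
        )
    logger.info(
        "read_interactions: %d rows read, %d nodes / %d edges kept (threshold %g)",
        n_rows, graph.number_of_nodes(), graph.number_of_edges(), score_threshold,
    )
    return graph


def read_disease_catalog(
    path,
    network: nx.Graph,
    min_seeds: int = 1,
) -> DiseaseCatalog:
    """Read a DisGeNET-style gene-disease table and build the catalog.

    Seed sets are intersected with the network's nodes; entries without a
    MeSH id or with fewer than ``min_seeds`` surviving seeds are dropped
    (and counted in the returned catalog's report).
    """
    if min_seeds < 1:
        raise ValueError("min_seeds must be >= 1")
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in DISEASE_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    table["score"] = table["score"].astype(float)
    bad = ~table["score"].between(0.0, 1.0)
    if bad.any():
        raise ValueError(
            f"{path}: {int(bad.sum())} association scores outside [0, 1]"
        )

    report = CatalogReport(rows_read=len(table))
    nodes = set(network.nodes)
    entries: dict[str, DiseaseEntry] = {}
    for disease_id, group in table.groupby("diseaseId", sort=True):
        report.diseases_seen += 1
        mesh = group["meshId"].iloc[0]
        if pd.isna(mesh) or str(mesh).strip() == "":
            report.dropped_no_mesh += 1
            continue
        scores = {
            g: float(s)
            for g, s in zip(group["geneSymbol"], group["score"])
            if g in nodes
        }
        if len(scores) < min_seeds:
            report.dropped_few_seeds += 1
            continue
        entries[str(disease_id)] = DiseaseEntry(
            disease_id=str(disease_id),
            name=str(group["diseaseName"].iloc[0]),
            mesh_id=str(mesh),
            seed_genes=frozenset(scores),
            gene_scores=scores,
        )
        report.kept += 1

    logger.info(
        "read_disease_catalog: %d rows, %d diseases kept, %d dropped (no MeSH), "
        "%d dropped (<%d seeds in network)",
        report.rows_read, report.kept, report.dropped_no_mesh,
        report.dropped_few_seeds, min_seeds,
    )
    return DiseaseCatalog(entries=entries, report=report)


def deduplicate_by_mesh(ranking: pd.DataFrame, catalog: DiseaseCatalog | None = None) -> pd.DataFrame:
    """Keep the best-ranked disease per MeSH id and re-rank densely.

    Many catalog entries can share one MeSH id; only the entry with the
    smallest rank survives.  Relative order is preserved, ranks are
    reassigned 1..K, and the inverse-rank association score is recomputed.
    """
    if ranking.empty:
        return ranking.copy()
    frame = ranking.sort_values("rank", kind="stable").copy()
    if catalog is not None and "mesh_id" not in frame.columns:
        frame["mesh_id"] = [
            catalog[d].mesh_id if d in catalog else None for d in frame["disease_id"]
        ]
    seen: set[str] = set()
    keep = []
    for mesh in frame["mesh_id"]:
        if mesh is None or (isinstance(mesh, float) and math.isnan(mesh)):
            keep.append(True)  # no key: nothing to deduplicate against
            continue
        keep.append(mesh not in seen)
        seen.add(mesh)
    out = frame[pd.Series(keep, index=frame.index)].copy()
    out["rank"] = range(1, len(out) + 1)
    if "score" in out.columns:
        out["score"] = 1.0 / out["rank"]
    return out.reset_index(drop=True)
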