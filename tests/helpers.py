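"""Independent oracles used across the test suite.

Everything here is deliberately naive — exhaustive enumeration, brute-force
BFS, rescan-everything module growth — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import math
from collections import deque

import networkx as nx


def hyper_tail_exact(k: int, population: int, marked: int, draws: int) -> float:
    """P(X >= k) for a hypergeometric draw, by exact enumeration."""
    total = math.comb(population, draws)
    acc = 0
    for i in range(max(k, 0), min(marked, draws) + 1):
        acc += math.comb(marked, i) * math.comb(population - marked, draws - i)
    return acc / total


def bfs_distances(graph: nx.Graph, source) -> dict:
    """Plain queue-based BFS hop counts from one source."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in graph.neighbors(v):
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def diamond_naive(graph: nx.Graph, seeds, n_iterations: int):
    """Rescan-everything DIAMOnD: recompute every candidate's tail each round."""
    current = set(seeds)
    added = []
    n = graph.number_of_nodes()
    for iteration in range(1, n_iterations + 1):
        candidates = sorted(
            v for v in graph.nodes
            if v not in current and any(u in current for u in graph.neighbors(v))
        )
        if not candidates:
            break
        best_node, best_p = None, None
        for c in candidates:
            k = sum(1 for u in graph.neighbors(c) if u in current)
            p = hyper_tail_exact(k, n - 1, len(current), graph.degree(c))
            if best_p is None or p < best_p:
                best_node, best_p = c, p
        added.append((best_node, best_p, iteration))
        current.add(best_node)
    return added, current


def auroc_pairs(ranking, positives) -> float:
    """AUROC by exhaustive concordant-pair counting over a ranking table."""
    pos = ranking[ranking["disease_id"].isin(set(positives))]["rank"].tolist()
    neg = ranking[~ranking["disease_id"].isin(set(positives))]["rank"].tolist()
    wins = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_graph(n: int, p: float, seed: int, prefix: str = "N") -> nx.Graph:
    """Erdos-Renyi graph with string node ids and no isolated nodes."""
    raw = nx.gnp_random_graph(n, p, seed=seed)
    raw.remove_nodes_from([v for v, d in raw.degree() if d == 0])
    if raw.number_of_edges() == 0:
        raw.add_edge(0, 1)
    width = len(str(n))
    return nx.relabel_nodes(raw, {v: f"{prefix}{v:0{width}d}" for v in raw.nodes})
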