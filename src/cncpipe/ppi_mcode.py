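"""Score-thresholded PPI subnetwork, degree hubs, and MCODE-style dense
module detection.

The module detector follows the classic three phases: (1) vertex weighting
by the density of the highest k-core of each vertex's closed neighborhood
times that core number; (2) greedy complex growth from the highest-weight
unassigned seed, admitting neighbors whose weight is within the node-score
cutoff of the seed's; (3) haircut post-processing (2-core of each complex).
Cluster score is density x node count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .io_formats import PPIEdgeTable

__all__ = ["McodeCluster", "build_ppi", "degree_hubs", "mcode_clusters", "graph_density"]


@dataclass(frozen=True)
class McodeCluster:
    members: frozenset[str]
    seed: str
    score: float


def build_ppi(
    edge_table: PPIEdgeTable,
    gene_universe: Iterable[str] | None = None,
    score_min: float = 0.7,
) -> nx.Graph:
    """Simple undirected graph of edges with confidence >= ``score_min`` and
    both endpoints inside ``gene_universe`` (no restriction when None).
    Isolated nodes never enter the graph."""
    universe = set(gene_universe) if gene_universe is not None else None
    g = nx.Graph()
    for a, b, s in edge_table.edges:
        if s < score_min:
            continue
        if universe is not None and (a not in universe or b not in universe):
            continue
        if g.has_edge(a, b):
            # keep the highest confidence on duplicate rows
            g[a][b]["confidence"] = max(g[a][b]["confidence"], s)
        else:
            g.add_edge(a, b, confidence=s)
    return g


def degree_hubs(graph: nx.Graph, min_degree: int = 5) -> list[tuple[str, int]]:
    """Nodes with degree >= min_degree, degree descending then name."""
    hubs = [(n, d) for n, d in graph.degree() if d >= min_degree]
    hubs.sort(key=lambda nd: (-nd[1], nd[0]))
    return hubs


def graph_density(graph: nx.Graph) -> float:
    """2E / (V(V-1)) for a simple undirected graph; 0 for < 2 nodes."""
    v = graph.number_of_nodes()
    if v < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (v * (v - 1))


def _vertex_weights(graph: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    weights: dict[str, float] = {}
    for v in graph.nodes:
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(set(graph.neighbors(v)) | {v})
        core_numbers = nx.core_number(nbhd)
        k_max = max(core_numbers.values())
        core = nbhd.subgraph([u for u, k in core_numbers.items() if k >= k_max])
        weights[v] = k_max * graph_density(core)
    return weights


def mcode_clusters(
    graph: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    score_min: float = 0.0,
    haircut: bool = True,
) -> list[McodeCluster]:
    """Detect dense modules; vertices belong to at most one cluster.

    Returns clusters with score strictly greater than ``score_min``,
    sorted by score descending then seed name.
    """
    if any(u == v for u, v in graph.edges):
        raise ValueError("graph must be simple (no self-loops)")
    weights = _vertex_weights(graph, degree_cutoff)
    assigned: set[str] = set()
    clusters: list[McodeCluster] = []
    for seed in sorted(graph.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        while frontier:
            u = frontier.pop()
            for w in graph.neighbors(u):
                if w in members or w in assigned:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    frontier.append(w)
        sub = graph.subgraph(members)
        if haircut:
            sub = nx.k_core(sub, k_core)
            if sub.number_of_nodes() == 0:
                continue
            members = set(sub.nodes)
        if seed not in members:
            continue
        assigned |= members
        score = graph_density(sub) * sub.number_of_nodes()
        clusters.append(McodeCluster(frozenset(members), seed, score))
    clusters = [c for c in clusters if c.score > score_min]
    clusters.sort(key=lambda c: (-c.score, c.seed))
    return clusters
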