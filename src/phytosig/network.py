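"""PPI graph construction and exhaustive k-clique enumeration.

A *k*-clique here is every fully connected subgraph of exactly *k* nodes, not
only the maximal ones — the union of members over all 3- and 4-cliques found
within a signature-induced subgraph is what feeds the enriched signature.
Enumeration orders vertices by degeneracy and extends each candidate clique
only into higher-ordered common neighbors, which keeps the search near-linear
on sparse PPI-like graphs while emitting each clique exactly once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .io import PPIEdgeList

logger = logging.getLogger(__name__)


@dataclass
class CliqueSet:
    k: int
    cliques: list[tuple[str, ...]]  # each sorted, no duplicates
    member_genes: set

    def __len__(self) -> int:
        return len(self.cliques)


def build_graph(edges: PPIEdgeList) -> nx.Graph:
    """Undirected simple graph from a validated, deduplicated edge list."""
    g = nx.Graph()
    g.add_edges_from(edges.edges)
    return g


def induced_subgraph(graph: nx.Graph, genes: Iterable[str]) -> nx.Graph:
    genes = set(genes)
    missing = genes - set(graph.nodes)
    if missing:
        logger.info("induced_subgraph: %d gene(s) absent from the graph", len(missing))
    return nx.Graph(graph.subgraph(genes & set(graph.nodes)))


def _degeneracy_order(graph: nx.Graph) -> list[str]:
    """Vertex order by repeated minimum-degree removal (ties by node name)."""
    degrees = {v: d for v, d in graph.degree()}
    remaining = set(graph.nodes)
    adj = {v: set(graph[v]) for v in graph.nodes}
    order = []
    import heapq

    heap = [(d, v) for v, d in degrees.items()]
    heapq.heapify(heap)
    while heap:
        d, v = heapq.heappop(heap)
        if v not in remaining or d != degrees[v]:
            continue
        order.append(v)
        remaining.discard(v)
        for u in adj[v]:
            if u in remaining:
                degrees[u] -= 1
                heapq.heappush(heap, (degrees[u], u))
    return order


def enumerate_k_cliques(graph: nx.Graph, k: int) -> CliqueSet:
    """All complete subgraphs of exactly size k, each emitted once, sorted."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if graph.number_of_nodes() < k:
        return CliqueSet(k, [], set())
    order = _degeneracy_order(graph)
    pos = {v: i for i, v in enumerate(order)}
    adj = {v: set(graph[v]) for v in graph.nodes}
    cliques: list[tuple[str, ...]] = []

    def extend(clique: list[str], candidates: set[str]) -> None:
        if len(clique) == k:
            cliques.append(tuple(sorted(clique)))
            return
        for v in sorted(candidates, key=pos.__getitem__):
            extend(clique + [v], {u for u in candidates & adj[v] if pos[u] > pos[v]})

    for v in order:
        higher = {u for u in adj[v] if pos[u] > pos[v]}
        extend([v], higher)
    cliques.sort()
    members = {g for c in cliques for g in c}
    return CliqueSet(k, cliques, members)


def clique_member_genes(*clique_sets: CliqueSet) -> list[str]:
    """Sorted union of member genes across clique sets (typically k=3 and k=4)."""
    members: set[str] = set()
    for cs in clique_sets:
        members |= cs.member_genes
    return sorted(members)


def signature_clique_genes(
    graph: nx.Graph, genes: Sequence[str], k_values: Sequence[int] = (3, 4)
) -> tuple[dict[int, CliqueSet], list[str]]:
    """Convenience: induce the signature subgraph and enumerate each k."""
    sub = induced_subgraph(graph, genes)
    sets = {k: enumerate_k_cliques(sub, k) for k in k_values}
    return sets, clique_member_genes(*sets.values())
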