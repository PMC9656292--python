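"""Bipartite miR-gene regulatory networks: centralities, communities, selection.

The network is the largest connected component of the bipartite graph built
from significant interactions restricted to one subtype's DE genes.  Nodes
are ranked by closeness and radiality; overlapping communities come from a
maximal-clique agglomeration scheme.  Because bipartite graphs are
triangle-free (maximal cliques are edges), community detection defaults to
running on the one-mode weighted projections and joining members back
through their bipartite neighbors; the direct mode is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from mirsubnet.io_core import get_logger
from mirsubnet.interaction_inference import InteractionRecord

log = get_logger("network")


@dataclass
class RegulatoryNetwork:
    graph: nx.Graph
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        for u, v in self.graph.edges():
            ku, kv = self.graph.nodes[u].get("kind"), self.graph.nodes[v].get("kind")
            if {ku, kv} != {"miR", "gene"}:
                raise ValueError(f"non-bipartite edge {u!r}-{v!r} ({ku}, {kv})")
        if self.graph.number_of_nodes() > 1 and not nx.is_connected(self.graph):
            raise ValueError("network must be a single connected component")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes())

    def kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]


@dataclass
class CentralityRecord:
    node_id: str
    degree: int
    closeness: float
    radiality: float
    rank_closeness: int
    rank_radiality: int


@dataclass
class CommunitySet:
    communities: list[set[str]]
    clique_size_threshold: int
    complex_size_threshold: int

    def __post_init__(self) -> None:
        for c in self.communities:
            if len(c) < self.complex_size_threshold:
                raise ValueError("community below complex size threshold")


def build_network(
    interactions: Sequence[InteractionRecord],
    de_genes: Optional[Iterable[str]] = None,
    subtype: Optional[str] = None,
) -> RegulatoryNetwork:
    """Bipartite graph from interactions, keeping the largest component.

    ``de_genes`` restricts the gene side (the subtype's DE genes).  Component
    ties break by node count, then by the lexicographically smallest member.
    """
    if not interactions:
        raise ValueError("empty interaction list")
    de_set = set(de_genes) if de_genes is not None else None
    g = nx.Graph()
    for rec in interactions:
        if de_set is not None and rec.gene_id not in de_set:
            continue
        g.add_node(rec.mir_id, kind="miR")
        g.add_node(rec.gene_id, kind="gene")
        g.add_edge(rec.mir_id, rec.gene_id,
                   coefficient=rec.coefficient, perm_p=rec.perm_p)
    if g.number_of_nodes() == 0:
        raise ValueError("no interactions left after DE-gene restriction")
    components = sorted(nx.connected_components(g),
                        key=lambda c: (-len(c), min(c)))
    largest = components[0]
    if len(components) > 1:
        log.info("build_network: kept component with %d of %d nodes",
                 len(largest), g.number_of_nodes())
    return RegulatoryNetwork(g.subgraph(largest).copy(), subtype=subtype)


def closeness(network: RegulatoryNetwork, node: str) -> float:
    """(n-1) / sum of shortest-path distances from node (unit edge lengths)."""
    g = network.graph
    n = g.number_of_nodes()
    if n == 1:
        return 0.0
    dist = nx.single_source_shortest_path_length(g, node)
    return (n - 1) / sum(dist.values())


def radiality(network: RegulatoryNetwork, node: str) -> float:
    """sum over other nodes of (diameter + 1 - d(node, w)) / (n - 1)."""
    g = network.graph
    n = g.number_of_nodes()
    if n == 1:
        return 0.0
    diameter = nx.diameter(g)
    dist = nx.single_source_shortest_path_length(g, node)
    return sum(diameter + 1 - d for w, d in dist.items() if w != node) / (n - 1)


def centrality_table(network: RegulatoryNetwork) -> list[CentralityRecord]:
    """Closeness and radiality for every node with 1-based ranks.

    Ranks order by descending centrality; ties break by descending degree,
    then node id, making the ranks a permutation.
    """
    g = network.graph
    n = g.number_of_nodes()
    diameter = nx.diameter(g) if n > 1 else 0
    rows = []
    for node in g.nodes():
        dist = nx.single_source_shortest_path_length(g, node)
        total = sum(dist.values())
        clo = (n - 1) / total if n > 1 and total > 0 else 0.0
        rad = (sum(diameter + 1 - d for w, d in dist.items() if w != node) / (n - 1)
               if n > 1 else 0.0)
        rows.append((node, g.degree(node), clo, rad))
    by_clo = sorted(rows, key=lambda r: (-r[2], -r[1], r[0]))
    by_rad = sorted(rows, key=lambda r: (-r[3], -r[1], r[0]))
    rank_clo = {r[0]: i + 1 for i, r in enumerate(by_clo)}
    rank_rad = {r[0]: i + 1 for i, r in enumerate(by_rad)}
    return [
        CentralityRecord(node, deg, clo, rad, rank_clo[node], rank_rad[node])
        for node, deg, clo, rad in rows
    ]


# ---------------------------------------------------------------------------
# Clique-agglomeration (EAGLE-style) communities
# ---------------------------------------------------------------------------

def eagle_communities_graph(
    g: nx.Graph,
    clique_size_threshold: int = 3,
    complex_size_threshold: int = 2,
    merge_threshold: float = 0.5,
) -> list[set[str]]:
    """Overlapping communities by agglomerating maximal cliques.

    Maximal cliques of size >= ``clique_size_threshold`` seed the
    communities; nodes covered only by smaller cliques join as subordinate
    singletons.  The pair with the highest similarity — shared-node count
    over the smaller community size — is merged while that similarity
    exceeds ``merge_threshold``.  Communities smaller than
    ``complex_size_threshold`` are discarded at the end.
    """
    if g.number_of_nodes() == 0:
        return []
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    seeds = [set(c) for c in cliques if len(c) >= clique_size_threshold]
    covered = set().union(*seeds) if seeds else set()
    subordinate = [{v} for v in sorted(set(g.nodes()) - covered)]
    communities = seeds + subordinate

    def similarity(a: set, b: set) -> float:
        return len(a & b) / min(len(a), len(b))

    while len(communities) > 1:
        best, best_pair = 0.0, None
        for i in range(len(communities)):
            for j in range(i + 1, len(communities)):
                s = similarity(communities[i], communities[j])
                if s > best:
                    best, best_pair = s, (i, j)
        if best_pair is None or best <= merge_threshold:
            break
        i, j = best_pair
        merged = communities[i] | communities[j]
        communities = [c for idx, c in enumerate(communities) if idx not in (i, j)]
        communities.append(merged)
    # drop duplicates and undersized communities
    out, seen = [], set()
    for c in communities:
        key = frozenset(c)
        if len(c) >= complex_size_threshold and key not in seen:
            seen.add(key)
            out.append(set(c))
    return out


def _weighted_projection(g: nx.Graph, nodes: Iterable[str]) -> nx.Graph:
    """One-mode projection: two same-side nodes link when they share a neighbor."""
    nodes = list(nodes)
    proj = nx.Graph()
    proj.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        nu = set(g.neighbors(u))
        for v in nodes[i + 1:]:
            shared = len(nu & set(g.neighbors(v)))
            if shared:
                proj.add_edge(u, v, weight=shared)
    return proj


def eagle_communities(
    network: RegulatoryNetwork,
    clique_size_threshold: int = 3,
    complex_size_threshold: int = 2,
    merge_threshold: float = 0.5,
    mode: str = "projection",
) -> CommunitySet:
    """Communities of a regulatory network.

    ``projection`` (default) detects communities on the union of the two
    one-mode projections (where cliques exist), then joins each community
    back to the bipartite graph by adding opposite-side neighbors adjacent
    to at least two members (or one, for two-node communities).
    ``bipartite`` runs the clique agglomeration on the graph directly; being
    triangle-free, its maximal cliques are single edges.
    """
    g = network.graph
    if mode == "bipartite":
        comms = eagle_communities_graph(
            g, clique_size_threshold, complex_size_threshold, merge_threshold)
    elif mode == "projection":
        proj = nx.Graph()
        for kind in ("miR", "gene"):
            side = [v for v in g.nodes() if g.nodes[v]["kind"] == kind]
            proj = nx.compose(proj, _weighted_projection(g, side))
        proj_comms = eagle_communities_graph(
            proj, clique_size_threshold, complex_size_threshold, merge_threshold)
        comms = []
        for c in proj_comms:
            need = 2 if len(c) > 2 else 1
            joined = set(c)
            for v in g.nodes():
                if v in joined:
                    continue
                if sum(1 for w in g.neighbors(v) if w in c) >= need:
                    joined.add(v)
            comms.append(joined)
    else:
        raise ValueError("mode must be 'projection' or 'bipartite'")
    comms = [c for c in comms if len(c) >= complex_size_threshold]
    log.info("eagle_communities(%s): %d communities", mode, len(comms))
    return CommunitySet(comms, clique_size_threshold, complex_size_threshold)


def select_candidates(
    network: RegulatoryNetwork,
    centralities: Sequence[CentralityRecord],
    communities: CommunitySet | None,
    top_central: int = 20,
) -> list[tuple[str, str]]:
    """Candidate edges from the top-central nodes and the most relevant community.

    The top-central node set is the intersection of the top-k lists by
    closeness and by radiality, padded back to size k by closeness rank.
    Selected edges are (a) edges with both endpoints in that set and (b)
    edges internal to the community with the highest mean member closeness
    (tie: larger community).  miR-first, deduplicated, sorted.
    """
    g = network.graph
    k = min(top_central, g.number_of_nodes())
    by_clo = sorted(centralities, key=lambda r: r.rank_closeness)
    by_rad = sorted(centralities, key=lambda r: r.rank_radiality)
    top_clo = [r.node_id for r in by_clo[:k]]
    top_rad = {r.node_id for r in by_rad[:k]}
    chosen = [n for n in top_clo if n in top_rad]
    for r in by_clo:
        if len(chosen) >= k:
            break
        if r.node_id not in chosen:
            chosen.append(r.node_id)
    chosen_set = set(chosen)

    def as_pair(u: str, v: str) -> tuple[str, str]:
        return (u, v) if network.kind(u) == "miR" else (v, u)

    selected = {as_pair(u, v) for u, v in g.edges()
                if u in chosen_set and v in chosen_set}

    if communities is not None and communities.communities:
        clo_of = {r.node_id: r.closeness for r in centralities}
        best = max(
            communities.communities,
            key=lambda c: (float(np.mean([clo_of.get(v, 0.0) for v in c])), len(c)),
        )
        selected |= {as_pair(u, v) for u, v in g.edges()
                     if u in best and v in best}
    return sorted(selected)
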