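import itertools

import networkx as nx
import numpy as np
import pytest

from mirsubnet.interaction_inference import InteractionRecord
from mirsubnet.network_analysis import (
    CommunitySet,
    RegulatoryNetwork,
    build_network,
    centrality_table,
    closeness,
    eagle_communities,
    eagle_communities_graph,
    radiality,
    select_candidates,
)


def rec(mir, gene):
    return InteractionRecord(mir, gene, -0.5, 0.01)


def bipartite_net(edges):
    return build_network([rec(m, g) for m, g in edges])


def bfs_distances(adj, source):
    """Brute-force BFS oracle independent of networkx."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def random_connected_bipartite(rng, n_mirs, n_genes, p):
    while True:
        edges = [(f"m{i}", f"g{j}") for i in range(n_mirs)
                 for j in range(n_genes) if rng.random() < p]
        if not edges:
            continue
        g = nx.Graph(edges)
        if nx.is_connected(g) and g.number_of_nodes() >= 4:
            return edges


class TestBuildNetwork:
    def test_largest_component_retained(self):
        net = bipartite_net([
            ("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2"),  # 4 nodes
            ("m9", "g9"),  # 2 nodes
        ])
        assert set(net.nodes) == {"m1", "m2", "g1", "g2"}

    def test_single_edge_network(self):
        net = bipartite_net([("m1", "g1")])
        assert set(net.nodes) == {"m1", "g1"}
        assert net.kind("m1") == "miR"
        assert net.kind("g1") == "gene"

    def test_component_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            edges = [(f"m{rng.integers(6)}", f"g{rng.integers(6)}")
                     for _ in range(rng.integers(3, 15))]
            net = build_network([rec(m, g) for m, g in set(edges)])
            # oracle: grow components by repeated scanning
            nodes = {n for e in edges for n in e}
            comps = []
            unseen = set(nodes)
            adj = {n: set() for n in nodes}
            for m, g in edges:
                adj[m].add(g)
                adj[g].add(m)
            while unseen:
                start = min(unseen)
                comp = set(bfs_distances(adj, start))
                comps.append(comp)
                unseen -= comp
            expected = sorted(comps, key=lambda c: (-len(c), min(c)))[0]
            assert set(net.nodes) == expected

    def test_de_gene_restriction(self):
        records = [rec("m1", "g1"), rec("m1", "g2"), rec("m2", "g2")]
        net = build_network(records, de_genes={"g2"})
        assert set(net.nodes) == {"m1", "m2", "g2"}

    def test_empty_interactions_rejected(self):
        with pytest.raises(ValueError):
            build_network([])

    def test_empty_after_restriction_rejected(self):
        with pytest.raises(ValueError, match="restriction"):
            build_network([rec("m1", "g1")], de_genes={"gX"})

    def test_bipartiteness_enforced(self):
        g = nx.Graph()
        g.add_node("a", kind="miR")
        g.add_node("b", kind="miR")
        g.add_edge("a", "b")
        with pytest.raises(ValueError, match="bipartite"):
            RegulatoryNetwork(g)


class TestCentralities:
    def test_star_center_closeness_one(self):
        net = bipartite_net([("m1", "g1"), ("m1", "g2"), ("m1", "g3")])
        assert closeness(net, "m1") == pytest.approx(1.0)
        assert closeness(net, "g1") == pytest.approx(3 / 5)

    def test_path_closeness_hand_values(self):
        net = bipartite_net([("m1", "g1"), ("m2", "g1")])  # path m1-g1-m2
        assert closeness(net, "g1") == pytest.approx(1.0)
        assert closeness(net, "m1") == pytest.approx(2 / 3)

    def test_path_radiality_hand_values(self):
        net = bipartite_net([("m1", "g1"), ("m2", "g1")])  # diameter 2
        assert radiality(net, "g1") == pytest.approx(2.0)
        assert radiality(net, "m1") == pytest.approx(1.5)

    def test_complete_bipartite_symmetry(self):
        # K_{2,2} is vertex-transitive: all closeness equal, all radiality equal
        net = bipartite_net([("m1", "g1"), ("m1", "g2"),
                             ("m2", "g1"), ("m2", "g2")])
        cents = centrality_table(net)
        assert len({round(c.closeness, 12) for c in cents}) == 1
        assert len({round(c.radiality, 12) for c in cents}) == 1

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            edges = random_connected_bipartite(rng, 4, 5, 0.45)
            net = bipartite_net(edges)
            adj = {n: set() for e in edges for n in e}
            for m, g in edges:
                adj[m].add(g)
                adj[g].add(m)
            n = len(adj)
            diam = max(max(bfs_distances(adj, s).values()) for s in adj)
            for node in adj:
                dist = bfs_distances(adj, node)
                clo_oracle = (n - 1) / sum(dist.values())
                rad_oracle = sum(diam + 1 - d for w, d in dist.items()
                                 if w != node) / (n - 1)
                assert closeness(net, node) == pytest.approx(clo_oracle)
                assert radiality(net, node) == pytest.approx(rad_oracle)

    def test_ranks_are_permutations(self):
        rng = np.random.default_rng(2)
        net = bipartite_net(random_connected_bipartite(rng, 5, 6, 0.4))
        cents = centrality_table(net)
        n = len(cents)
        assert sorted(c.rank_closeness for c in cents) == list(range(1, n + 1))
        assert sorted(c.rank_radiality for c in cents) == list(range(1, n + 1))

    def test_rankings_agree_on_vertex_transitive_graph(self):
        net = bipartite_net([(f"m{i}", f"g{j}")
                             for i in range(3) for j in range(3)])
        cents = centrality_table(net)
        assert all(c.rank_closeness == c.rank_radiality for c in cents)


class TestEagleCommunities:
    def test_triangle_single_community(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        comms = eagle_communities_graph(g, 3, 2)
        assert comms == [{"a", "b", "c"}]

    def test_two_triangles_sharing_vertex(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("c", "d"), ("d", "e"), ("c", "e")])
        comms = eagle_communities_graph(g, 3, 2)
        assert len(comms) == 2
        assert {"a", "b", "c"} in comms and {"c", "d", "e"} in comms
        # overlap at the shared vertex
        assert set.intersection(*map(set, comms)) == {"c"}

    def test_qualifying_maximal_cliques_contained(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = nx.gnp_random_graph(rng.integers(5, 11), 0.5,
                                    seed=int(rng.integers(1 << 30)))
            comms = eagle_communities_graph(g, 3, 2)
            # exhaustive maximal clique enumeration oracle
            nodes = list(g.nodes())
            maximal = []
            for r in range(3, len(nodes) + 1):
                for cand in itertools.combinations(nodes, r):
                    if all(g.has_edge(u, v)
                           for u, v in itertools.combinations(cand, 2)):
                        cand = set(cand)
                        if not any(
                            cand < set(other) and all(
                                g.has_edge(u, v) for u, v in
                                itertools.combinations(other, 2))
                            for other in
                            (set(cand) | {x} for x in nodes if x not in cand)
                        ):
                            maximal.append(cand)
            for clique in maximal:
                assert any(clique <= c for c in comms), clique

    def test_min_community_size_enforced(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")])
        comms = eagle_communities_graph(g, 3, complex_size_threshold=3)
        assert all(len(c) >= 3 for c in comms)

    def test_bipartite_mode_on_mir_gene_graph(self):
        net = bipartite_net([("m1", "g1"), ("m1", "g2"),
                             ("m2", "g1"), ("m2", "g2")])
        cs = eagle_communities(net, mode="bipartite")
        assert all(len(c) >= 2 for c in cs.communities)
        all_nodes = set(net.nodes)
        assert all(c <= all_nodes for c in cs.communities)

    def test_projection_mode_groups_shared_targets(self):
        # m1, m2, m3 all regulate g1, g2, g3 -> one community with everything
        edges = [(f"m{i}", f"g{j}") for i in range(1, 4) for j in range(1, 4)]
        net = bipartite_net(edges)
        cs = eagle_communities(net, mode="projection")
        assert any(c == set(net.nodes) for c in cs.communities)

    def test_community_members_subset_of_network(self, small_cohort):
        net = bipartite_net([("m1", "g1"), ("m1", "g2"), ("m2", "g2"),
                             ("m3", "g2"), ("m3", "g3")])
        for mode in ("projection", "bipartite"):
            cs = eagle_communities(net, mode=mode)
            for c in cs.communities:
                assert c <= set(net.nodes)


class TestSelectCandidates:
    def test_star_top_pair_edges_selected(self):
        net = bipartite_net([("m1", "g1"), ("m1", "g2"), ("m1", "g3")])
        cents = centrality_table(net)
        selected = select_candidates(net, cents, None, top_central=2)
        # hub m1 plus its best leaf form the top pair; their edge is selected
        assert ("m1", "g1") in selected

    def test_no_communities_gives_top_central_edges_only(self):
        net = bipartite_net([("m1", "g1"), ("m1", "g2"),
                             ("m2", "g2"), ("m2", "g3")])
        cents = centrality_table(net)
        empty = CommunitySet([], 3, 2)
        a = select_candidates(net, cents, empty, top_central=3)
        b = select_candidates(net, cents, None, top_central=3)
        assert a == b

    def test_small_network_uses_all_nodes(self):
        net = bipartite_net([("m1", "g1"), ("m2", "g1")])
        cents = centrality_table(net)
        selected = select_candidates(net, cents, None, top_central=20)
        assert set(selected) == {("m1", "g1"), ("m2", "g1")}

    def test_community_edges_added(self):
        edges = [("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2"),
                 ("m3", "g3"), ("g3", "m1")]
        net = build_network([rec(m, g) if m.startswith("m") else rec(g, m)
                             for m, g in edges])
        cents = centrality_table(net)
        comms = eagle_communities(net, mode="projection")
        selected = select_candidates(net, cents, comms, top_central=2)
        only_top = select_candidates(net, cents, None, top_central=2)
        assert set(only_top) <= set(selected)

    def test_edges_are_mir_first(self):
        net = bipartite_net([("m1", "g1"), ("m2", "g1")])
        cents = centrality_table(net)
        for m, g in select_candidates(net, cents, None, 5):
            assert net.kind(m) == "miR" and net.kind(g) == "gene"
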