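import itertools

import networkx as nx
import numpy as np
import pytest

from coloc_longevity import (
    build_original_network,
    connected_components,
    detect_communities,
    ego_subnetwork,
    extend_network,
    make_genome_layout,
    node_degree,
    shared_nodes,
)
from coloc_longevity.network import ColocationNetwork, read_network_tsv, write_network_tsv

from conftest import contact_matrix_from_entries, flat_thresholds


@pytest.fixture
def layout():
    return make_genome_layout([("A", 800_000), ("B", 480_000)], 80_000)


def make_net(layout, nodes, edges, origins=None):
    g = nx.Graph()
    for n in nodes:
        g.add_node(n, origin=(origins or {}).get(n, "original"))
    g.add_weighted_edges_from(edges)
    return ColocationNetwork(graph=g, layout=layout)


class TestOriginalNetwork:
    def test_empty_significant_set(self, layout):
        cm = contact_matrix_from_entries(layout, {(1, 2): 5.0})
        net = build_original_network(set(), cm, flat_thresholds(layout, 1.0))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_isolated_nodes_retained(self, layout):
        tau = 4.0
        cm = contact_matrix_from_entries(layout, {(1, 2): 2 * tau, (1, 3): tau / 2})
        net = build_original_network({1, 2, 3}, cm, flat_thresholds(layout, tau))
        assert net.nodes == {1, 2, 3}
        assert net.n_edges == 1
        assert net.graph.has_edge(1, 2)
        assert node_degree(net)[3] == 0

    def test_edge_requires_strict_exceedance(self, layout):
        cm = contact_matrix_from_entries(layout, {(1, 2): 4.0})
        net = build_original_network({1, 2}, cm, flat_thresholds(layout, 4.0))
        assert net.n_edges == 0

    def test_inter_chromosomal_threshold_applies(self, layout):
        ts = flat_thresholds(layout, 100.0, tau_inter=1.0)
        cm = contact_matrix_from_entries(layout, {(1, 11): 2.0, (1, 2): 50.0})
        net = build_original_network({1, 2, 11}, cm, ts)
        assert net.graph.has_edge(1, 11)  # 2.0 > inter threshold 1.0
        assert not net.graph.has_edge(1, 2)  # 50 < intra threshold 100

    def test_sig_bin_outside_layout(self, layout):
        cm = contact_matrix_from_entries(layout, {(1, 2): 5.0})
        with pytest.raises(ValueError):
            build_original_network({99}, cm, flat_thresholds(layout, 1.0))


class TestExtendNetwork:
    def test_no_external_bin_passes(self, layout):
        tau = 1.0
        cm = contact_matrix_from_entries(layout, {(1, 2): 5.0})
        net = build_original_network({1, 2}, cm, flat_thresholds(layout, tau))
        ext = extend_network(net, cm, flat_thresholds(layout, tau))
        assert ext.nodes == net.nodes
        assert ext.n_edges == net.n_edges

    def test_added_node_with_two_links(self, layout):
        tau = 1.0
        cm = contact_matrix_from_entries(
            layout, {(1, 2): 5.0, (3, 1): 4.0, (3, 2): 3.0}
        )
        net = build_original_network({1, 2}, cm, flat_thresholds(layout, tau))
        ext = extend_network(net, cm, flat_thresholds(layout, tau))
        assert ext.nodes == {1, 2, 3}
        assert ext.origin(3) == "added"
        assert ext.origin(1) == "original"
        assert ext.n_edges == 3

    def test_added_added_edges_included_by_default(self, layout):
        tau = 1.0
        # 3 and 4 both recruit off node 1 and interact strongly with each other
        cm = contact_matrix_from_entries(
            layout, {(3, 1): 4.0, (4, 1): 4.0, (3, 4): 9.0}
        )
        ext = extend_network(
            build_original_network({1}, cm, flat_thresholds(layout, tau)),
            cm,
            flat_thresholds(layout, tau),
        )
        assert ext.graph.has_edge(3, 4)
        star = extend_network(
            build_original_network({1}, cm, flat_thresholds(layout, tau)),
            cm,
            flat_thresholds(layout, tau),
            star_extension=True,
        )
        assert not star.graph.has_edge(3, 4)
        assert star.nodes == ext.nodes

    def test_single_round_extension(self, layout):
        tau = 1.0
        # 2 recruits off 1; 3 interacts only with 2, so one round must NOT add 3
        cm = contact_matrix_from_entries(layout, {(1, 2): 5.0, (2, 3): 5.0})
        ext = extend_network(
            build_original_network({1}, cm, flat_thresholds(layout, tau)),
            cm,
            flat_thresholds(layout, tau),
        )
        assert ext.nodes == {1, 2}

    def test_removing_added_recovers_original(self, layout):
        from coloc_longevity import ContactMatrix, compute_thresholds

        rng = np.random.default_rng(8)
        m = rng.gamma(0.5, 5.0, size=(16, 16))
        m = np.triu(m, 1) + np.triu(m, 1).T
        cm = ContactMatrix(layout, m)
        ts = compute_thresholds(cm, q=0.9)
        net = build_original_network({1, 5, 12}, cm, ts)
        ext = extend_network(net, cm, ts)
        assert net.nodes <= ext.nodes
        for b in ext.added_nodes():
            assert any(ext.graph.has_edge(b, o) for o in net.nodes)
        pruned = ext.graph.subgraph(net.nodes)
        assert set(pruned.nodes) == net.nodes
        assert set(map(frozenset, pruned.edges)) == set(map(frozenset, net.graph.edges))


class TestGraphMeasures:
    def test_degree_and_components_triangle(self, layout):
        net = make_net(layout, [1, 2, 3, 5], [(1, 2, 1.0), (2, 3, 1.0), (1, 3, 1.0)])
        deg = node_degree(net)
        assert deg == {1: 2, 2: 2, 3: 2, 5: 0}
        assert sum(deg.values()) == 2 * net.n_edges
        comps = connected_components(net)
        assert comps == [{1, 2, 3}, {5}]

    def test_ego_subnetwork(self, layout):
        hub = make_net(layout, [1, 2, 3, 4, 9], [(1, 2, 1), (1, 3, 1), (1, 4, 1)])
        sub = ego_subnetwork(hub, 1)
        assert sub.nodes == {1, 2, 3, 4}
        assert sub.n_edges == 3
        assert ego_subnetwork(hub, 9).nodes == {9}
        tri = make_net(layout, [1, 2, 3], [(1, 2, 1), (2, 3, 1), (1, 3, 1)])
        assert ego_subnetwork(tri, 2).n_edges == 3
        with pytest.raises(KeyError):
            ego_subnetwork(hub, 99)

    def test_shared_nodes_spans(self, layout):
        a = make_net(layout, [1, 2, 3, 11], [])
        b = make_net(layout, [2, 3, 12], [])
        common, span = shared_nodes(a, b)
        assert common == {2, 3}
        assert span == pytest.approx(2 * 0.08)
        # symmetry and the disjoint case
        assert shared_nodes(b, a)[0] == common
        c = make_net(layout, [14, 15], [])
        assert shared_nodes(a, c) == (set(), 0.0)

    def test_shared_nodes_resolution_mismatch(self, layout):
        fine = make_genome_layout([("A", 800_000), ("B", 480_000)], 10_000)
        a = make_net(layout, [1], [])
        b = make_net(fine, [1], [])
        with pytest.raises(ValueError):
            shared_nodes(a, b)


class TestCommunities:
    def test_single_clique_one_community(self, layout):
        edges = [(i, j, 1.0) for i, j in itertools.combinations(range(1, 6), 2)]
        net = make_net(layout, range(1, 6), edges)
        part = detect_communities(net, resolution=0.1, seed=0)
        assert part.n_communities == 1

    def test_two_cliques_with_light_bridge(self):
        lay = make_genome_layout([("A", 2_000_000)], 80_000)
        c1, c2 = list(range(1, 7)), list(range(7, 13))
        edges = [(i, j, 10.0) for i, j in itertools.combinations(c1, 2)]
        edges += [(i, j, 10.0) for i, j in itertools.combinations(c2, 2)]
        edges += [(6, 7, 0.1)]
        net = make_net(lay, range(1, 13), edges)
        part = detect_communities(net, resolution=1.0, seed=0)
        assert part.communities() == [set(c1), set(c2)]
        # the clique split beats the trivial partitions it competes with
        g = net.graph
        all_one = [set(range(1, 13))]
        singletons = [{i} for i in range(1, 13)]
        for other in (all_one, singletons):
            assert part.modularity > nx.community.modularity(g, other, weight="weight")

    def test_seeded_reproducibility(self, layout):
        rng = np.random.default_rng(11)
        edges = [
            (int(i), int(j), float(w))
            for i, j, w in zip(
                rng.integers(1, 16, 60), rng.integers(1, 16, 60), rng.uniform(0.1, 5, 60)
            )
            if i != j
        ]
        net = make_net(layout, range(1, 17), edges)
        p1 = detect_communities(net, resolution=0.5, seed=42)
        p2 = detect_communities(net, resolution=0.5, seed=42)
        assert p1.membership == p2.membership
        assert p1.modularity == p2.modularity

    def test_partition_covers_nodes(self, layout):
        net = make_net(layout, [1, 2, 3, 8], [(1, 2, 1.0)])
        part = detect_communities(net, seed=0)
        assert set(part.membership) == net.nodes

    def test_empty_network_rejected(self, layout):
        net = make_net(layout, [], [])
        with pytest.raises(ValueError):
            detect_communities(net)


def test_network_tsv_roundtrip(layout, tmp_path):
    net = make_net(
        layout,
        [1, 2, 3, 7],
        [(1, 2, 3.5), (2, 3, 1.25)],
        origins={7: "added", 1: "original", 2: "original", 3: "added"},
    )
    path = tmp_path / "net.tsv"
    write_network_tsv(net, path)
    back = read_network_tsv(path, layout)
    assert back.nodes == net.nodes
    assert {n: back.origin(n) for n in back.nodes} == {
        n: net.origin(n) for n in net.nodes
    }
    assert set(map(frozenset, back.graph.edges)) == set(map(frozenset, net.graph.edges))
    assert back.graph[1][2]["weight"] == pytest.approx(3.5)
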