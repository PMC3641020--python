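import pytest

from ppinet import centrality as ct
from ppinet import subnetworks as sn
from ppinet.graph_model import seeds_of

import _oracles as oracle
from conftest import graph


class TestTopFraction:
    @pytest.mark.parametrize("n,fraction,expected", [
        (535, 0.05, 27),   # the published 5% cutoff on the 535-node giant
        (100, 0.05, 5),
        (40, 0.05, 2),
        (20, 0.05, 1),
    ])
    def test_ceil_cutoff(self, n, fraction, expected):
        assert sn.cutoff_count(n, fraction) == expected

    def test_selection_ranked_desc_then_symbol(self):
        vals = {"A": 0.3, "B": 0.9, "C": 0.3, "D": 0.1}
        assert sn.select_top_fraction(vals, 4, 0.5) == ["B", "A", "C"]

    def test_boundary_ties_all_included(self):
        vals = {"A": 0.9, "B": 0.5, "C": 0.5, "D": 0.5, "E": 0.1}
        got = sn.select_top_fraction(vals, 5, 0.4)  # nominal cutoff 2
        assert got == ["A", "B", "C", "D"]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            sn.cutoff_count(10, 0.0)


class TestBackbone:
    def test_planted_bridge_tops_backbone(self, small_synthetic):
        import ppinet as pp
        cfg, interactions, truth, seeds = small_synthetic
        giant = pp.giant_component(
            pp.build_extended_network(seeds.symbols, interactions))
        bc = ct.betweenness(giant)
        bb = sn.extract_backbone(giant, bc)
        assert bb.members[0][0] == truth.bridge_node
        assert set(bb.backbone_net.nodes) == set(bb.nodes)

    def test_single_node_backbone_is_edgeless(self, rng):
        g = oracle.random_connected_graph(rng, 20)
        bc = ct.betweenness(g)
        bb = sn.extract_backbone(g, bc, 0.05)
        assert bb.cutoff == 1
        if len(bb.members) == 1:
            assert bb.backbone_net.number_of_edges() == 0

    def test_members_sorted_by_bc(self, rng):
        g = oracle.random_connected_graph(rng, 15)
        bb = sn.extract_backbone(g, ct.betweenness(g), 0.3)
        scores = [v for _, v in bb.members]
        assert scores == sorted(scores, reverse=True)


class TestKeyNodeClassification:
    def test_star_partition(self):
        g = graph([("HUB", f"L{i}") for i in range(9)])
        deg, bc = ct.degree(g), ct.betweenness(g)
        cls = sn.classify_key_nodes(deg, bc, 10, 0.1)
        assert cls.labels["HUB"] == "hub-bottleneck"
        assert all(cls.labels[f"L{i}"] == "nonhub-nonbottleneck" for i in range(9))

    def test_coincident_rankings_leave_bottleneck_only_empty(self):
        deg = {"A": 5, "B": 4, "C": 2, "D": 1}
        bc = {"A": 0.9, "B": 0.7, "C": 0.2, "D": 0.1}
        cls = sn.classify_key_nodes(deg, bc, 4, 0.5)
        assert cls.bottleneck_only == [] and cls.hub_only == []
        assert cls.hub_bottlenecks == ["A", "B"]

    def test_four_classes_partition_nodes(self, rng):
        g = oracle.random_connected_graph(rng, 30)
        cls = sn.classify_key_nodes(ct.degree(g), ct.betweenness(g), 30, 0.2)
        assert sum(cls.counts().values()) == 30

    def test_mismatched_maps_rejected(self):
        with pytest.raises(ValueError):
            sn.classify_key_nodes({"A": 1}, {"B": 0.1}, 2, 0.5)


class TestSeedSubnetwork:
    def test_square_keeps_both_shortest_paths(self):
        g = graph([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")], seeds=["A", "D"])
        sub = sn.seed_shortest_path_subnetwork(g)
        assert sub.nodes == {"A", "B", "C", "D"}
        assert len(sub.paths[("A", "D")]) == 2

    def test_adjacent_seeds_trivial(self):
        g = graph([("A", "B"), ("B", "C")], seeds=["A", "B"])
        sub = sn.seed_shortest_path_subnetwork(g)
        assert sub.nodes == {"A", "B"}

    def test_path_cap_aborts_loudly(self):
        # 3 stacked squares: 2^3 = 8 shortest paths end to end
        edges = []
        for i in range(3):
            edges += [(f"S{i}", f"U{i}"), (f"S{i}", f"V{i}"),
                      (f"U{i}", f"S{i+1}"), (f"V{i}", f"S{i+1}")]
        g = graph(edges, seeds=["S0", "S3"])
        with pytest.raises(sn.PathExplosionError):
            sn.seed_shortest_path_subnetwork(g, path_cap=4)

    def test_matches_enumeration_oracle(self, rng):
        """Every vertex of every enumerated shortest seed-seed path is
        collected, and nothing else."""
        for _ in range(15):
            g = oracle.random_connected_graph(rng, int(rng.integers(4, 10)))
            nodes = sorted(g.nodes)
            seeds = [nodes[0], nodes[-1], nodes[len(nodes) // 2]]
            seeds = sorted(set(seeds))
            if len(seeds) < 2:
                continue
            for n in g.nodes:
                g.nodes[n]["seed"] = n in seeds
            sub = sn.seed_shortest_path_subnetwork(g, seeds)
            expect = set(seeds)
            for i, a in enumerate(seeds):
                for b in seeds[i + 1:]:
                    for p in oracle.all_shortest_paths(g, a, b):
                        expect.update(p)
            assert sub.nodes == expect

    def test_seed_distances_preserved(self, rng):
        """Within the subnetwork every seed pair keeps its giant-network
        distance (the subnetwork contains a shortest path for each pair)."""
        for _ in range(10):
            g = oracle.random_connected_graph(rng, 9)
            nodes = sorted(g.nodes)
            seeds = nodes[:3]
            sub = sn.seed_shortest_path_subnetwork(g, seeds)
            for i, a in enumerate(seeds):
                for b in seeds[i + 1:]:
                    assert (oracle.distance(sub.net, a, b)
                            == oracle.distance(g, a, b))

    def test_minimality_every_connector_carries_a_path(self, rng):
        """Each non-seed member lies on at least one recorded shortest path."""
        g = oracle.random_connected_graph(rng, 10)
        nodes = sorted(g.nodes)
        seeds = [nodes[0], nodes[-1]]
        sub = sn.seed_shortest_path_subnetwork(g, seeds)
        on_paths = set()
        for paths in sub.paths.values():
            for p in paths:
                on_paths.update(p)
        assert sub.nodes == on_paths

    def test_bc_recomputed_within_subnetwork(self):
        g = graph([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D"), ("D", "E")],
                  seeds=["A", "D"])
        sub = sn.seed_shortest_path_subnetwork(g)
        assert set(n for n, _ in sub.bc_ranking) == sub.nodes
        assert "E" not in sub.nodes

    def test_fewer_than_two_seeds_rejected(self, path3):
        with pytest.raises(ValueError):
            sn.seed_shortest_path_subnetwork(path3, ["A"])

    def test_composition_partition_sums_to_total(self, small_synthetic):
        import ppinet as pp
        cfg, interactions, truth, seeds = small_synthetic
        giant = pp.giant_component(
            pp.build_extended_network(seeds.symbols, interactions))
        bc = ct.betweenness(giant)
        bb = sn.extract_backbone(giant, bc)
        sub = sn.seed_shortest_path_subnetwork(giant)
        comp = sub.composition(bb.nodes)
        parts = (comp["seed_and_backbone"] + comp["seed_only"]
                 + comp["backbone_only"] + comp["connector"])
        assert parts == comp["total"] == len(sub.nodes)
        assert seeds_of(sub.net) <= sub.nodes
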