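import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppinet import graph_model as gm

from conftest import graph, table


# strategy: small random interaction tables over a fixed symbol alphabet
SYMBOLS = [f"G{i}" for i in range(12)]
row_st = st.tuples(st.sampled_from(SYMBOLS), st.sampled_from(SYMBOLS),
                   st.floats(min_value=0, max_value=1000))
table_st = st.lists(row_st, min_size=1, max_size=40).map(
    lambda rows: gm.InteractionTable(list(rows)))


class TestBuildExtendedNetwork:
    def test_neighbor_closure_keeps_induced_edges(self):
        t = table(("A", "B", 900), ("B", "C", 900), ("A", "C", 900))
        net = gm.build_extended_network(["A"], t, min_score=400)
        assert set(net.nodes) == {"A", "B", "C"}
        # B-C is a neighbour-neighbour edge: included because the edge set
        # is induced on the node set, not restricted to seed-incident edges
        assert {tuple(sorted(e)) for e in net.edges} == {("A", "B"), ("A", "C"), ("B", "C")}
        assert gm.seeds_of(net) == {"A"}

    def test_second_neighbors_excluded(self):
        t = table(("A", "B", 900), ("B", "C", 900), ("C", "D", 900))
        net = gm.build_extended_network(["A"], t, min_score=400)
        assert set(net.nodes) == {"A", "B"}

    def test_score_threshold_filters_edges(self):
        t = table(("A", "B", 900), ("A", "C", 150))
        net = gm.build_extended_network(["A"], t, min_score=400)
        assert set(net.nodes) == {"A", "B"}

    def test_missing_seed_kept_when_configured(self):
        t = table(("A", "B", 900))
        net = gm.build_extended_network(["A", "ZZZ"], t, keep_missing_seeds=True)
        assert "ZZZ" in net.nodes and net.degree("ZZZ") == 0
        assert net.nodes["ZZZ"]["seed"]

    def test_missing_seed_dropped_by_default(self, caplog):
        t = table(("A", "B", 900))
        with caplog.at_level("WARNING"):
            net = gm.build_extended_network(["A", "ZZZ"], t)
        assert "ZZZ" not in net.nodes
        assert "ZZZ" in caplog.text

    def test_single_seed_empty_table_kept(self):
        net = gm.build_extended_network(["A"], gm.InteractionTable([]),
                                        keep_missing_seeds=True)
        assert set(net.nodes) == {"A"}

    def test_empty_result_is_an_error(self):
        with pytest.raises(gm.EmptyNetworkError):
            gm.build_extended_network(["A"], gm.InteractionTable([]))
        with pytest.raises(ValueError):
            gm.build_extended_network([], gm.InteractionTable([("A", "B", 900.0)]))

    def test_symbols_case_normalized(self):
        t = table(("a", "b", 900))
        net = gm.build_extended_network(["A"], t)
        assert set(net.nodes) == {"A", "B"}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(t=table_st, seeds=st.lists(st.sampled_from(SYMBOLS), min_size=1,
                                      max_size=4, unique=True),
           lo=st.floats(min_value=0, max_value=500),
           delta=st.floats(min_value=0, max_value=500))
    def test_monotone_in_min_score(self, t, seeds, lo, delta):
        """Lowering the threshold never removes nodes or edges."""
        try:
            high = gm.build_extended_network(seeds, t, min_score=lo + delta)
        except gm.EmptyNetworkError:
            return
        low = gm.build_extended_network(seeds, t, min_score=lo)
        assert set(high.nodes) <= set(low.nodes)
        assert set(map(frozenset, high.edges)) <= set(map(frozenset, low.edges))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(t=table_st, seeds=st.lists(st.sampled_from(SYMBOLS), min_size=1,
                                      max_size=4, unique=True))
    def test_always_simple(self, t, seeds):
        """No self-loops and no parallel edges, for any input table."""
        try:
            net = gm.build_extended_network(seeds, t, min_score=0)
        except gm.EmptyNetworkError:
            return
        assert not any(a == b for a, b in net.edges)
        assert isinstance(net, nx.Graph) and not net.is_multigraph()


class TestDecomposeComponents:
    def test_sizes_and_giant(self):
        # triangle + isolated edge + isolated node -> sizes [3, 2, 1]
        g = graph([("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y")], nodes=["Z"])
        dec = gm.decompose_components(g)
        assert dec.sizes == [3, 2, 1]
        assert dec.giant == {"A", "B", "C"}

    def test_connected_graph_single_component(self, path3):
        dec = gm.decompose_components(path3)
        assert dec.components == [{"A", "B", "C"}]

    def test_partition_property(self):
        g = graph([("A", "B"), ("C", "D"), ("E", "F"), ("E", "G")])
        dec = gm.decompose_components(g)
        assert sum(dec.sizes) == g.number_of_nodes()
        seen = set().union(*dec.components)
        assert seen == set(g.nodes)
        for a, b in g.edges:
            assert any(a in c and b in c for c in dec.components)

    def test_tie_broken_by_smallest_member(self):
        g = graph([("B", "C"), ("A", "D")])
        dec = gm.decompose_components(g)
        assert dec.giant == {"A", "D"}

    def test_empty_graph_rejected(self):
        with pytest.raises(gm.EmptyNetworkError):
            gm.decompose_components(nx.Graph())


class TestInducedSubgraph:
    def test_edge_filtering(self):
        tri = graph([("A", "B"), ("B", "C"), ("A", "C")], seeds=["A"])
        sub = gm.induced_subgraph(tri, {"A", "B"})
        assert set(sub.nodes) == {"A", "B"}
        assert {tuple(sorted(e)) for e in sub.edges} == {("A", "B")}
        assert gm.seeds_of(sub) == {"A"}

    def test_isolated_member_kept(self):
        p = graph([("A", "B"), ("B", "C"), ("C", "D")])
        sub = gm.induced_subgraph(p, {"A", "C", "D"})
        assert {tuple(sorted(e)) for e in sub.edges} == {("C", "D")}
        assert sub.degree("A") == 0

    def test_identity_roundtrip(self, path3):
        sub = gm.induced_subgraph(path3, set(path3.nodes))
        assert nx.utils.graphs_equal(sub, path3)

    def test_unknown_nodes_named_in_error(self, path3):
        with pytest.raises(KeyError, match="QQ"):
            gm.induced_subgraph(path3, {"A", "QQ"})


class TestInteractionCleaning:
    def test_reverse_duplicates_keep_max_score(self):
        t = table(("A", "B", 900), ("B", "A", 800), ("C", "C", 950))
        assert t.rows == [("A", "B", 900.0)]

    def test_idempotent(self):
        t = table(("A", "B", 900), ("B", "A", 800))
        assert t.cleaned().rows == t.rows

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError):
            gm.InteractionTable([("A", "B", -5.0)]).cleaned()
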