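"""Multilayer graph container: layers, CRUD, transitive derivation, I/O."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathlayers import errors, export_graph, fixtures, graphs_equal, import_graph, new_graph


class TestLayers:
    def test_empty_graph(self):
        g = new_graph("g")
        assert g.shape() == (0, 0, 0)
        assert g.layers == []

    def test_layer_ids_sequential(self):
        g = new_graph("")
        assert [g.add_layer(n) for n in ("A", "B", "C")] == [1, 2, 3]

    def test_duplicate_layer_case_insensitive(self):
        g = new_graph("")
        g.add_layer("Protein")
        with pytest.raises(errors.DuplicateLayerError):
            g.add_layer("protein")

    def test_layer_ids_never_reused(self):
        g = new_graph("")
        g.add_layer("A")
        g.add_layer("B")
        g.remove_layer("B")
        assert g.add_layer("C") == 3


class TestNodesEdges:
    def test_add_node_missing_layer(self):
        g = new_graph("")
        with pytest.raises(errors.UnknownLayerError):
            g.add_node("x", "Nope")

    def test_duplicate_node(self):
        g = new_graph("")
        g.add_layer("L")
        g.add_node("x", "L")
        with pytest.raises(errors.DuplicateNodeError):
            g.add_node("x", "L")

    def test_parallel_edges_get_distinct_keys(self):
        g = new_graph("")
        g.add_layer("L")
        g.add_node("a", "L")
        g.add_node("b", "L")
        e0 = g.add_edge("a", "b", {"source": "DrugBank"})
        e1 = g.add_edge("a", "b", {"source": "UniProt"})
        assert {e0.key, e1.key} == {0, 1}
        assert len(g.edges_between("a", "b")) == 2

    def test_self_loop_allowed(self):
        g = new_graph("")
        g.add_layer("L")
        g.add_node("a", "L")
        e = g.add_edge("a", "a")
        assert e.attributes["type"] == "direct"

    def test_edge_unknown_endpoint(self):
        g = new_graph("")
        g.add_layer("L")
        g.add_node("a", "L")
        with pytest.raises(errors.UnknownNodeError):
            g.add_edge("a", "z")

    def test_remove_edge_by_key_and_all(self):
        g = new_graph("")
        g.add_layer("L")
        g.add_node("a", "L")
        g.add_node("b", "L")
        for _ in range(3):
            g.add_edge("a", "b")
        assert len(g.remove_edge("a", "b", 0)) == 1
        assert len(g.remove_edge("a", "b", "all")) == 2
        with pytest.raises(errors.UnknownEdgeError):
            g.remove_edge("a", "b")


class TestTransitiveRemoval:
    def test_star_spawns_all_pairs(self, star_graph):
        removed, added = star_graph.remove_node("c", transitive=True)
        assert len(removed) == 4
        assert len(added) == 6  # C(4,2)
        for e in added:
            assert e.attributes["type"] == "transitive"
            assert e.attributes["via"] == "c"

    def test_existing_direct_edge_suppresses_transitive(self):
        g = new_graph("")
        g.add_layer("L")
        for n in ("u", "c", "w"):
            g.add_node(n, "L")
        g.add_edge("u", "c")
        g.add_edge("c", "w")
        g.add_edge("u", "w")  # pre-existing direct edge
        _, added = g.remove_node("c", transitive=True)
        assert added == []

    def test_dedupe_off_adds_parallel(self):
        g = new_graph("", transitive_dedupe=False)
        g.add_layer("L")
        for n in ("u", "c", "w"):
            g.add_node(n, "L")
        g.add_edge("u", "c")
        g.add_edge("c", "w")
        g.add_edge("u", "w")
        _, added = g.remove_node("c", transitive=True)
        assert len(added) == 1
        assert len(g.edges_between("u", "w")) == 2

    def test_isolated_node(self):
        g = new_graph("")
        g.add_layer("L")
        g.add_node("x", "L")
        assert g.remove_node("x", transitive=True) == ([], [])

    def test_self_loop_never_pairs(self):
        g = new_graph("")
        g.add_layer("L")
        g.add_node("c", "L")
        g.add_node("u", "L")
        g.add_edge("c", "c")
        g.add_edge("c", "u")
        _, added = g.remove_node("c", transitive=True)
        assert added == []

    @pytest.mark.parametrize("seed", range(30))
    def test_pair_enumeration_oracle(self, seed):
        """Removal matches the brute-force oracle: one transitive edge per
        non-adjacent neighbor pair."""
        g = fixtures.gen_random_graph(seed, max_nodes=25)
        nodes = [n.name for n in g.nodes()]
        if not nodes:
            return
        import random

        victim = random.Random(seed).choice(nodes)
        neighbors = sorted({e.a if e.b == victim else e.b for e in g.edges() if victim in (e.a, e.b)} - {victim})
        expected = {
            tuple(sorted(p))
            for p in itertools.combinations(neighbors, 2)
            if not any({p[0], p[1]} == {e.a, e.b} for e in g.edges() if victim not in (e.a, e.b))
        }
        _, added = g.remove_node(victim, transitive=True)
        assert {e.pair for e in added} == expected


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), pick=st.integers(0, 1_000))
def test_transitive_removal_preserves_neighbor_connectivity(seed, pick):
    """Any two surviving former neighbors of a transitively removed node
    remain connected by some path."""
    g = fixtures.gen_random_graph(seed, max_nodes=20)
    nodes = [n.name for n in g.nodes()]
    if not nodes:
        return
    victim = nodes[pick % len(nodes)]
    neighbors = {e.a if e.b == victim else e.b for e in g.edges() if victim in (e.a, e.b)} - {victim}
    g.remove_node(victim, transitive=True)
    h = nx.Graph()
    h.add_nodes_from(n.name for n in g.nodes())
    h.add_edges_from((e.a, e.b) for e in g.edges())
    for u, w in itertools.combinations(sorted(neighbors), 2):
        assert nx.has_path(h, u, w)


class TestLayerRemoval:
    def test_single_bridge(self):
        g = new_graph("")
        g.add_layer("Keep")
        g.add_layer("Gone")
        g.add_node("u", "Keep")
        g.add_node("w", "Keep")
        g.add_node("m", "Gone")
        g.add_edge("u", "m")
        g.add_edge("m", "w")
        nodes, edges, trans = g.remove_layer("Gone", transitive=True)
        assert [n.name for n in nodes] == ["m"]
        assert len(edges) == 2
        assert len(trans) == 1
        assert trans[0].pair == ("u", "w")
        assert trans[0].attributes["via"] == "m"

    def test_cascade_through_chain(self):
        """u—m1—m2—w with m1,m2 on the removed layer: survivors stay connected."""
        g = new_graph("")
        g.add_layer("Keep")
        g.add_layer("Gone")
        for n in ("u", "w"):
            g.add_node(n, "Keep")
        for n in ("m1", "m2"):
            g.add_node(n, "Gone")
        g.add_edge("u", "m1")
        g.add_edge("m1", "m2")
        g.add_edge("m2", "w")
        nodes, edges, trans = g.remove_layer("Gone", transitive=True)
        assert len(trans) == 1
        assert trans[0].pair == ("u", "w")
        # intermediate transitive edges cancel: removed_edges are originals only
        assert len(edges) == 3
        assert all(e.attributes["type"] == "direct" for e in edges)

    def test_empty_layer(self):
        g = new_graph("")
        g.add_layer("Empty")
        assert g.remove_layer("Empty") == ([], [], [])
        assert not g.has_layer("Empty")

    def test_edge_count_without_transitive(self):
        for seed in range(20):
            g = fixtures.gen_random_graph(seed, max_nodes=20)
            if len(g.layers) < 2:
                continue
            layer = g.layers[0][1]
            member = {n.name for n in g.nodes(layer)}
            incident = sum(1 for e in g.edges() if e.a in member or e.b in member)
            total = g.shape()[2]
            g.remove_layer(layer, transitive=False)
            assert g.shape()[2] == total - incident

    def test_survivor_edge_set_is_order_invariant(self):
        """With dedupe on, which surviving pairs end up connected does not
        depend on the node-removal order inside the layer."""
        import random

        for seed in range(10):
            base = fixtures.gen_random_graph(seed, max_nodes=15)
            if len(base.layers) < 2:
                continue
            layer = base.layers[0][1]
            member = [n.name for n in base.nodes(layer)]
            results = set()
            for perm_seed in range(5):
                g = base.copy()
                order = member[:]
                random.Random(perm_seed).shuffle(order)
                for n in order:
                    g.remove_node(n, transitive=True)
                results.add(frozenset(e.pair for e in g.edges()))
            assert len(results) <= 1


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["graphml", "json"])
    def test_round_trip_identity(self, fmt, tmp_path, toy_three_layer):
        g = toy_three_layer
        g.add_edge("P1", "P2", {"source": "again"})  # parallel edge
        path = str(tmp_path / f"g.{fmt}")
        export_graph(g, path, fmt)
        assert graphs_equal(g, import_graph(path, fmt))

    @pytest.mark.parametrize("fmt", ["graphml", "json"])
    def test_empty_round_trip(self, fmt, tmp_path):
        path = str(tmp_path / f"e.{fmt}")
        export_graph(new_graph("empty"), path, fmt)
        assert graphs_equal(new_graph("empty"), import_graph(path, fmt))

    def test_graphml_missing_layer_table(self, tmp_path):
        import networkx as nx

        path = str(tmp_path / "bad.graphml")
        nx.write_graphml(nx.Graph([(1, 2)]), path)
        with pytest.raises(errors.FormatError, match="layers"):
            import_graph(path, "graphml")

    def test_json_malformed(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(errors.FormatError):
            import_graph(str(path), "json")

    def test_copy_is_independent(self, toy_three_layer):
        g2 = toy_three_layer.copy()
        g2.add_node("extra", "Protein")
        g2.update_node_attributes("P1", {"mark": "yes"})
        assert not toy_three_layer.has_node("extra")
        assert "mark" not in toy_three_layer.get_node("P1").attributes
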