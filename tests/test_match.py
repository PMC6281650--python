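"""Approximate subgraph matching: signatures, criterion, invariants."""

import networkx as nx
import numpy as np
import pytest

from dpnnet.match import MatchParams, match_networks, nh_signature, pairwise_match_all

from oracles import brute_match, graph_to_adj


def graph(edges, nodes=()):
    g = nx.Graph(namespace="human", dataset="q")
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestSignature:
    def test_triangle(self):
        g = graph([("A", "B"), ("B", "C"), ("A", "C")])
        sig = nh_signature(g, "A")
        assert sig["degree"] == 2
        assert sig["n_neighbour_connections"] == 1
        assert sig["neighbour_labels"] == {"B", "C"}

    def test_star_centre(self):
        g = graph([("C", f"L{i}") for i in range(4)])
        sig = nh_signature(g, "C")
        assert sig["degree"] == 4 and sig["n_neighbour_connections"] == 0

    def test_isolated_node(self):
        g = graph([], nodes=["A"])
        sig = nh_signature(g, "A")
        assert sig["degree"] == 0
        assert sig["n_neighbour_connections"] == 0
        assert sig["neighbour_labels"] == frozenset()

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            nh_signature(graph([("A", "B")]), "Z")


class TestMatch:
    def test_identical_networks_rho_zero(self):
        g = graph([("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")])
        shared = match_networks(g, g.copy(), MatchParams(mismatch_rho=0.0))
        assert set(shared.graph.nodes) == set(g.nodes)
        assert set(map(frozenset, shared.graph.edges)) == set(map(frozenset, g.edges))

    def test_gene_absent_from_db_never_matched(self):
        q = graph([("A", "B")])
        db = graph([("A", "C")])
        shared = match_networks(q, db, MatchParams(mismatch_rho=1.0))
        assert "B" not in shared.graph

    def test_namespace_mismatch_rejected(self):
        q = graph([("A", "B")])
        db = graph([("A", "B")])
        db.graph["namespace"] = "mouse"
        with pytest.raises(ValueError):
            match_networks(q, db)

    def test_perturbed_neighbourhood_rho_dependence(self):
        """A node whose neighbourhood is half-broken in the database matches
        at rho=0.5 but not rho=0; expectations from the brute-force oracle."""
        q = graph([("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")])
        db = graph([("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"),
                    ("D", "X"), ("E", "X"), ("E", "Y"), ("F", "Y")])
        for rho in (0.0, 0.5):
            result = set(match_networks(q, db, MatchParams(mismatch_rho=rho)).graph.nodes)
            assert result == brute_match(graph_to_adj(q), graph_to_adj(db), rho)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        nodes = [f"G{i}" for i in range(12)]
        q = graph([(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                   if rng.uniform() < 0.25], nodes=nodes)
        db_nodes = [n for n in nodes if rng.uniform() < 0.8] + ["H1", "H2"]
        db = graph([(a, b) for i, a in enumerate(db_nodes) for b in db_nodes[i + 1:]
                    if rng.uniform() < 0.25], nodes=db_nodes)
        prev = None
        for rho in (0.0, 0.1, 0.5, 1.0):
            got = set(match_networks(q, db, MatchParams(mismatch_rho=rho)).graph.nodes)
            assert got == brute_match(graph_to_adj(q), graph_to_adj(db), rho)
            if prev is not None:
                assert prev <= got  # monotone in rho
            prev = got

    def test_output_subgraph_of_both_inputs(self):
        rng = np.random.default_rng(7)
        nodes = [f"G{i}" for i in range(15)]
        q = graph([(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                   if rng.uniform() < 0.3], nodes=nodes)
        db = graph([(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                    if rng.uniform() < 0.3], nodes=nodes)
        out = match_networks(q, db).graph
        for a, b in out.edges:
            assert q.has_edge(a, b) and db.has_edge(a, b)

    def test_importance_fraction_does_not_change_fixpoint(self):
        rng = np.random.default_rng(11)
        nodes = [f"G{i}" for i in range(14)]
        q = graph([(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                   if rng.uniform() < 0.2], nodes=nodes)
        db = graph([(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                    if rng.uniform() < 0.2], nodes=nodes)
        results = {
            frozenset(match_networks(q, db, MatchParams(0.1, f)).graph.nodes)
            for f in (0.05, 0.25, 1.0)
        }
        assert len(results) == 1


class TestPairwise:
    def test_cardinality_and_order(self):
        base = graph([("A", "B"), ("B", "C")])
        queries = []
        for i in range(7):
            g = base.copy()
            g.graph["dataset"] = f"m{i}"
            queries.append(g)
        results = pairwise_match_all(queries, base)
        assert [r.label for r in results] == [f"m{i}" for i in range(7)]

    def test_empty_query_gives_empty_shared(self):
        empty = graph([], nodes=[])
        empty.graph["dataset"] = "empty"
        result = pairwise_match_all([empty], graph([("A", "B")]))
        assert len(result) == 1 and len(result[0]) == 0

    def test_requires_at_least_one_query(self):
        with pytest.raises(ValueError):
            pairwise_match_all([], graph([("A", "B")]))

    def test_results_independent_of_query_order(self):
        rng = np.random.default_rng(2)
        nodes = [f"G{i}" for i in range(10)]
        queries = []
        for i in range(3):
            g = graph([(a, b) for j, a in enumerate(nodes) for b in nodes[j + 1:]
                       if rng.uniform() < 0.3], nodes=nodes)
            g.graph["dataset"] = f"m{i}"
            queries.append(g)
        db = graph([(a, b) for j, a in enumerate(nodes) for b in nodes[j + 1:]
                    if rng.uniform() < 0.3], nodes=nodes)
        fwd = pairwise_match_all(queries, db)
        rev = pairwise_match_all(queries[::-1], db)
        by_label_fwd = {r.label: set(r.graph.nodes) for r in fwd}
        by_label_rev = {r.label: set(r.graph.nodes) for r in rev}
        assert by_label_fwd == by_label_rev
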