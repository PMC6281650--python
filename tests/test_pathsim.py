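"""Pathway similarity scoring, edge retention, map-equation clustering."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpnnet.pathsim import build_similarity_network, cluster_map_equation, similarity


class TestSimilarity:
    def test_identical_pathways_identical_directions(self):
        genes = {"A", "B", "C"}
        fc = {"A": 1.0, "B": -2.0, "C": 0.5}
        assert similarity(genes, genes, fc, fc) == 1.0

    def test_disjoint_is_zero(self):
        assert similarity({"A", "B"}, {"C", "D"}) == 0.0

    def test_half_overlap_all_signs_agree(self):
        # |A∩B| = 2, |A∪B| = 6 -> Jaccard 1/3; shared signs agree -> 1/3
        a = {"A", "B", "C", "D"}
        b = {"A", "B", "E", "F"}
        fc = {"A": 1.0, "B": -1.0}
        assert similarity(a, b, fc, fc) == pytest.approx(1 / 3)

    def test_sign_disagreement_halves_score(self):
        a = {"A", "B", "C", "D"}
        b = {"A", "B", "E", "F"}
        fc_a = {"A": 1.0, "B": 1.0}
        fc_b = {"A": 1.0, "B": -1.0}
        assert similarity(a, b, fc_a, fc_b) == pytest.approx(1 / 6)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            similarity(set(), {"A"})

    @given(st.sets(st.integers(0, 12), min_size=1, max_size=8),
           st.sets(st.integers(0, 12), min_size=1, max_size=8),
           st.integers(0, 2 ** 13 - 1))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b, sign_bits):
        fc = {g: (1.0 if sign_bits >> g & 1 else -1.0) for g in range(13)}
        s_ab = similarity(a, b, fc, fc)
        s_ba = similarity(b, a, fc, fc)
        assert s_ab == s_ba
        assert 0.0 <= s_ab <= 1.0


class TestRetention:
    def _pathways(self, n, size=4, overlap=2, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(40)]
        return {f"P{i}": set(rng.choice(genes, size=size, replace=False)) | {"SHARED"}
                for i in range(n)}

    def test_quantile_counting(self):
        """8 positive pairwise scores at quantile 0.25 retain ceil(2)=2 edges
        (absent ties)."""
        # build 8 pathway pairs with distinct positive scores via a chain
        pathways = {}
        for i in range(8):
            pathways[f"A{i}"] = {f"X{i}_{j}" for j in range(i + 1)} | {f"S{i}"}
            pathways[f"B{i}"] = {f"S{i}"} | {f"Y{i}_{j}" for j in range(8)}
        net = build_similarity_network(pathways, quantile=0.25)
        scores = sorted((d["similarity"] for *_, d in net.graph.edges(data=True)),
                        reverse=True)
        assert len(scores) == 2

    def test_all_equal_scores_all_retained(self):
        pathways = {f"P{i}": {"S", f"U{i}"} for i in range(5)}
        net = build_similarity_network(pathways, quantile=0.25)
        # every pair scores 1/3; ties at the cut keep all 10 pairs
        assert net.graph.number_of_edges() == 10

    def test_quantile_one_keeps_all_positive(self):
        pathways = self._pathways(6)
        net = build_similarity_network(pathways, quantile=1.0)
        n_pos = sum(1 for a, b in itertools.combinations(pathways, 2)
                    if similarity(pathways[a], pathways[b]) > 0)
        assert net.graph.number_of_edges() == n_pos

    @pytest.mark.parametrize("quantile", [0.1, 0.25, 0.5])
    def test_retention_matches_sort_oracle(self, quantile):
        pathways = self._pathways(10, seed=3)
        net = build_similarity_network(pathways, quantile=quantile)
        scores = sorted((similarity(pathways[a], pathways[b])
                         for a, b in itertools.combinations(sorted(pathways), 2)),
                        reverse=True)
        scores = [s for s in scores if s > 0]
        k = max(1, math.ceil(quantile * len(scores)))
        cut = scores[k - 1]
        expected = sum(1 for s in scores if s >= cut)
        assert net.graph.number_of_edges() == expected
        assert net.threshold == cut

    def test_fewer_than_two_pathways_rejected(self):
        with pytest.raises(ValueError):
            build_similarity_network({"P": {"A"}})


class TestClustering:
    def _clique_pair(self, bridge=True):
        g = nx.Graph()
        for base in ("L", "R"):
            members = [f"{base}{i}" for i in range(6)]
            g.add_edges_from(itertools.combinations(members, 2))
        if bridge:
            g.add_edge("L0", "R0")
        return g

    def test_disjoint_cliques_two_clusters(self):
        clusters = cluster_map_equation(self._clique_pair(bridge=False), seed=1)
        assert len(set(clusters.values())) == 2
        assert len({clusters[f"L{i}"] for i in range(6)}) == 1

    def test_complete_graph_one_cluster(self):
        g = nx.complete_graph(8)
        g = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes})
        assert len(set(cluster_map_equation(g, seed=1).values())) == 1

    def test_bridged_cliques_two_clusters(self):
        """Two 6-cliques joined by one bridge: map equation splits them
        (frozen from a reference igraph community_infomap run)."""
        clusters = cluster_map_equation(self._clique_pair(bridge=True), seed=1)
        left = {clusters[f"L{i}"] for i in range(6)}
        right = {clusters[f"R{i}"] for i in range(6)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(30, 0.15, seed=9)
        g = nx.relabel_nodes(g, {i: f"P{i}" for i in g.nodes})
        a = cluster_map_equation(g, seed=4)
        b = cluster_map_equation(g, seed=4)
        assert a == b

    def test_singletons_get_own_cluster(self):
        g = nx.Graph()
        g.add_edge("A", "B")
        g.add_node("Z")
        clusters = cluster_map_equation(g, seed=0)
        assert clusters["Z"] not in {clusters["A"], clusters["B"]}

    def test_planted_two_block_recovery(self):
        """A planted two-block similarity network is recovered with adjusted
        Rand index >= 0.9 across 10 seeds."""
        from sklearn.metrics import adjusted_rand_score
        scores = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g = nx.Graph()
            truth = {}
            for block, base in enumerate(("A", "B")):
                members = [f"{base}{i}" for i in range(10)]
                for v in members:
                    truth[v] = block
                for u, v in itertools.combinations(members, 2):
                    if rng.uniform() < 0.7:
                        g.add_edge(u, v, similarity=1.0)
            for u in range(10):
                if rng.uniform() < 0.1:
                    g.add_edge(f"A{u}", f"B{u}", similarity=0.2)
            clusters = cluster_map_equation(g, seed=seed)
            labels = [clusters[v] for v in sorted(truth)]
            scores.append(adjusted_rand_score([truth[v] for v in sorted(truth)], labels))
        assert np.mean(scores) >= 0.9
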