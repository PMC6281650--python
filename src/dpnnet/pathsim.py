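"""Pathway contextual-similarity network and map-equation clustering.

Two enriched pathways are similar when they share genes and those shared
genes change in the same direction. The score is

    similarity = Jaccard(gene sets) * directional agreement,

where the agreement is the fraction of shared genes, with fold changes
available in both pathways' source datasets, whose signs agree; with a
single reference dataset (the human comparator, the default in the
pipeline) every covered shared gene agrees with itself and the score
reduces to the Jaccard index. Edges in the similarity network keep only the
top quantile of positive scores (top 25% by default), with all ties at the
cut retained; clusters come from two-level map-equation (Infomap) community
detection.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import igraph
import networkx as nx

__all__ = ["similarity", "build_similarity_network", "cluster_map_equation"]


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def similarity(genes_a, genes_b, fc_a=None, fc_b=None) -> float:
    """Gene-overlap x directional-agreement similarity in [0, 1].

    ``fc_a`` / ``fc_b`` map genes to log2 fold changes in each pathway's
    source dataset; omit both (or pass the same reference mapping) to score
    on gene overlap alone. Shared genes lacking a fold change on either
    side do not enter the agreement fraction; when no shared gene is
    covered, agreement defaults to 1.
    """
    a, b = set(genes_a), set(genes_b)
    if not a or not b:
        raise ValueError("similarity needs non-empty gene sets")
    inter = a & b
    if not inter:
        return 0.0
    jaccard = len(inter) / len(a | b)
    fc_a = fc_a or {}
    fc_b = fc_b or {}
    covered = [g for g in inter if g in fc_a and g in fc_b]
    if covered:
        agree = sum(1 for g in covered if _sign(fc_a[g]) == _sign(fc_b[g]))
        agreement = agree / len(covered)
    else:
        agreement = 1.0
    return jaccard * agreement


@dataclass
class SimilarityNetwork:
    """Thresholded pathway-similarity graph with optional cluster labels."""

    graph: nx.Graph
    threshold: float
    clusters: dict[str, int] = field(default_factory=dict)


def build_similarity_network(pathway_genes: dict[str, set],
                             reference_fold_changes: dict[str, float] | None = None,
                             quantile: float = 0.25,
                             score_fn=similarity) -> SimilarityNetwork:
    """Score all pathway pairs and keep the top quantile of positive scores.

    ``pathway_genes`` maps pathway name -> gene set; similarities are scored
    against a single reference fold-change map (``score_fn`` is pluggable).
    Among pairs with score > 0, the top ``quantile`` fraction is retained
    (at least one edge when any score is positive); all pairs tied with the
    cut score are kept. Every pathway appears as a node even if isolated.
    """
    names = sorted(pathway_genes)
    if len(names) < 2:
        raise ValueError("need at least two pathways")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    fc = reference_fold_changes or {}
    scored: list[tuple[str, str, float]] = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            s = score_fn(pathway_genes[a], pathway_genes[b], fc, fc)
            if s > 0.0:
                scored.append((a, b, s))
    g = nx.Graph()
    g.add_nodes_from(names)
    if not scored:
        return SimilarityNetwork(graph=g, threshold=float("inf"))
    values = sorted((s for _, _, s in scored), reverse=True)
    k = max(1, math.ceil(quantile * len(values)))
    threshold = values[k - 1]
    for a, b, s in scored:
        if s >= threshold:
            g.add_edge(a, b, similarity=s)
    return SimilarityNetwork(graph=g, threshold=threshold)


def cluster_map_equation(net: SimilarityNetwork | nx.Graph, seed: int = 0) -> dict[str, int]:
    """Two-level map-equation (Infomap) clustering, deterministic under seed.

    Edge similarity scores are used as flow weights. Singleton components
    receive their own cluster. Cluster ids are re-labelled deterministically
    by each cluster's lexicographically smallest member.
    """
    g = net.graph if isinstance(net, SimilarityNetwork) else net
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("cannot cluster an empty network")
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in g.edges]
    weights = [g.edges[a, b].get("similarity", 1.0) for a, b in g.edges]
    ig = igraph.Graph(len(nodes), edges)
    igraph.set_random_number_generator(random.Random(seed))
    try:
        membership = ig.community_infomap(edge_weights=weights or None).membership
    finally:
        igraph.set_random_number_generator(random)
    # relabel clusters by smallest member for reproducible ids
    groups: dict[int, list[str]] = {}
    for v, m in zip(nodes, membership):
        groups.setdefault(m, []).append(v)
    order = sorted(groups.values(), key=lambda members: min(members))
    out: dict[str, int] = {}
    for cid, members in enumerate(order):
        for v in members:
            out[v] = cid
    if isinstance(net, SimilarityNetwork):
        net.clusters = out
    return out
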