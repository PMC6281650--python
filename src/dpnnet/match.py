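"""Approximate subgraph matching between a murine (query) and the human
(database) transcriptional network.

The matcher follows the neighbourhood-signature approach of approximate
subgraph matching tools: a query node may match a database node when their
labels agree and at most a fraction ``mismatch_rho`` of the query node's
neighbours are missing from the database node's neighbourhood (missing
count <= ceil(rho * query degree)). Because gene labels are unique within a
network, the general many-to-many candidate search collapses to a per-label
neighbourhood test: high-degree "important" query nodes seed the match and
the match is extended over neighbours to a fixpoint, but under the collapsed
criterion the fixpoint is exactly the set of query nodes passing the test —
the seeding choice only affects traversal order. We implement the collapsed
algorithm and assert the equivalence in tests.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

__all__ = ["MatchParams", "SharedNetwork", "nh_signature", "match_networks",
           "pairwise_match_all"]


@dataclass(frozen=True)
class MatchParams:
    """Matching parameters.

    mismatch_rho : allowed fraction of a query node's neighbours missing from
        the database neighbourhood (default 0.10, the published setting).
    importance_fraction : fraction of top-degree query nodes used as seeds
        (default 0.25); affects traversal order only.
    """

    mismatch_rho: float = 0.10
    importance_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.mismatch_rho <= 1.0:
            raise ValueError("mismatch_rho must be in [0, 1]")
        if not 0.0 < self.importance_fraction <= 1.0:
            raise ValueError("importance_fraction must be in (0, 1]")


@dataclass
class SharedNetwork:
    """Conserved subnetwork extracted from one query-vs-database comparison.

    The node correspondence is the identity on gene labels; ``graph`` holds
    the matched genes and the edges present in both inputs.
    """

    label: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def nh_signature(network: nx.Graph, node: str) -> dict:
    """Neighbourhood signature used for candidate pruning.

    Returns the node label, its degree, the number of edges among its
    neighbours, and the neighbour label set.
    """
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    neighbours = set(network[node])
    n_conn = sum(1 for u in neighbours for v in network[u] if v in neighbours) // 2
    return {
        "label": node,
        "degree": len(neighbours),
        "n_neighbour_connections": n_conn,
        "neighbour_labels": frozenset(neighbours),
    }


def _node_passes(query: nx.Graph, db: nx.Graph, v: str, rho: float) -> bool:
    # mismatches are counted after restriction to common labels: a query
    # neighbour entirely absent from the database cannot be a mismatch
    # (the database may simply not cover that gene); a neighbour present in
    # the database but not adjacent to v there is one
    if v not in db:
        return False
    q_nbrs = set(query[v])
    missing = sum(1 for u in q_nbrs if u in db and u not in db[v])
    return missing <= math.ceil(rho * len(q_nbrs))


def match_networks(query: nx.Graph, db: nx.Graph, params: MatchParams | None = None) -> SharedNetwork:
    """Match a query network into a database network.

    Seed phase: the top ``importance_fraction`` of query nodes by degree
    (minimum one; ties by gene name) that pass the mismatch criterion start
    the match. Extension phase: neighbours of matched nodes are tested under
    the same criterion until no new node is added; remaining passing nodes
    found outside the explored region are re-seeded, so the result is the
    full criterion-passing set. The output subgraph contains exactly the
    edges present in both networks among matched nodes.
    """
    params = params or MatchParams()
    if query.graph.get("namespace", "human") != db.graph.get("namespace", "human"):
        raise ValueError("query and database networks are in different gene namespaces")
    rho = params.mismatch_rho

    # deterministic order: degree descending, then gene name
    by_importance = sorted(query.nodes, key=lambda n: (-query.degree(n), n))
    n_seeds = max(1, math.ceil(params.importance_fraction * len(by_importance)))
    seeds = [v for v in by_importance[:n_seeds] if _node_passes(query, db, v, rho)]

    matched: set[str] = set()
    queue: deque[str] = deque(seeds)
    matched.update(seeds)
    while queue:
        v = queue.popleft()
        for u in sorted(query[v]):
            if u not in matched and _node_passes(query, db, u, rho):
                matched.add(u)
                queue.append(u)
    # re-seed passing nodes not reachable from the important seeds; this makes
    # the fixpoint independent of the seeding fraction (asserted in tests)
    for v in by_importance[n_seeds:] + by_importance[:n_seeds]:
        if v not in matched and _node_passes(query, db, v, rho):
            matched.add(v)
            queue.append(v)
            while queue:
                w = queue.popleft()
                for u in sorted(query[w]):
                    if u not in matched and _node_passes(query, db, u, rho):
                        matched.add(u)
                        queue.append(u)

    label = query.graph.get("dataset", "")
    out = nx.Graph(dataset=label, namespace=query.graph.get("namespace", "human"))
    for v in sorted(matched):
        fc = dict(query.nodes[v].get("fold_change", {}))
        fc.update(db.nodes[v].get("fold_change", {}))
        datasets = tuple(sorted(set(query.nodes[v].get("datasets", ()))
                                | set(db.nodes[v].get("datasets", ()))))
        out.add_node(v, fold_change=fc, datasets=datasets)
    for a, b, attrs in query.edges(data=True):
        if a in matched and b in matched and db.has_edge(a, b):
            out.add_edge(a, b, **dict(db.edges[a, b] or attrs))
    return SharedNetwork(label=label, graph=out)


def pairwise_match_all(mouse_networks, human_network: nx.Graph,
                       params: MatchParams | None = None) -> list[SharedNetwork]:
    """Match every murine network against the human network, in input order."""
    mouse_networks = list(mouse_networks)
    if not mouse_networks:
        raise ValueError("need at least one mouse network")
    return [match_networks(q, human_network, params) for q in mouse_networks]
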