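"""Merging pairwise shared networks into one conserved network.

The merged human–mouse-conserved network is the union of the pairwise shared
networks: nodes carry fold changes per source dataset and a count of how
many shared networks contained them; edges keep the union of supporting
citations. A citation-support filter then removes weakly supported edges
(fewer than three citations by default) and drops nodes left isolated.
"""

from __future__ import annotations

import networkx as nx

from .match import SharedNetwork

__all__ = ["merge_shared_networks", "filter_edges_by_citations"]


def merge_shared_networks(shared) -> nx.Graph:
    """Union the shared networks' nodes and edges.

    Node attributes after merging: ``fold_change`` (dataset label -> log2
    fc, merged across inputs), ``datasets`` and ``n_source_networks`` (how
    many input shared networks contained the gene). Edge attributes:
    ``citations`` union and the resulting ``citation_count``.
    """
    shared = list(shared)
    if not shared:
        raise ValueError("need at least one shared network to merge")
    merged = nx.Graph(namespace="human")
    for sn in shared:
        g = sn.graph if isinstance(sn, SharedNetwork) else sn
        for v, attrs in g.nodes(data=True):
            if v not in merged:
                merged.add_node(v, fold_change={}, datasets=set(), n_source_networks=0)
            node = merged.nodes[v]
            node["fold_change"].update(attrs.get("fold_change", {}))
            node["datasets"].update(attrs.get("datasets", ()))
            node["n_source_networks"] += 1
        for a, b, attrs in g.edges(data=True):
            cites = set(attrs.get("citations", ()))
            if merged.has_edge(a, b):
                merged.edges[a, b]["citations"].update(cites)
            else:
                merged.add_edge(a, b, citations=set(cites))
    for v in merged.nodes:
        merged.nodes[v]["datasets"] = tuple(sorted(merged.nodes[v]["datasets"]))
    for a, b in merged.edges:
        cites = merged.edges[a, b]["citations"]
        merged.edges[a, b]["citations"] = tuple(sorted(cites))
        merged.edges[a, b]["citation_count"] = len(cites)
    return merged


def filter_edges_by_citations(net: nx.Graph, min_citations: int = 3) -> nx.Graph:
    """Keep edges supported by at least ``min_citations`` citations.

    Edges below the threshold are removed; nodes left with no edges are
    dropped from the returned network (they are excluded from centrality)
    but recorded, sorted, in ``graph.graph["isolated_dropped"]``.
    """
    for a, b, attrs in net.edges(data=True):
        if "citation_count" not in attrs:
            raise ValueError(f"edge ({a}, {b}) is missing the citation_count attribute")
    out = net.copy()
    weak = [(a, b) for a, b, c in out.edges(data="citation_count") if c < min_citations]
    out.remove_edges_from(weak)
    isolated = sorted(v for v in out.nodes if out.degree(v) == 0)
    out.remove_nodes_from(isolated)
    out.graph["isolated_dropped"] = tuple(isolated)
    out.graph["min_citations"] = min_citations
    return out
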