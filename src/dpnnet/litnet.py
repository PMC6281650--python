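"""Literature co-occurrence corpus and per-dataset transcriptional networks.

The corpus stands in for a sentence-level text-mining system: an undirected
map from unordered gene pairs to the set of citation identifiers in which the
two genes co-occur. A dataset's transcriptional network is the corpus
subgraph induced on the dataset's DEGs; isolated DEGs are retained as
degree-0 nodes so that downstream reports can distinguish "no literature
support" from "not differentially expressed".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .deg import DEGSet

__all__ = ["CooccurrenceCorpus", "build_network"]

logger = logging.getLogger(__name__)


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CooccurrenceCorpus:
    """Unordered gene pair -> set of supporting citation identifiers."""

    edges: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def add(self, gene_a: str, gene_b: str, citations) -> None:
        if gene_a == gene_b:
            raise ValueError(f"self-pair not allowed: {gene_a}")
        citations = set(citations)
        if not citations:
            raise ValueError(f"edge ({gene_a}, {gene_b}) needs at least one citation")
        self.edges.setdefault(_pair(gene_a, gene_b), set()).update(citations)

    def citation_count(self, gene_a: str, gene_b: str) -> int:
        return len(self.edges.get(_pair(gene_a, gene_b), ()))

    def __len__(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out


def build_network(deg: DEGSet, corpus: CooccurrenceCorpus) -> nx.Graph:
    """Induce the co-occurrence subgraph on one DEG set.

    Nodes are the DEG genes (isolated ones kept with degree 0); an edge is
    present iff the pair is in the corpus and both endpoints are DEGs. Edge
    attributes: ``citations`` (sorted tuple of ids) and ``citation_count``.
    Node attributes: ``fold_change`` (dict dataset label -> log2 fc) and
    ``datasets`` (tuple of labels), in merge-ready form.
    """
    if deg.species != "human":
        raise ValueError("networks are built in the human namespace; map orthologues first")
    g = nx.Graph(dataset=deg.label, namespace="human")
    if len(deg) == 0:
        logger.warning("empty DEG set %r: returning empty network", deg.label)
        return g
    for gene in sorted(deg.records):
        g.add_node(gene, fold_change={deg.label: deg.records[gene]}, datasets=(deg.label,))
    members = deg.genes()
    for (a, b), cites in corpus.edges.items():
        if a in members and b in members:
            g.add_edge(a, b, citations=tuple(sorted(cites)), citation_count=len(cites))
    return g
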