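"""Readers and writers for the pipeline's plain-text formats.

Formats: probe-statistic TSV (transcript_id, gene_id, n_significant_probes,
fdr, fold_change); DEG TSV (gene, log2 fold change); co-occurrence corpus
TSV (gene_a, gene_b, pipe-separated citation ids); orthologue TSV
(mouse_id, human_id); GMT pathway collections; GraphML and SIF network
serializations. GraphML node/edge attributes that are containers are
serialized as JSON strings (GraphML only supports scalars) and restored on
read. All writers emit deterministically ordered rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .deg import DEGSet, OrthologueMap, ProbeStatRecord
from .litnet import CooccurrenceCorpus

__all__ = [
    "read_probe_table", "write_probe_table", "probe_records_from_frame",
    "read_deg_tsv", "write_deg_tsv",
    "read_corpus_tsv", "write_corpus_tsv",
    "read_orthologue_tsv", "write_orthologue_tsv",
    "read_gmt", "write_gmt",
    "write_graphml", "read_graphml", "write_sif",
]

PROBE_COLUMNS = ["transcript_id", "gene_id", "n_significant_probes", "fdr", "fold_change"]


def read_probe_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "gene_id": str})
    missing = set(PROBE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return frame[PROBE_COLUMNS]


def write_probe_table(frame: pd.DataFrame, path) -> None:
    frame = frame[PROBE_COLUMNS].sort_values(["gene_id", "transcript_id"], kind="stable")
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def probe_records_from_frame(frame: pd.DataFrame) -> list[ProbeStatRecord]:
    return [
        ProbeStatRecord(
            transcript_id=str(r.transcript_id), gene_id=str(r.gene_id),
            n_significant_probes=int(r.n_significant_probes),
            fdr=float(r.fdr), fold_change=float(r.fold_change),
        )
        for r in frame.itertuples(index=False)
    ]


def write_deg_tsv(deg: DEGSet, path) -> None:
    frame = pd.DataFrame(
        {"gene": sorted(deg.records), "log2_fold_change": [deg.records[g] for g in sorted(deg.records)]}
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_deg_tsv(path, label: str = "", species: str = "human") -> DEGSet:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return DEGSet(label=label, species=species,
                  records=dict(zip(frame["gene"], frame["log2_fold_change"])))


def write_corpus_tsv(corpus: CooccurrenceCorpus, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcitations\n")
        for (a, b) in sorted(corpus.edges):
            fh.write(f"{a}\t{b}\t{'|'.join(sorted(corpus.edges[(a, b)]))}\n")


def read_corpus_tsv(path) -> CooccurrenceCorpus:
    corpus = CooccurrenceCorpus()
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"{path}: expected corpus TSV header")
        for line in fh:
            a, b, cites = line.rstrip("\n").split("\t")
            corpus.add(a, b, cites.split("|"))
    return corpus


def write_orthologue_tsv(omap: OrthologueMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("mouse_id\thuman_id\n")
        for mouse in sorted(omap.pairs):
            fh.write(f"{mouse}\t{omap.pairs[mouse]}\n")


def read_orthologue_tsv(path) -> OrthologueMap:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("mouse_id"):
            raise ValueError(f"{path}: expected orthologue TSV header")
        for line in fh:
            mouse, human = line.rstrip("\n").split("\t")
            pairs.append((mouse, human))
    return OrthologueMap.from_pairs(pairs)


def write_gmt(pathways: dict[str, set], path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(pathways):
            genes = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def read_gmt(path) -> dict[str, set]:
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out


_JSON_ATTRS = ("fold_change", "datasets", "citations", "isolated_dropped")


def write_graphml(net: nx.Graph, path) -> None:
    g = net.copy()
    for _, attrs in g.nodes(data=True):
        for key in list(attrs):
            if isinstance(attrs[key], (dict, tuple, list, set, frozenset)):
                value = attrs[key]
                if isinstance(value, (set, frozenset)):
                    value = sorted(value)
                attrs[key] = json.dumps(value, sort_keys=True)
    for _, _, attrs in g.edges(data=True):
        for key in list(attrs):
            if isinstance(attrs[key], (dict, tuple, list, set, frozenset)):
                value = attrs[key]
                if isinstance(value, (set, frozenset)):
                    value = sorted(value)
                attrs[key] = json.dumps(value, sort_keys=True)
    for key in list(g.graph):
        if isinstance(g.graph[key], (dict, tuple, list, set, frozenset)):
            g.graph[key] = json.dumps(sorted(g.graph[key])
                                      if isinstance(g.graph[key], (set, frozenset))
                                      else g.graph[key], sort_keys=True)
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    mapping = {}

    def restore(attrs):
        for key in list(attrs):
            if key in _JSON_ATTRS and isinstance(attrs[key], str):
                attrs[key] = json.loads(attrs[key])
                if isinstance(attrs[key], list):
                    attrs[key] = tuple(attrs[key])
    for _, attrs in g.nodes(data=True):
        restore(attrs)
    for _, _, attrs in g.edges(data=True):
        restore(attrs)
    restore(g.graph)
    return nx.relabel_nodes(g, mapping) if mapping else g


def write_sif(net: nx.Graph, path, interaction: str = "cooccurrence") -> None:
    """Simple interaction format: one edge per line; isolated nodes bare."""
    with open(path, "w") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), net.edges)):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for v in sorted(net.nodes):
            if net.degree(v) == 0:
                fh.write(f"{v}\n")


def write_bundle(bundle, outdir) -> dict[str, str]:
    """Write a complete synthetic input bundle; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def slug(label: str) -> str:
        return "".join(c if c.isalnum() else "_" for c in label)

    for deg, table in zip(bundle.deg_sets, bundle.probe_tables):
        name = f"probes_{slug(deg.label)}.tsv"
        write_probe_table(table, outdir / name)
        files[deg.label] = name
    write_corpus_tsv(bundle.corpus, outdir / "corpus.tsv")
    write_orthologue_tsv(bundle.orthologue_map, outdir / "orthologues.tsv")
    write_gmt(bundle.pathways, outdir / "pathways.gmt")
    with open(outdir / "universe.txt", "w") as fh:
        fh.write("\n".join(bundle.universe) + "\n")
    meta = {
        "seed": bundle.config.seed,
        "n_genes": bundle.config.n_genes,
        "planted_hubs": bundle.hubs,
        "hub_signs": bundle.hub_signs,
        "datasets": [
            {"label": d.label, "species": d.species, "probes": files[d.label]}
            for d in bundle.deg_sets
        ],
    }
    with open(outdir / "bundle.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return files
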