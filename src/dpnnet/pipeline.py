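"""End-to-end pipeline orchestration.

Stages: probe-statistic filtering and orthologue mapping -> per-dataset
co-occurrence networks -> pairwise approximate matching against the human
network -> merged conserved network with the citation filter -> centrality
and the random-gene-set null -> pathway enrichment (per dataset and for the
top central genes) -> pathway-similarity network and clustering. Each stage
writes its outputs under the configured output directory and re-loads its
inputs from there, so the pipeline is restartable per stage; a manifest
records input hashes, seeds and versions. Outputs are deterministically
ordered, so identical config + seed reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .centrality import compute_centralities, top_central_genes
from .deg import filter_significant_transcripts, map_orthologues, shared_deg_counts
from .enrich import PathwayDB, direction_summary, enrich, recurrent_pathways
from .litnet import build_network
from .match import MatchParams, pairwise_match_all
from .merge import filter_edges_by_citations, merge_shared_networks
from .nullmodel import build_null, z_test
from .pathsim import build_similarity_network, cluster_map_equation

__all__ = ["DatasetSpec", "PipelineConfig", "Pipeline", "run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class DatasetSpec:
    label: str
    species: str
    probes: str  # path to the probe-statistic TSV


@dataclass
class PipelineConfig:
    datasets: list[DatasetSpec]
    corpus: str
    orthologues: str
    gmt: str
    universe: str
    outdir: str
    min_probes: int = 5
    fdr_max: float = 0.01
    match_params: MatchParams = field(default_factory=MatchParams)
    min_citations: int = 3
    null_replicates: int = 1000
    centrality_k_small: int = 10
    centrality_k_large: int = 50
    similarity_quantile: float = 0.25
    min_shared_datasets: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        humans = [d for d in self.datasets if d.species == "human"]
        if len(humans) != 1:
            raise ValueError("config must declare exactly one human dataset")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def resolve(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        datasets = [DatasetSpec(label=d["label"], species=d["species"],
                                probes=resolve(d["probes"]))
                    for d in raw["datasets"]]
        mp = raw.get("match_params", {})
        return cls(
            datasets=datasets,
            corpus=resolve(raw["corpus"]),
            orthologues=resolve(raw["orthologues"]),
            gmt=resolve(raw["gmt"]),
            universe=resolve(raw["universe"]),
            outdir=resolve(raw["outdir"]),
            min_probes=raw.get("min_probes", 5),
            fdr_max=raw.get("fdr_max", 0.01),
            match_params=MatchParams(
                mismatch_rho=mp.get("mismatch_rho", 0.10),
                importance_fraction=mp.get("importance_fraction", 0.25),
            ),
            min_citations=raw.get("min_citations", 3),
            null_replicates=raw.get("null_replicates", 1000),
            centrality_k_small=raw.get("centrality_k_small", 10),
            centrality_k_large=raw.get("centrality_k_large", 50),
            similarity_quantile=raw.get("similarity_quantile", 0.25),
            min_shared_datasets=raw.get("min_shared_datasets", 3),
            seed=raw.get("seed", 0),
        )

    @classmethod
    def from_bundle(cls, bundle_dir, outdir, **overrides) -> "PipelineConfig":
        """Convenience constructor over a `simulate` bundle directory."""
        bundle_dir = Path(bundle_dir)
        meta_path = bundle_dir / "bundle.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"not a bundle directory (missing {meta_path})")
        with open(meta_path) as fh:
            meta = json.load(fh)
        datasets = [DatasetSpec(label=d["label"], species=d["species"],
                                probes=str(bundle_dir / d["probes"]))
                    for d in meta["datasets"]]
        return cls(datasets=datasets,
                   corpus=str(bundle_dir / "corpus.tsv"),
                   orthologues=str(bundle_dir / "orthologues.tsv"),
                   gmt=str(bundle_dir / "pathways.gmt"),
                   universe=str(bundle_dir / "universe.txt"),
                   outdir=str(outdir),
                   seed=meta.get("seed", 0),
                   **overrides)

    def check_paths(self) -> None:
        paths = [self.corpus, self.orthologues, self.gmt, self.universe]
        paths += [d.probes for d in self.datasets]
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label)


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


class Pipeline:
    """Stage-by-stage pipeline over an output directory."""

    def __init__(self, config: PipelineConfig):
        config.check_paths()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    # -- helpers -----------------------------------------------------------
    def _timed(self, name, fn):
        t0 = time.perf_counter()
        result = fn()
        logger.info("stage %-12s %6.2fs", name, time.perf_counter() - t0)
        return result

    def _path(self, name) -> Path:
        return self.outdir / name

    def _load_degs(self):
        degs = []
        for spec in self.config.datasets:
            degs.append(io.read_deg_tsv(self._path(f"deg_{_slug(spec.label)}.tsv"),
                                        label=spec.label, species="human"))
        return degs

    # -- stages ------------------------------------------------------------
    def stage_filter(self):
        """Probe filter, transcript->gene collapse, orthologue mapping."""
        cfg = self.config
        omap = io.read_orthologue_tsv(cfg.orthologues)
        summary = []
        degs = []
        for spec in cfg.datasets:
            records = io.probe_records_from_frame(io.read_probe_table(spec.probes))
            deg, report = filter_significant_transcripts(
                records, cfg.min_probes, cfg.fdr_max,
                label=spec.label, species=spec.species)
            n_unmapped = 0
            if spec.species == "mouse":
                deg, dropped = map_orthologues(deg, omap)
                n_unmapped = len(dropped)
            io.write_deg_tsv(deg, self._path(f"deg_{_slug(spec.label)}.tsv"))
            degs.append(deg)
            summary.append({"label": spec.label, "species": spec.species,
                            "n_input_transcripts": report.n_input,
                            "n_genes_after_filter": report.n_genes,
                            "n_unmapped": n_unmapped,
                            "n_genes": len(deg)})
        shared = shared_deg_counts(degs, cfg.min_shared_datasets)
        pd.DataFrame(sorted(shared.counts.items()),
                     columns=["gene", "n_datasets"]).to_csv(
            self._path("shared_deg_counts.tsv"), sep="\t", index=False)
        with open(self._path("filter_summary.json"), "w") as fh:
            json.dump({"datasets": summary,
                       "n_distinct_genes": shared.n_distinct,
                       "min_shared_datasets": cfg.min_shared_datasets,
                       "n_shared": shared.n_shared}, fh, indent=2, sort_keys=True)
        return degs

    def stage_networks(self):
        corpus = io.read_corpus_tsv(self.config.corpus)
        nets = []
        for deg in self._load_degs():
            net = build_network(deg, corpus)
            io.write_graphml(net, self._path(f"net_{_slug(deg.label)}.graphml"))
            nets.append(net)
        return nets

    def stage_match(self):
        cfg = self.config
        nets = {spec.label: io.read_graphml(self._path(f"net_{_slug(spec.label)}.graphml"))
                for spec in cfg.datasets}
        human_label = next(d.label for d in cfg.datasets if d.species == "human")
        queries = [nets[d.label] for d in cfg.datasets if d.species == "mouse"]
        shared = pairwise_match_all(queries, nets[human_label], cfg.match_params)
        rows = []
        for sn in shared:
            io.write_graphml(sn.graph, self._path(f"shared_{_slug(sn.label)}.graphml"))
            rows.append({"query": sn.label,
                         "n_matched_genes": sn.graph.number_of_nodes(),
                         "n_matched_edges": sn.graph.number_of_edges()})
        pd.DataFrame(rows).to_csv(self._path("match_summary.tsv"), sep="\t", index=False)
        return shared

    def stage_merge(self):
        cfg = self.config
        shared = [io.read_graphml(self._path(f"shared_{_slug(d.label)}.graphml"))
                  for d in cfg.datasets if d.species == "mouse"]
        merged = merge_shared_networks(shared)
        io.write_graphml(merged, self._path("merged.graphml"))
        filtered = filter_edges_by_citations(merged, cfg.min_citations)
        io.write_graphml(filtered, self._path("merged_filtered.graphml"))
        io.write_sif(filtered, self._path("merged_filtered.sif"))
        labels = [d.label for d in cfg.datasets]
        rows = []
        for gene in sorted(filtered.nodes):
            fc = filtered.nodes[gene].get("fold_change", {})
            rows.append({"gene": gene,
                         "n_source_networks": filtered.nodes[gene].get("n_source_networks", 0),
                         **{lab: fc.get(lab, float("nan")) for lab in labels}})
        pd.DataFrame(rows).to_csv(self._path("merged_fold_changes.tsv"),
                                  sep="\t", index=False, float_format=_FLOAT_FMT)
        return filtered

    def stage_centrality(self):
        net = io.read_graphml(self._path("merged_filtered.graphml"))
        table = compute_centralities(net)
        table.to_csv(self._path("centrality.tsv"), sep="\t", float_format=_FLOAT_FMT)
        return table

    def stage_null(self):
        cfg = self.config
        with open(cfg.universe) as fh:
            universe = [line.strip() for line in fh if line.strip()]
        corpus = io.read_corpus_tsv(cfg.corpus)
        sizes = [len(deg) for deg in self._load_degs()]
        bg = build_null(universe, corpus, sizes, n_replicates=cfg.null_replicates,
                        params=cfg.match_params, min_citations=cfg.min_citations,
                        seed=cfg.seed)
        bg.summary().to_csv(self._path("null_background.tsv"), sep="\t",
                            float_format=_FLOAT_FMT)
        table = pd.read_csv(self._path("centrality.tsv"), sep="\t", index_col="gene")
        with_p = z_test(table, bg)
        with_p.to_csv(self._path("centrality_pvalues.tsv"), sep="\t",
                      float_format=_FLOAT_FMT)
        return bg, with_p

    def stage_enrich(self):
        cfg = self.config
        with open(cfg.universe) as fh:
            universe = {line.strip() for line in fh if line.strip()}
        db = PathwayDB(pathways=io.read_gmt(cfg.gmt), universe=universe)
        degs = self._load_degs()
        per_dataset = {}
        for deg in degs:
            table = enrich(deg.genes() & universe, db)
            table.to_csv(self._path(f"enrich_{_slug(deg.label)}.tsv"),
                         sep="\t", index=False, float_format=_FLOAT_FMT)
            per_dataset[deg.label] = table
        recurrent = recurrent_pathways(per_dataset, min_datasets=5)
        recurrent.to_csv(self._path("recurrent_pathways.tsv"), sep="\t", index=False)
        cent = pd.read_csv(self._path("centrality.tsv"), sep="\t", index_col="gene")
        central_small = top_central_genes(cent, min(cfg.centrality_k_small, len(cent)))
        central_table = enrich(central_small & universe, db)
        central_table.to_csv(self._path("enrich_central_genes.tsv"),
                             sep="\t", index=False, float_format=_FLOAT_FMT)
        direction_rows = []
        for _, row in central_table.iterrows():
            if row["n_overlap"] == 0:
                continue
            summ = direction_summary(set(row["genes"].split(",")), degs)
            summ.insert(0, "pathway", row["pathway"])
            direction_rows.append(summ)
        if direction_rows:
            pd.concat(direction_rows, ignore_index=True).to_csv(
                self._path("pathway_directions.tsv"), sep="\t", index=False,
                float_format=_FLOAT_FMT)
        return per_dataset, central_table

    def stage_pathsim(self):
        cfg = self.config
        with open(cfg.universe) as fh:
            universe = {line.strip() for line in fh if line.strip()}
        db = PathwayDB(pathways=io.read_gmt(cfg.gmt), universe=universe)
        cent = pd.read_csv(self._path("centrality.tsv"), sep="\t", index_col="gene")
        central_large = top_central_genes(cent, min(cfg.centrality_k_large, len(cent)))
        table = enrich(central_large & universe, db)
        significant = table.loc[(table["q_value"] < 0.05) & (table["n_overlap"] > 0),
                                "pathway"].tolist()
        if len(significant) < 2:  # fall back to nominal significance on tiny runs
            significant = table.loc[(table["p_value"] < 0.05) & (table["n_overlap"] > 0),
                                    "pathway"].tolist()
        if len(significant) < 2:  # last resort: pathways sharing >=2 central genes
            significant = table.loc[table["n_overlap"] >= 2, "pathway"].tolist()
        human_label = next(d.label for d in cfg.datasets if d.species == "human")
        human_deg = io.read_deg_tsv(self._path(f"deg_{_slug(human_label)}.tsv"),
                                    label=human_label, species="human")
        edges_path = self._path("pathway_similarity.tsv")
        clusters_path = self._path("pathway_clusters.tsv")
        if len(significant) < 2:
            pd.DataFrame(columns=["pathway_a", "pathway_b", "similarity"]).to_csv(
                edges_path, sep="\t", index=False)
            pd.DataFrame(columns=["pathway", "cluster"]).to_csv(
                clusters_path, sep="\t", index=False)
            return None
        genes = {name: db.pathways[name] for name in significant}
        simnet = build_similarity_network(genes, human_deg.records,
                                          quantile=cfg.similarity_quantile)
        clusters = cluster_map_equation(simnet, seed=cfg.seed)
        rows = [{"pathway_a": a, "pathway_b": b,
                 "similarity": simnet.graph.edges[a, b]["similarity"]}
                for a, b in sorted(map(lambda e: tuple(sorted(e)), simnet.graph.edges))]
        pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "similarity"]).to_csv(
            edges_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        pd.DataFrame(sorted(clusters.items()), columns=["pathway", "cluster"]).to_csv(
            clusters_path, sep="\t", index=False)
        for name, cid in clusters.items():
            simnet.graph.nodes[name]["cluster"] = cid
        io.write_graphml(simnet.graph, self._path("pathway_similarity.graphml"))
        return simnet

    def write_manifest(self):
        cfg = self.config
        inputs = {p: _sha256(p) for p in
                  [cfg.corpus, cfg.orthologues, cfg.gmt, cfg.universe]
                  + [d.probes for d in cfg.datasets]}
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "null_replicates": cfg.null_replicates,
            "match_params": {"mismatch_rho": cfg.match_params.mismatch_rho,
                             "importance_fraction": cfg.match_params.importance_fraction},
            "min_citations": cfg.min_citations,
            "datasets": [d.label for d in cfg.datasets],
            "inputs_sha256": inputs,
        }
        with open(self._path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    def run_all(self):
        self._timed("filter", self.stage_filter)
        self._timed("networks", self.stage_networks)
        self._timed("match", self.stage_match)
        self._timed("merge", self.stage_merge)
        self._timed("centrality", self.stage_centrality)
        self._timed("null", self.stage_null)
        self._timed("enrich", self.stage_enrich)
        self._timed("pathsim", self.stage_pathsim)
        self.write_manifest()
        return self.outdir


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write the output bundle; see :class:`Pipeline`."""
    return Pipeline(config).run_all()
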