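"""Synthetic input generator with planted conserved hub genes.

Emulates the statistical structure the pipeline assumes, at desk scale:

* a platform gene universe (human namespace) with mouse orthologue ids;
* eight DEG sets — seven "mouse" models and one "human" — whose sizes
  default to the published per-dataset DEG counts scaled down tenfold
  (2,955 / 871 / 5,068 / 2,096 / 723 / 482 / 3,022 / 5,757 -> universe of
  1,000 genes);
* probe-level statistic tables for each dataset, in which every DEG gene
  carries a transcript passing the significance filter (>=5 significant
  probes, FDR < 1%) and decoy transcripts fail it;
* a heavy-tailed literature co-occurrence corpus in which a configurable
  set of planted hub genes has a boosted edge propensity — the ground truth
  for centrality-recovery tests;
* a 1:1 mouse->human orthologue map with dropout (planted hubs are exempt,
  since the planted structure must survive mapping to serve as ground
  truth);
* pathway gene sets, one of which is enriched for the planted hubs.

Fold changes are log2-scale: magnitudes |N(0, 1)| with a +0.5 shift for
hubs; each hub keeps a consistent sign across all datasets, non-hub signs
are independent per dataset. Citation counts per corpus edge follow a
discrete power law (Zipf, exponent 2.5, minimum 1); a configurable fraction
of edges is forced below three citations to exercise the merge filter.
Every generator is fully deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deg import DEGSet, OrthologueMap
from .litnet import CooccurrenceCorpus

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate_universe",
           "planted_hubs", "generate_deg_sets", "generate_probe_table",
           "generate_corpus", "generate_orthologue_map", "generate_pathways",
           "generate_bundle"]

#: published per-dataset DEG counts, scaled down tenfold
DEFAULT_DEG_SIZES = (296, 87, 507, 210, 72, 48, 302, 576)
DEFAULT_LABELS = ("8wk db/db", "16wk db/db", "24wk db/db", "5wk ob/ob",
                  "13wk ob/ob", "26wk ob/ob F", "34wk STZ", "human")


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 1000
    n_datasets: int = 8
    deg_set_sizes: tuple[int, ...] = DEFAULT_DEG_SIZES
    dataset_labels: tuple[str, ...] = DEFAULT_LABELS
    n_planted_hubs: int = 5
    hub_edge_boost: float = 10.0
    orthologue_dropout: float = 0.05
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 40)
    citation_exponent: float = 2.5
    mean_degree: float = 6.0
    low_citation_fraction: float = 0.3
    decoy_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if len(self.deg_set_sizes) != self.n_datasets:
            raise ValueError("deg_set_sizes length must equal n_datasets")
        if len(self.dataset_labels) != self.n_datasets:
            raise ValueError("dataset_labels length must equal n_datasets")
        if self.deg_set_sizes and self.n_planted_hubs > min(self.deg_set_sizes):
            raise ValueError("n_planted_hubs must not exceed the smallest DEG set")
        for name in ("orthologue_dropout", "low_citation_fraction", "decoy_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.hub_edge_boost <= 0:
            raise ValueError("hub_edge_boost must be positive")
        lo, hi = self.pathway_size_range
        if not 0 < lo <= hi:
            raise ValueError("pathway_size_range must satisfy 0 < min <= max")

    def scaled(self, **overrides) -> "SyntheticConfig":
        return replace(self, **overrides)


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent child streams keyed off the config seed
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _mouse_id(human_id: str) -> str:
    # mouse symbols conventionally use title case
    return human_id.capitalize()


def generate_universe(config: SyntheticConfig) -> list[str]:
    """The platform gene universe: ``n_genes`` unique human-style ids."""
    return [f"GENE{i:05d}" for i in range(config.n_genes)]


def planted_hubs(universe, config: SyntheticConfig) -> tuple[list[str], dict[str, int]]:
    """Choose the planted hub genes and their conserved fold-change signs."""
    rng = _rng(config, 1)
    if config.n_planted_hubs == 0 or not universe:
        return [], {}
    hubs = sorted(rng.choice(universe, size=config.n_planted_hubs, replace=False).tolist())
    signs = {h: int(rng.choice((-1, 1))) for h in hubs}
    return hubs, signs


def generate_deg_sets(universe, config: SyntheticConfig,
                      hubs=None, hub_signs=None) -> list[DEGSet]:
    """Draw the per-dataset DEG memberships and log2 fold changes.

    Every planted hub is a member of every dataset with a consistent
    fold-change sign; the remaining members are sampled without replacement
    from the rest of the universe. Mouse datasets are emitted in the mouse
    namespace; the last dataset is human.
    """
    universe = list(universe)
    if any(s > len(universe) for s in config.deg_set_sizes):
        raise ValueError("a DEG set size exceeds the universe")
    if hubs is None:
        hubs, hub_signs = planted_hubs(universe, config)
    rng = _rng(config, 2)
    non_hubs = [g for g in universe if g not in set(hubs)]
    out = []
    for i, (size, label) in enumerate(zip(config.deg_set_sizes, config.dataset_labels)):
        members = list(hubs) + list(rng.choice(non_hubs, size=size - len(hubs),
                                               replace=False))
        records = {}
        for g in members:
            mag = abs(rng.normal(0.0, 1.0))
            if g in hub_signs:
                sign = hub_signs[g]
                mag += 0.5
            else:
                sign = int(rng.choice((-1, 1)))
            records[g] = sign * mag
        species = "human" if i == config.n_datasets - 1 else "mouse"
        if species == "mouse":
            records = {_mouse_id(g): fc for g, fc in records.items()}
        out.append(DEGSet(label=label, species=species, records=records))
    return out


def generate_probe_table(deg: DEGSet, universe, config: SyntheticConfig,
                         stream: int = 0) -> pd.DataFrame:
    """Probe-level statistics whose significance filter reproduces ``deg``.

    Each DEG gene gets one passing transcript carrying the assigned fold
    change, and some get a second passing transcript with a smaller |fold
    change| (so the per-gene collapse rule is exercised). Decoy transcripts
    for non-DEG genes fail either the probe-count or the FDR rule.
    """
    rng = _rng(config, 100 + stream)
    rows = []
    to_native = _mouse_id if deg.species == "mouse" else (lambda g: g)
    for g in sorted(deg.records):
        fc = deg.records[g]
        rows.append((f"T_{g}_1", g, int(5 + rng.poisson(3.0)),
                     float(rng.uniform(0.0, 0.0099)), fc))
        if rng.uniform() < 0.2:  # secondary weaker transcript, also passing
            rows.append((f"T_{g}_2", g, int(5 + rng.poisson(2.0)),
                         float(rng.uniform(0.0, 0.0099)), fc * float(rng.uniform(0.1, 0.9))))
    deg_genes = set(deg.records)
    decoys = [to_native(g) for g in universe if to_native(g) not in deg_genes]
    n_decoys = int(config.decoy_fraction * len(deg.records))
    for g in rng.choice(decoys, size=min(n_decoys, len(decoys)), replace=False):
        if rng.uniform() < 0.5:  # too few significant probes
            rows.append((f"T_{g}_1", g, int(rng.integers(0, 5)),
                         float(rng.uniform(0.0, 0.0099)), float(rng.normal(0.0, 1.0))))
        else:  # FDR too high
            rows.append((f"T_{g}_1", g, int(5 + rng.poisson(3.0)),
                         float(rng.uniform(0.01, 0.5)), float(rng.normal(0.0, 1.0))))
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id",
                                       "n_significant_probes", "fdr", "fold_change"])


def generate_corpus(universe, config: SyntheticConfig, hubs=None) -> CooccurrenceCorpus:
    """Heavy-tailed co-occurrence corpus with boosted hub propensity.

    Edge endpoints are drawn proportionally to per-gene weights (1 for
    ordinary genes, ``hub_edge_boost`` for planted hubs) until
    ``mean_degree * n / 2`` distinct edges exist. Citation counts are
    Zipf-distributed (>=1); a ``low_citation_fraction`` of edges is capped
    below three citations so the merge filter has work to do.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    if hubs is None:
        hubs, _ = planted_hubs(universe, config)
    rng = _rng(config, 3)
    hub_set = set(hubs)
    weights = np.array([config.hub_edge_boost if g in hub_set else 1.0 for g in universe])
    weights = weights / weights.sum()
    n = len(universe)
    target = min(int(round(config.mean_degree * n / 2)), n * (n - 1) // 2)
    corpus = CooccurrenceCorpus()
    pmid = 0
    max_draws = 50 * target + 100
    draws = 0
    while len(corpus) < target and draws < max_draws:
        draws += 1
        a, b = rng.choice(n, size=2, replace=False, p=weights)
        ga, gb = universe[a], universe[b]
        key = (ga, gb) if ga <= gb else (gb, ga)
        if key in corpus.edges:
            continue
        if rng.uniform() < config.low_citation_fraction:
            count = int(rng.integers(1, 3))  # 1 or 2 citations
        else:
            count = 2 + int(rng.zipf(config.citation_exponent))  # >= 3
        ids = {f"PMID{pmid + j:08d}" for j in range(count)}
        pmid += count
        corpus.add(ga, gb, ids)
    return corpus


def generate_orthologue_map(universe, config: SyntheticConfig,
                            always_keep=()) -> OrthologueMap:
    """1:1 mouse->human map covering (1 - dropout) of the universe.

    Genes in ``always_keep`` (the planted hubs, in the full bundle) are
    never dropped.
    """
    rng = _rng(config, 4)
    keep = set(always_keep)
    pairs = []
    for g in universe:
        if g in keep or rng.uniform() >= config.orthologue_dropout:
            pairs.append((_mouse_id(g), g))
    return OrthologueMap.from_pairs(pairs)


def generate_pathways(universe, config: SyntheticConfig, hubs=None) -> dict[str, set[str]]:
    """Pathway gene sets; the first is enriched for the planted hubs."""
    universe = list(universe)
    if hubs is None:
        hubs, _ = planted_hubs(universe, config)
    rng = _rng(config, 5)
    lo, hi = config.pathway_size_range
    out: dict[str, set[str]] = {}
    for i in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        name = f"PATHWAY_{i:03d}"
        if i == 0 and hubs:
            fill = [g for g in universe if g not in set(hubs)]
            extra = rng.choice(fill, size=max(size - len(hubs), 0), replace=False)
            genes = set(hubs) | set(extra.tolist())
            name = "PLANTED_HUB_PATHWAY"
        else:
            genes = set(rng.choice(universe, size=min(size, len(universe)),
                                   replace=False).tolist())
        out[name] = genes
    return out


@dataclass
class SyntheticBundle:
    """A complete, self-consistent set of pipeline inputs."""

    config: SyntheticConfig
    universe: list[str]
    hubs: list[str]
    hub_signs: dict[str, int]
    deg_sets: list[DEGSet]            # native namespaces (mouse sets in mouse ids)
    probe_tables: list[pd.DataFrame]  # one per dataset, native namespace
    corpus: CooccurrenceCorpus       # human namespace
    orthologue_map: OrthologueMap
    pathways: dict[str, set[str]]

    @property
    def human_deg(self) -> DEGSet:
        return next(d for d in self.deg_sets if d.species == "human")


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate all inputs from one config; deterministic given the seed."""
    universe = generate_universe(config)
    hubs, hub_signs = planted_hubs(universe, config)
    deg_sets = generate_deg_sets(universe, config, hubs, hub_signs)
    probe_tables = [generate_probe_table(d, universe, config, stream=i)
                    for i, d in enumerate(deg_sets)]
    corpus = generate_corpus(universe, config, hubs)
    omap = generate_orthologue_map(universe, config, always_keep=hubs)
    pathways = generate_pathways(universe, config, hubs)
    return SyntheticBundle(config=config, universe=universe, hubs=hubs,
                           hub_signs=hub_signs, deg_sets=deg_sets,
                           probe_tables=probe_tables, corpus=corpus,
                           orthologue_map=omap, pathways=pathways)
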