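"""Differential-expression filtering, orthologue mapping and DEG sharing.

Differentially expressed genes (DEGs) enter the pipeline as per-transcript
probe statistics computed upstream (single-probe significance analysis of
microarray data). A transcript is called significant when it has at least
``min_probes`` significant probes and a false discovery rate strictly below
``fdr_max`` (defaults: 5 probes, FDR < 1%). Murine DEG sets are then lifted
into the human gene namespace through a 1:1 orthologue map so that all eight
datasets can be compared and fed to the network stages.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "ProbeStatRecord",
    "DEGSet",
    "OrthologueMap",
    "FilterReport",
    "filter_significant_transcripts",
    "map_orthologues",
    "shared_deg_counts",
    "SharedDEGReport",
]

logger = logging.getLogger(__name__)

MOUSE = "mouse"
HUMAN = "human"


@dataclass(frozen=True)
class ProbeStatRecord:
    """Per-transcript probe-level summary statistics.

    Parameters
    ----------
    transcript_id : str
        Transcript identifier (unique within a dataset table).
    gene_id : str
        Gene the transcript belongs to.
    n_significant_probes : int
        Number of individually significant probes supporting the transcript.
    fdr : float
        False discovery rate (q-value) of the transcript call, in [0, 1].
    fold_change : float
        Signed log2 fold change between the two sample groups.
    """

    transcript_id: str
    gene_id: str
    n_significant_probes: int
    fdr: float
    fold_change: float

    def is_valid(self) -> bool:
        return self.n_significant_probes >= 0 and 0.0 <= self.fdr <= 1.0


@dataclass
class DEGSet:
    """One dataset's differentially expressed genes with log2 fold changes."""

    label: str
    species: str
    records: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in (MOUSE, HUMAN):
            raise ValueError(f"species must be {MOUSE!r} or {HUMAN!r}, got {self.species!r}")

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> set[str]:
        return set(self.records)


@dataclass
class OrthologueMap:
    """1:1 mouse-to-human gene identifier map.

    Many-to-one conflicts (duplicate mouse keys, or two mouse genes pointing
    at the same human gene) are resolved first-pair-wins in input order; the
    discarded pairs are logged and counted in ``n_conflicts``.
    """

    pairs: dict[str, str] = field(default_factory=dict)
    n_conflicts: int = 0

    @classmethod
    def from_pairs(cls, pairs) -> "OrthologueMap":
        resolved: dict[str, str] = {}
        used_human: set[str] = set()
        conflicts = 0
        for mouse_id, human_id in pairs:
            if mouse_id in resolved or human_id in used_human:
                conflicts += 1
                logger.debug("orthologue conflict dropped: %s -> %s", mouse_id, human_id)
                continue
            resolved[mouse_id] = human_id
            used_human.add(human_id)
        if conflicts:
            logger.info("orthologue map: %d conflicting pairs dropped (first wins)", conflicts)
        return cls(pairs=resolved, n_conflicts=conflicts)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class FilterReport:
    """Bookkeeping for the significance filter."""

    n_input: int
    n_retained_transcripts: int
    n_dropped: int
    n_rejected_invalid: int
    n_genes: int


def filter_significant_transcripts(
    records,
    min_probes: int = 5,
    fdr_max: float = 0.01,
    label: str = "",
    species: str = HUMAN,
) -> tuple[DEGSet, FilterReport]:
    """Apply the transcript significance filter and collapse to genes.

    Retains transcripts with ``n_significant_probes >= min_probes`` and
    ``fdr < fdr_max`` (strict, mirroring "FDR < 1%"). Malformed records
    (negative probe counts, FDR outside [0, 1]) are rejected with a logged
    diagnostic rather than raising. Transcripts are collapsed to genes by
    keeping the retained transcript with the largest absolute fold change;
    ties break on lexicographically smallest transcript id.

    Returns the gene-level :class:`DEGSet` and a :class:`FilterReport`.
    """
    records = list(records)
    best: dict[str, tuple[float, str, float]] = {}  # gene -> (|fc|, transcript, fc)
    n_kept = 0
    n_invalid = 0
    for rec in records:
        if not rec.is_valid():
            n_invalid += 1
            logger.warning("rejecting malformed probe record %s (probes=%d fdr=%g)",
                           rec.transcript_id, rec.n_significant_probes, rec.fdr)
            continue
        if rec.n_significant_probes >= min_probes and rec.fdr < fdr_max:
            n_kept += 1
            key = (abs(rec.fold_change), rec.transcript_id, rec.fold_change)
            prev = best.get(rec.gene_id)
            # larger |fc| wins; on exact tie the smaller transcript_id wins
            if prev is None or key[0] > prev[0] or (key[0] == prev[0] and key[1] < prev[1]):
                best[rec.gene_id] = key
    deg = DEGSet(label=label, species=species,
                 records={g: fc for g, (_, _, fc) in best.items()})
    report = FilterReport(
        n_input=len(records),
        n_retained_transcripts=n_kept,
        n_dropped=len(records) - n_kept - n_invalid,
        n_rejected_invalid=n_invalid,
        n_genes=len(deg),
    )
    return deg, report


def map_orthologues(deg: DEGSet, omap: OrthologueMap) -> tuple[DEGSet, list[str]]:
    """Convert a murine DEG set to the human orthologue namespace.

    Genes without a map entry are dropped and returned (sorted) alongside the
    mapped set; fold changes are carried over unchanged.
    """
    if deg.species != MOUSE:
        raise ValueError(f"map_orthologues expects a mouse DEG set, got species={deg.species!r}")
    mapped: dict[str, float] = {}
    dropped: list[str] = []
    for gene, fc in deg.records.items():
        human = omap.pairs.get(gene)
        if human is None:
            dropped.append(gene)
        else:
            mapped[human] = fc
    return DEGSet(label=deg.label, species=HUMAN, records=mapped), sorted(dropped)


@dataclass
class SharedDEGReport:
    counts: dict[str, int]
    n_distinct: int
    n_shared: int
    min_datasets: int

    def shared_genes(self) -> set[str]:
        return {g for g, c in self.counts.items() if c >= self.min_datasets}


def shared_deg_counts(deg_sets, min_datasets: int) -> SharedDEGReport:
    """Count, per gene, how many datasets contain it.

    All sets must already be in the human namespace. Reports the number of
    distinct genes and how many appear in at least ``min_datasets`` sets.
    """
    for deg in deg_sets:
        if deg.species != HUMAN:
            raise ValueError(f"dataset {deg.label!r} is not in the human namespace")
    counts: Counter[str] = Counter()
    for deg in deg_sets:
        counts.update(deg.genes())
    counts = dict(counts)
    n_shared = sum(1 for c in counts.values() if c >= min_datasets)
    return SharedDEGReport(counts=counts, n_distinct=len(counts),
                           n_shared=n_shared, min_datasets=min_datasets)
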