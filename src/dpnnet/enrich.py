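"""Pathway over-representation testing with direction summaries.

Enrichment is the right-tailed hypergeometric test (equivalently a one-sided
Fisher exact test): for a query of n genes drawn from a universe of N genes,
the probability of seeing at least the observed overlap with a pathway of K
genes. Benjamini–Hochberg q-values are attached alongside raw p-values.
Direction summaries report, per dataset, the mean log2 fold change of the
pathway's genes and a majority-vote direction (up/down/mixed) — the sign of
the count majority, not of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PathwayDB", "enrich", "direction_summary", "recurrent_pathways"]


@dataclass
class PathwayDB:
    """Named pathway gene sets over a platform background universe."""

    pathways: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pathways = {name: set(genes) for name, genes in self.pathways.items()}
        self.universe = set(self.universe)
        stray = {name for name, genes in self.pathways.items()
                 if self.universe and not genes <= self.universe}
        # pathway annotations routinely cite genes off-platform; restrict
        for name in stray:
            self.pathways[name] &= self.universe

    def __len__(self) -> int:
        return len(self.pathways)


def enrich(query, db: PathwayDB) -> pd.DataFrame:
    """Right-tailed hypergeometric over-representation test.

    Returns one row per pathway sorted by p-value (ties by name) with
    columns: pathway, n_overlap, pathway_size, ratio (overlap/pathway size),
    p_value, neg_log10_p, q_value (Benjamini–Hochberg), genes
    (comma-joined overlap). Raises if any query gene is outside the
    universe.
    """
    query = set(query)
    offenders = sorted(query - db.universe)
    if offenders:
        raise ValueError(f"query genes outside the universe: {', '.join(offenders)}")
    n_universe = len(db.universe)
    n_query = len(query)
    rows = []
    for name in sorted(db.pathways):
        genes = db.pathways[name]
        if not genes:
            continue
        overlap = sorted(query & genes)
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(genes), n_query))
        p = min(p, 1.0)
        rows.append({
            "pathway": name,
            "n_overlap": k,
            "pathway_size": len(genes),
            "ratio": k / len(genes),
            "p_value": p,
            "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
            "genes": ",".join(overlap),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(["p_value", "pathway"], kind="stable").reset_index(drop=True)
    return out[["pathway", "n_overlap", "pathway_size", "ratio",
                "p_value", "neg_log10_p", "q_value", "genes"]]


def direction_summary(pathway_genes, deg_sets) -> pd.DataFrame:
    """Per-dataset mean fold change and majority direction of a pathway.

    For each DEG set: the mean log2 fold change over the pathway genes
    present in the set, counts of up- and down-regulated genes, and the
    majority direction ("up"/"down"; a tie gives "mixed"). Datasets with no
    overlapping gene yield a null entry (NaN mean, direction None).
    """
    genes = set(pathway_genes)
    rows = []
    for deg in deg_sets:
        folds = [fc for g, fc in deg.records.items() if g in genes]
        n_up = sum(1 for f in folds if f > 0)
        n_down = sum(1 for f in folds if f < 0)
        if not folds:
            direction = None
            mean_fc = np.nan
        else:
            mean_fc = float(np.mean(folds))
            direction = "up" if n_up > n_down else "down" if n_down > n_up else "mixed"
        rows.append({"dataset": deg.label, "n_genes": len(folds),
                     "mean_fold_change": mean_fc, "n_up": n_up,
                     "n_down": n_down, "direction": direction})
    return pd.DataFrame(rows)


def recurrent_pathways(results_per_dataset: dict[str, pd.DataFrame],
                       min_datasets: int = 5, q_max: float = 0.05) -> pd.DataFrame:
    """Pathways significantly enriched (q < q_max) in at least min_datasets sets."""
    counts: dict[str, int] = {}
    for table in results_per_dataset.values():
        if table.empty:
            continue
        for name in table.loc[table["q_value"] < q_max, "pathway"]:
            counts[name] = counts.get(name, 0) + 1
    rows = [{"pathway": p, "n_datasets": c} for p, c in counts.items() if c >= min_datasets]
    out = pd.DataFrame(rows, columns=["pathway", "n_datasets"])
    return out.sort_values(["n_datasets", "pathway"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)
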