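"""Random-gene-set null model for centrality significance.

The null replays the entire conserved-network pipeline on random gene sets:
for each replicate, gene sets of the same sizes as the real DEG sets are
drawn uniformly without replacement from the platform universe, each is
induced on the co-occurrence corpus, every "mouse" network is matched
against the "human" network (the last set), the shared networks are merged
and citation-filtered, and all four centrality metrics are computed. The
scores of every gene in every replicate network are pooled per metric into
the background distribution for a one-sided (upper-tail) Z-test: the
hypothesis of interest is that the real network's genes are more central
than genes of random networks of matched size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import METRICS, compute_centralities
from .deg import DEGSet
from .litnet import CooccurrenceCorpus, build_network
from .match import MatchParams, pairwise_match_all
from .merge import filter_edges_by_citations, merge_shared_networks

__all__ = ["NullBackground", "build_null", "conserved_network_from_gene_sets", "z_test"]


def conserved_network_from_gene_sets(gene_sets, corpus: CooccurrenceCorpus,
                                     params: MatchParams | None = None,
                                     min_citations: int = 3,
                                     labels=None):
    """Run gene sets through build -> match -> merge -> filter.

    ``gene_sets`` are collections of human-namespace genes (or DEGSets); the
    last one plays the role of the human database network, all others are
    matched against it as queries. Returns the filtered merged network.
    """
    gene_sets = list(gene_sets)
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene sets (queries + database)")
    if labels is None:
        labels = [f"set{i}" for i in range(len(gene_sets))]
    degs = []
    for label, gs in zip(labels, gene_sets):
        if isinstance(gs, DEGSet):
            degs.append(gs)
        else:
            degs.append(DEGSet(label=label, species="human",
                               records={g: 0.0 for g in gs}))
    nets = [build_network(d, corpus) for d in degs]
    shared = pairwise_match_all(nets[:-1], nets[-1], params)
    merged = merge_shared_networks(shared)
    return filter_edges_by_citations(merged, min_citations)


@dataclass
class NullBackground:
    """Pooled background distribution of null centrality scores."""

    samples: dict[str, np.ndarray]
    n_replicates: int
    seed: int
    pooling: str = "pooled"
    n_empty_replicates: int = 0
    mean: dict[str, float] = field(init=False)
    sd: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.mean = {m: float(np.mean(s)) if len(s) else float("nan")
                     for m, s in self.samples.items()}
        self.sd = {m: float(np.std(s, ddof=1)) if len(s) > 1 else 0.0
                   for m, s in self.samples.items()}

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.mean, "sd": self.sd,
             "n": {m: len(s) for m, s in self.samples.items()}}
        ).rename_axis("metric")


def build_null(universe, corpus: CooccurrenceCorpus, deg_set_sizes,
               n_replicates: int = 1000, params: MatchParams | None = None,
               min_citations: int = 3, seed: int = 0,
               pooling: str = "pooled") -> NullBackground:
    """Build the random-gene-set background distribution.

    For each replicate, ``len(deg_set_sizes)`` gene sets of the stated sizes
    are sampled without replacement from ``universe`` and pushed through the
    full pipeline; each resulting gene's four centrality scores join the
    per-metric background. ``pooling`` selects between pooling every gene's
    score ("pooled", default) and pooling per-replicate means
    ("replicate_mean"). Replicates whose filtered merged network is empty
    contribute nothing (counted in ``n_empty_replicates``).
    """
    universe = sorted(universe)
    sizes = list(deg_set_sizes)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if any(s > len(universe) for s in sizes):
        raise ValueError("a requested gene-set size exceeds the universe")
    if pooling not in ("pooled", "replicate_mean"):
        raise ValueError(f"unknown pooling mode {pooling!r}")
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {m: [] for m in METRICS}
    n_empty = 0
    for _ in range(n_replicates):
        gene_sets = [list(rng.choice(universe, size=s, replace=False)) for s in sizes]
        net = conserved_network_from_gene_sets(gene_sets, corpus, params, min_citations)
        if net.number_of_nodes() == 0:
            n_empty += 1
            continue
        table = compute_centralities(net)
        for m in METRICS:
            if pooling == "pooled":
                samples[m].extend(table[m].tolist())
            else:
                samples[m].append(float(table[m].mean()))
    return NullBackground(
        samples={m: np.asarray(v, dtype=float) for m, v in samples.items()},
        n_replicates=n_replicates, seed=seed, pooling=pooling,
        n_empty_replicates=n_empty,
    )


def z_test(real: pd.DataFrame, bg: NullBackground) -> pd.DataFrame:
    """Upper-tail Z-test of real centrality scores against the background.

    For each gene and metric: ``z = (score - bg mean) / bg sd`` and
    ``p = P(Z >= z)`` under the standard normal. Returns the input table
    with ``z_<metric>`` and ``p_<metric>`` columns appended. Raises if any
    metric's background standard deviation is zero.
    """
    out = real.copy()
    for m in METRICS:
        if bg.sd[m] == 0.0 or not np.isfinite(bg.sd[m]):
            raise ValueError(f"degenerate null background: metric {m!r} has sd=0")
        z = (real[m] - bg.mean[m]) / bg.sd[m]
        out[f"z_{m}"] = z
        out[f"p_{m}"] = stats.norm.sf(z)
    return out
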