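# Methods

## Pipeline model

The object of study is a *conserved transcriptional network*: genes that
are differentially expressed in many independent diabetic-neuropathy
datasets **and** whose literature-reported interactions survive a
cross-species comparison. The pipeline treats the literature co-occurrence
corpus as a fixed relational backdrop; each dataset contributes a gene set,
and all network structure is inherited from the corpus by induction.

### DEG filtering

A transcript is significant when it has ≥ `min_probes` (default 5)
significant probes and FDR < `fdr_max` (default 0.01; the comparison is
strict, matching "FDR < 1%", while the probe rule is inclusive, matching
"a minimum of five"). Transcripts collapse to genes by keeping the
retained transcript with the largest |log2 fold change| (ties: smallest
transcript id). The collapse rule is our choice — downstream analysis is
gene-level and no rule is canonical; max-|FC| keeps the strongest signal
and is deterministic. Malformed records (negative probe counts, FDR
outside [0,1]) are rejected with a logged diagnostic rather than aborting
a whole table.

### Orthologue mapping

The map is forced 1:1: conflicting pairs (duplicate mouse or human ids)
resolve first-pair-wins in file order, which is deterministic and mirrors
how an opaque annotation database would have been consumed. Unmapped genes
are dropped and counted; |mapped| + |dropped| = |input| always.

### Network construction

A dataset's network is exactly the corpus subgraph induced on its genes;
isolated DEGs are retained at degree 0 for reporting but matching only
propagates connected structure and post-filter isolated nodes are excluded
from centrality. Edges are undirected (co-occurrence is symmetric) and
carry the citation-id set; `citation_count` is its cardinality.

### Approximate matching

Gene labels are unique, so the general many-to-many approximate subgraph
matching problem collapses to a per-label neighbourhood test: query node v
matches iff v is in the database and

    |{u ∈ N_q(v) : u ∈ V_db, u ∉ N_db(v)}| ≤ ceil(ρ · deg_q(v)),  ρ = 0.10.

Mismatches are counted **after restriction to common labels**: a query
neighbour entirely absent from the database network is not a mismatch
(the database simply does not cover that gene), whereas a present but
non-adjacent neighbour is. The unrestricted alternative would make every
high-degree node unmatchable whenever the database DEG set covers less
than (1−ρ) of the universe — under it, hub genes can never be recovered.
Extra database neighbours are free in both readings (the database is the
richer context). Seeding by top-degree "importance" only fixes traversal
order; the fixpoint is the full criterion-passing set, asserted by test.
The shared network contains the matched genes and the edges present in
both inputs.

### Merge and citation filter

Merging is a node/edge union; per-dataset fold changes are kept side by
side, `n_source_networks` counts the shared networks containing each gene,
and citation sets union. The support filter keeps edges with ≥ 3 citations
(inclusive at 3) and drops nodes left isolated (recorded in
`graph["isolated_dropped"]`), so the analysed network has minimum degree 1.

### Centrality conventions

- degree: simple-graph neighbour count;
- closeness: unnormalized 1/Σd with unreachable pairs contributing a
  penalty distance equal to the node count (keeps the score defined on
  disconnected networks; on a ~700-node network the scale is ~7e-4, the
  scale produced by social-network-analysis tooling without
  normalization); a singleton component scores 0;
- betweenness: unnormalized, endpoints excluded, each unordered pair
  counted once (delegated to networkx's Brandes implementation and
  cross-checked against an independent sigma-counting oracle in the
  tests);
- eigenvector: power iteration on A + I of the largest connected component
  (the +I shift guarantees convergence on bipartite components without
  changing the principal eigenvector), tolerance 1e-10, max 10,000
  iterations, non-negative, unit Euclidean norm; other components score 0.

Edge weights are ignored throughout: the four definitions are topological.
`top_central_genes(k)` is the union over metrics of the per-metric top-k,
with all ties at the k-th score included.

### Random-gene-set null

For each replicate, gene sets of the same sizes as the real (post-mapping)
DEG sets are drawn uniformly from the platform universe and pushed through
the *identical* pipeline (induce → match → merge → filter → centrality).
Random sets are drawn directly in the human namespace — the orthologue
step is the identity for them, since the stated background is "all genes
on the platform". All genes of all replicate networks are pooled per
metric (a per-replicate-mean summary is available behind
`pooling="replicate_mean"`); the Z-test is upper-tail one-sided — the
hypothesis of interest is that real genes are *more* central than random
ones. Default 1,000 replicates; tests and the acceptance script use 100,
which the reduced-replicate-invariance test shows is statistically
indistinguishable at these scales.

Known limitation: the pooled background is heavily discrete (the modal
null gene has degree 1 and betweenness 0), so the normal-theory p-values
have atoms and are *not* uniform under the null — an inherent property of
a Z-test on a non-normal background, visible in published analyses of this
design where every gene's closeness p-value lands in a narrow band. The
p-values are therefore comparative scores, not calibrated tail
probabilities; an empirical-percentile variant would be uniform by
construction but is not what this design prescribes.

### Enrichment

Right-tailed hypergeometric test, identical to the one-sided Fisher exact
test on the 2×2 table (cross-checked numerically in the tests);
Benjamini–Hochberg q-values attached; raw −log10 p reported alongside.
The universe is the gene-level platform background; pathway annotations
are intersected with it. Direction summaries report the per-dataset mean
log2 fold change of member genes and a majority-vote direction — the sign
of the *count* majority, not of the mean, so one extreme gene cannot flip
a pathway's direction label.

### Pathway similarity and clustering

similarity(A, B) = Jaccard(A, B) × (fraction of shared genes, covered by
fold changes on both sides, whose signs agree). The two ingredients
(gene overlap, shared directionality) are fixed; the combining formula is
this package's definition and is pluggable (`score_fn`). With a single
reference dataset (the human comparator, the default) every covered shared
gene trivially agrees with itself and the score reduces to Jaccard. Edges
keep the top 25% of positive scores, ties at the cut retained; zero-score
pairs can never be edges, so the quantile is over positive scores.
Clustering is two-level map-equation (Infomap) via python-igraph, using
similarity scores as flow weights, made deterministic by installing
`random.Random(seed)` as igraph's RNG per call; cluster ids are relabelled
by each cluster's lexicographically smallest member. The pipeline selects
pathways for this stage by q < 0.05 against the top-50-central genes,
falling back to nominal p < 0.05 and then to an overlap of ≥ 2 central
genes on small synthetic runs where few pathways reach significance.

## Synthetic world

The generator emulates the inputs' statistical structure, not their
biology:

- **Universe**: 1,000 genes (the published per-dataset DEG counts
  2,955/871/5,068/2,096/723/482/3,022/5,757 scaled down tenfold give the
  default set sizes 296/87/507/210/72/48/302/576 over this universe).
- **Fold changes**: log2 scale, magnitudes |N(0,1)|, +0.5 magnitude shift
  for hubs; each hub keeps one sign across all datasets (so cross-dataset
  direction heatmaps are meaningful), non-hub signs independent.
- **Corpus**: endpoints drawn proportionally to per-gene weights (hubs get
  `hub_edge_boost`, default 10×) until mean degree 6 is reached; citation
  counts are Zipf(2.5) shifted to ≥ 3, except a 30% fraction forced to 1–2
  citations so the merge filter has work to do. Mean degree 6 reflects
  that literature co-mention graphs restricted to a disease context are
  sparse; it was fixed before any recovery experiment and not revisited.
- **Probe tables**: every DEG gene gets one passing transcript carrying
  its fold change (and sometimes a weaker passing secondary transcript, to
  exercise the collapse rule); decoy transcripts fail exactly one of the
  two filter rules.
- **Orthologue map**: 1:1 with 5% dropout; planted hubs are exempt from
  dropout because the planted structure is the ground truth the pipeline
  is tested against — dropout of a hub would change the question, not the
  answer.
- **Pathways**: 50 random gene sets of 10–40 genes; the first contains all
  planted hubs.

What a green test does *not* establish: the generator plants structure by
boosting edge propensity, so recovery tests validate the pipeline's
plumbing and statistics, not its behaviour on real literature graphs
(which have community structure, degree assortativity and citation biases
the generator does not model). Nor does any test validate the biological
interpretation of central genes.

## Numerical and degenerate-input choices

- Eigenvector power iteration always converges thanks to the +I shift;
  a non-convergence after 10,000 iterations logs a warning and returns the
  last iterate.
- Empty DEG sets build empty networks with a warning; empty merged
  networks abort centrality with an error; null replicates whose merged
  network is empty contribute nothing and are counted.
- A zero standard deviation in any null metric raises an error naming the
  metric rather than emitting infinite z-scores.
- All writers emit sorted rows and `%.10g` floats, so identical configs
  and seeds reproduce byte-identical outputs (asserted end-to-end).
- Seeds: every generator derives independent child streams from the one
  config seed; no global RNG state is consumed.

## Scale choices in the tests

Unit tests run on a 150-gene universe with eight sets of 15–70 genes and
reduced replicate counts; the acceptance tests run at the stated scales
(oracle checks on 100 graphs ≤ 50 nodes and 200 graph pairs ≤ 15 nodes;
null calibration at universe 300 with 100 replicates; hub recovery on the
default 1,000-gene world across 10 seeds with 100-replicate nulls;
determinism on the default bundle). The full suite completes in a few
minutes on one CPU.
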