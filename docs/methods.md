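# Methods

This note documents the models and procedures implemented in `coexreg`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Preprocessing

Genes whose **total** read count across samples is below
`min_total_count` (default 10) are removed; the threshold is inclusive
(a row sum of exactly 10 survives). Normalisation uses median-of-ratios
size factors: per-gene geometric means over samples define a reference,
each sample's factor is its median count/reference ratio over genes
with no zero counts, and factors are rescaled to geometric mean 1. The
variance-stabilising step is a shifted log,
`log2(count/factor + pseudocount)` with pseudocount 1. A full
dispersion-trend VST (as in DESeq2-style differential-expression work)
is deliberately not reimplemented: downstream, the values feed only a
variance ranking and Pearson correlations, and the shifted log
preserves the rank structure and monotonicity those rely on. Because
factors are anchored to geometric mean 1, a global rescaling of all
counts is a pure additive shift on the log2 scale and leaves every
between-sample contrast unchanged.

High-variance selection keeps the top `ceil((1 − q)·G)` genes by sample
variance (default q = 0.95, the "q95" filter). A count rule rather
than a variance threshold makes the output size deterministic under
ties; ties are broken by gene identifier. On 130,020 genes the rule
selects exactly 6,501.

## Co-expression network and modules

The network is **signed**: `a_ij = ((1 + cor_ij)/2)^β`, so strong
anti-correlation maps to weight ≈ 0 rather than to a strong edge. The
default power β = 12 can be replaced by a data-driven pick: for each
candidate power the connectivities `k_i = Σ_{j≠i} a_ij` are binned into
10 equal-width bins and the scale-free fit index is the R² of
log10(frequency) against log10(mean k). The smallest power reaching
`r2_target` (default 0.80) wins; otherwise the best-fitting power is
used with a warning. Note that whether any power reaches 0.80 depends
on the degree heterogeneity of the data — equal-sized planted modules
produce a bimodal, not scale-free, degree distribution, which is why
the pipeline's default is the fixed power.

Topological overlap is the standard unsigned measure
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
`l_ij = Σ_{u≠i,j} a_iu a_uj`, computed by matrix product
(`l = A² − 2A` for a unit diagonal) and cross-checked in the tests
against a brute-force double loop at 1e-12.

Module detection is a **static cut of the average-linkage dendrogram**
of `1 − TOM`, not a reimplementation of the dynamic hybrid tree cut.
The cut height is chosen by scanning merge-height quantiles from 0.50
to 0.99 and keeping the cut that yields the most branches of at least
`min_module_size` (default 30) genes, breaking ties toward fewer
unassigned genes and then the higher cut. A fixed quantile can be
forced via `cut_quantile`. The scan exists because any single fixed
quantile ties the resolution of the cut to the gene count: on small
matrices the top percentile of merges spans only a handful of joins and
distinct modules collapse into one branch.

Average linkage absorbs weakly attached genes into branches below the
cut, so detection is followed by a **coherence filter**
(`refine_modules`): genes whose kME to their own module eigengene falls
below `min_kme` (default 0.5) are moved to the unassigned (grey)
module, and modules that drop below the size floor dissolve. The filter
is disabled when `min_module_size` is 1, where every branch is a valid
module by contract. Finally, modules whose eigengenes are closer than
`merge_cut_height` (default 0.25) in correlation dissimilarity are
merged iteratively, closest pair first, recomputing eigengenes after
each merge.

Eigengenes are the first right singular vector of the module's
row-standardised expression, sign-oriented to correlate non-negatively
with the module's mean profile and scaled to unit variance. Module–
stage association uses Pearson correlation against one-vs-rest stage
indicators with two-sided p-values from the t distribution on n − 2
degrees of freedom; key modules are those with positive, significant
correlation to the stage of interest. Hub genes are module members with
kME ≥ 0.80 (inclusive).

## Overlapping clustering

Clusters are grown greedily on the interaction network. Seeds are
uncovered nodes in decreasing degree order (ties by identifier). A
cluster grows by repeatedly adding the neighbour with most edges into
the current members (ties again by identifier), subject to two
constraints at the moment of insertion: post-addition density
`d_k ≥ d_min`, and cluster property `cp_nk = E_nk/(d_k·N_k) ≥ cp_min`
(default 0.5). A singleton's density is defined as 1. Emitted clusters
need at least `min_cluster_size` (default 2) members; members are
marked covered but stay in the graph, so later clusters may overlap
them. The growth loop and tie-breaks are fully pinned, making the
output a pure function of graph and parameters; every emitted cluster
records its insertion order so the tests can replay the growth and
verify the constraints held step by step. The density sweep defaults to
{0.5, 0.6, 0.7, 0.8, 0.9}.

## Enrichment, SScore, ROC

Cluster enrichment is the one-sided hypergeometric upper tail
`P(X ≥ a)` for the 2×2 table of cluster membership against regulatory
labels over a fixed background (the clustered network's node set by
default). The one-sided tail is used because it exactly reproduces the
reference worked examples on the 338-gene / 30-regulatory background
(e.g. a 15-node cluster holding 9 regulatory genes gives p = 3.52e-7);
the two-sided variant does not. The computation delegates to
`scipy.stats.hypergeom`; tests verify it against exhaustive tail
enumeration for all backgrounds up to N = 25.

A gene's SScore is `−log10` of the smallest p-value among clusters
containing it; genes in no cluster score 0. The log base is
presentational only: the ROC/AUC machinery is invariant under any
strictly monotone transform of the scores (property-tested), so base
choice cannot affect density selection. ROC thresholds sweep the unique
scores in descending order behind a sentinel above the maximum, calling
a gene positive when its score is ≥ the threshold; the AUC is the
trapezoidal area under (FPR, TPR). The density with maximal AUC is
selected, ties resolved toward the smaller (coarser) density. Cluster
significance uses strict p < alpha (default 0.05) with no
multiple-testing correction at this stage; candidates are the known
regulatory genes inside at least one significant cluster, ranked by
SScore then identifier.

Pathway enrichment of candidate lists shares the identical
hypergeometric kernel, adds a Bonferroni correction whose divisor is
the number of sets passing the minimum-overlap filter (overlap ≥ 3),
and applies the conventional enrichment-factor > 1.5 and adjusted
p < 0.05 filters. The gene universe is an explicit required input.

## Synthetic data

The count generator emulates a stage-resolved developmental
transcriptome at a deliberately reduced scale: by default 250 genes ×
12 samples (3 samples in each of four stages: egg, third-instar larva,
pupa, adult), with four planted modules of 50 genes and 50 unstructured
noise genes. Each module has a latent per-sample factor — its true
eigengene — shifted by `stage_effect_size` (default 2) latent standard
deviations in the associated stage's samples. Gene log-means are
`sqrt(ρ)·factor + sqrt(1 − ρ)·noise` with ρ the within-module
correlation (default 0.9), plus a per-gene baseline (normal, mean 3 on
the natural-log scale) and a per-sample library factor (uniform on
0.7–1.3); counts are negative-binomial with size parameter
`dispersion` (default 10, i.e. variance = μ + μ²/10). The same seed
gives bit-identical output.

The network generator plants 10 clusters of 8 nodes in a 338-node
graph, each cluster holding 3 of the 30 regulatory labels, with
intra-cluster edge probability 1.0 (planted cliques; the realised edge
count per cluster is fixed at `round(p·pairs)` so planted density is
not a binomial draw) over a background edge probability of 0.01. The
8-node / 3-regulatory margins are the smallest configuration the
enrichment test can call significant on this background (p = 0.026),
i.e. the significance boundary the reference analysis itself operated
at; a 12-node cluster with 3 regulatory genes (p = 0.09) would be
structurally undetectable.

What the generator does **not** emulate: read-level sequencing noise,
gene length and GC biases, isoform structure, correlated noise between
modules, batch effects, and the scale of a real transcriptome (130k
transcripts). Passing recovery tests therefore show the pipeline's
statistical machinery is sound under its own model assumptions, not
that real data meet those assumptions.

## Numerical and degenerate-input conventions

Zero-variance genes get correlation 0 (adjacency `(1/2)^β`, kME 0) with
a warning. The top-k selection rounds `(1 − q)·G` to 9 decimals before
the ceiling, so binary floating point cannot inflate the count (0.05 ×
100 must select 5, not 6). Hypergeometric p-values are clamped into
(0, 1]; ROC requires both a positive and a negative class and raises
otherwise. Empty graphs cluster to an empty set; an all-removed count
matrix raises with a threshold hint rather than returning an empty
frame.

## Known limitations

- The static-cut module detection has no within-branch sub-splitting;
  deeply nested module structure that the dynamic hybrid algorithm
  would resolve may stay merged.
- The clustering growth rule is a deterministic reconstruction of a
  density-based overlapping procedure described at the equation level
  only; other implementations may order insertions differently and emit
  slightly different cluster boundaries at equal parameters.
- AUC-based density selection inherits the instability of small label
  sets: with 30 positives, AUC differences of ~0.01 between densities
  are within seed-to-seed noise.
- Problem sizes in the tests and the acceptance script (250-gene
  expression matrices, 338-node networks, 20-seed Monte-Carlo suites)
  are the package's chosen reference conditions; statistics quoted in
  the documentation refer to these conditions.
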