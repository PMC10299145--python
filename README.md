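# coexreg

Prioritising candidate regulatory genes from developmental transcriptome
counts by combining a weighted gene co-expression network with
overlapping graph clustering and enrichment-driven ROC scoring.

## The problem

Insect development (the motivating system is a lepidopteran oil-palm
pest with egg, larval, pupal and adult stages) is driven by hormone
signalling whose transcriptional regulators are attractive targets for
RNAi-based control. Given stage-resolved RNA-seq counts, an interaction
network over the proteins of interest, and a list of genes annotated as
regulatory, the pipeline asks: *which regulatory genes sit inside
densely interacting, stage-associated gene neighbourhoods?*

The procedure:

1. **Preprocess** — drop genes with fewer than 10 reads in total,
   normalise by median-of-ratios size factors, shift-log transform, and
   keep the top-5% most variable genes (the q95 filter).
2. **Co-expression network** — signed adjacency
   `a_ij = ((1 + cor(x_i, x_j))/2)^β` (default β = 12), topological
   overlap `TOM_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij)`, modules
   from average-linkage clustering of `1 − TOM` (minimum module size
   30, eigengene merge height 0.25), module eigengenes (first principal
   component), module–stage Pearson correlation, and hub genes with
   module membership kME ≥ 0.80.
3. **Overlapping clustering** — DPClusO-style greedy growth of dense
   clusters on the interaction network, constrained by cluster density
   `d_k ≥ d_min` and cluster property `cp_nk = E_nk/(d_k·N_k) ≥ 0.5`,
   swept over `d_min ∈ {0.5, …, 0.9}`.
4. **Prioritisation** — one-sided hypergeometric (Fisher) enrichment
   of regulatory labels per cluster; per-gene
   `SScore = −log10(min p over containing clusters)`; ROC of the SScore
   against the labels per density; the density with maximal AUC wins;
   regulatory genes inside significant clusters (p < 0.05) are the
   candidates.
5. **Pathway enrichment** — hypergeometric tests of the candidates
   against GMT gene-set collections with Bonferroni correction.

A synthetic-data module generates count matrices with planted,
stage-associated co-expression modules (negative-binomial counts over a
latent-factor model) and interaction networks with planted regulatory
clusters, so every stage is testable without external data.

## Worked example

```python
import coexreg as cr
import networkx as nx

# synthetic study: 4 stage-associated modules of 50 genes, 12 samples,
# and a 338-node network with 10 planted clusters holding 30 regulatory genes
cfg = cr.SyntheticConfig(seed=1)
counts, truth = cr.generate_count_matrix(cfg)
edges, labels, net_truth = cr.generate_interaction_network(
    cr.SyntheticNetworkConfig(seed=1))

graph = nx.Graph()
graph.add_nodes_from(f"n{i:04d}" for i in range(1, 339))
graph.add_edges_from(edges)

filtered, _ = cr.filter_low_counts(counts)
expr = cr.vst_transform(filtered, cr.estimate_size_factors(filtered))
tom = cr.tom_similarity(cr.signed_adjacency(expr, power=12))
modules = cr.refine_modules(expr, cr.detect_modules(1 - tom, 30))
print(modules.sizes())
# {'blue': 56, 'turquoise': 55, 'brown': 51, 'yellow': 51, 'grey': 37}

from coexreg.dpcluso import density_sweep
from coexreg.prioritize import enrich_cluster_set
bg, reg = set(graph.nodes), set(labels)
aucs = {}
for d, cs in density_sweep(graph).items():
    enr = enrich_cluster_set(cs, reg, bg)
    scores = cr.sscore_table(cs, enr, bg)
    aucs[d] = cr.roc_curve(scores, reg).auc
print({d: round(a, 3) for d, a in sorted(aucs.items())})
# {0.5: 0.911, 0.6: 0.916, 0.7: 0.924, 0.8: 0.924, 0.9: 0.924}
print(cr.select_best_density(aucs))
# 0.7
```

The module sizes show the four planted modules recovered almost
exactly (the grey entry collects unassigned noise genes); the AUC map
says how well each density's cluster set concentrates regulatory genes,
and the selected density is the one whose clusters best separate
regulatory from non-regulatory genes.

The same pipeline runs from the shell:

```sh
coexreg simulate --seed 1 --outdir sim/
coexreg run --config pipeline.yaml --outdir out/
```

`out/manifest.json` records the config, per-stage counts, output
checksums, the AUC table and the ranked candidate list.

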