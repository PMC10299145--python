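"""Synthetic transcriptome and interaction-network generators.

Counts follow a latent-factor model: each planted module shares a latent
per-sample factor (the module's eigengene in the downstream analysis),
shifted upward in the samples of the module's associated developmental
stage. Gene-level log-means are loading * latent + baseline, counts are
drawn negative-binomially around ``library_size * exp(log_mean)``.

The interaction network is a planted-partition graph: dense clusters on
a sparse background, with a configurable number of regulatory labels
planted inside each cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


NOISE_MODULE = "none"


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic count-matrix generator.

    Defaults plant 4 modules of 50 genes across 12 samples (3 per
    developmental stage), each module associated with one stage, with a
    within-module Pearson correlation of 0.9 on the log scale.
    """

    n_genes: int = 250
    n_samples: int = 12
    stages: Dict[str, int] = field(
        default_factory=lambda: {"egg": 3, "larva3": 3, "pupa": 3, "adult": 3}
    )
    n_modules: int = 4
    module_sizes: List[int] = field(default_factory=lambda: [50, 50, 50, 50])
    within_module_correlation: float = 0.9
    stage_association: Dict[str, str] = field(
        default_factory=lambda: {
            "module_1": "egg",
            "module_2": "larva3",
            "module_3": "pupa",
            "module_4": "adult",
        }
    )
    # Mean shift of the latent factor in associated-stage samples, in
    # latent standard deviations.
    stage_effect_size: float = 2.0
    dispersion: float = 10.0
    library_size_range: Tuple[float, float] = (0.7, 1.3)
    noise_gene_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be positive")
        if not self.stages:
            raise ConfigurationError("stages must be non-empty")
        if any(c <= 0 for c in self.stages.values()):
            raise ConfigurationError("per-stage sample counts must be positive")
        if sum(self.stages.values()) != self.n_samples:
            raise ConfigurationError(
                f"per-stage sample counts sum to {sum(self.stages.values())}, "
                f"expected n_samples={self.n_samples}"
            )
        if len(self.module_sizes) != self.n_modules:
            raise ConfigurationError(
                f"module_sizes has {len(self.module_sizes)} entries, "
                f"expected n_modules={self.n_modules}"
            )
        if any(s <= 0 for s in self.module_sizes):
            raise ConfigurationError("module_sizes must be positive")
        n_noise = self.n_genes - sum(self.module_sizes)
        if n_noise < 0:
            raise ConfigurationError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        expected_noise = round(self.noise_gene_fraction * self.n_genes)
        if n_noise != expected_noise:
            raise ConfigurationError(
                f"noise_gene_fraction={self.noise_gene_fraction} implies "
                f"{expected_noise} noise genes but module_sizes leave {n_noise}"
            )
        if not 0.0 < self.within_module_correlation < 1.0:
            raise ConfigurationError("within_module_correlation must lie in (0, 1)")
        for module, stage in self.stage_association.items():
            if stage not in self.stages:
                raise ConfigurationError(
                    f"stage_association maps {module!r} to unknown stage {stage!r}"
                )
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library_size_range must be positive and ordered")


@dataclass
class SyntheticNetworkConfig:
    """Parameters of the planted-cluster interaction network generator.

    Defaults mirror a 338-node network carrying 30 regulatory genes,
    organised as 10 dense planted clusters of 8 nodes with 3 regulatory
    genes each — the margins of the smallest cluster the enrichment
    test can call significant on this background (8 nodes, 3 of 30
    regulatory: one-sided hypergeometric p = 0.026).
    """

    n_nodes: int = 338
    n_regulatory: int = 30
    n_planted_clusters: int = 10
    planted_cluster_size: int = 8
    planted_regulatory_per_cluster: int = 3
    intra_cluster_edge_prob: float = 1.0
    background_edge_prob: float = 0.01
    node_names: Optional[Sequence[str]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes <= 0:
            raise ConfigurationError("n_nodes must be positive")
        if self.n_regulatory > self.n_nodes:
            raise ConfigurationError(
                f"n_regulatory={self.n_regulatory} exceeds n_nodes={self.n_nodes}"
            )
        if self.planted_regulatory_per_cluster > self.planted_cluster_size:
            raise ConfigurationError(
                "planted_regulatory_per_cluster exceeds planted_cluster_size"
            )
        planted_reg = self.n_planted_clusters * self.planted_regulatory_per_cluster
        if planted_reg > self.n_regulatory:
            raise ConfigurationError(
                f"{self.n_planted_clusters} clusters x "
                f"{self.planted_regulatory_per_cluster} regulatory genes = "
                f"{planted_reg} > n_regulatory={self.n_regulatory}"
            )
        if self.n_planted_clusters * self.planted_cluster_size > self.n_nodes:
            raise ConfigurationError("planted clusters do not fit into n_nodes")
        if not 0.0 < self.intra_cluster_edge_prob <= 1.0:
            raise ConfigurationError("intra_cluster_edge_prob must lie in (0, 1]")
        if not 0.0 <= self.background_edge_prob < 1.0:
            raise ConfigurationError("background_edge_prob must lie in [0, 1)")
        if self.node_names is not None and len(self.node_names) != self.n_nodes:
            raise ConfigurationError(
                f"node_names has {len(self.node_names)} entries, expected {self.n_nodes}"
            )


@dataclass
class TruthRecord:
    """Ground truth emitted alongside synthetic data."""

    gene_module: Dict[str, str] = field(default_factory=dict)
    regulatory: Dict[str, bool] = field(default_factory=dict)
    module_stage: Dict[str, str] = field(default_factory=dict)
    planted_clusters: List[List[str]] = field(default_factory=list)
    latent_factors: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        return {
            "gene_module": self.gene_module,
            "regulatory": self.regulatory,
            "module_stage": self.module_stage,
            "planted_clusters": self.planted_clusters,
        }


def _gene_names(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_stage_design(config: SyntheticConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Build the sample→stage design table and its one-vs-rest indicator.

    Returns ``(design, indicator)``: *design* has one row per sample with
    a categorical ``stage`` column; *indicator* is a binary sample-by-stage
    matrix with one column per stage.
    """
    config.validate()
    samples, stage_labels = [], []
    i = 0
    for stage, count in config.stages.items():
        for _ in range(count):
            i += 1
            samples.append(f"s{i:02d}")
            stage_labels.append(stage)
    design = pd.DataFrame(
        {"sample": samples, "stage": pd.Categorical(stage_labels, categories=list(config.stages))}
    )
    indicator = pd.DataFrame(
        {stage: (design["stage"] == stage).astype(int).to_numpy() for stage in config.stages},
        index=samples,
    )
    return design, indicator


def generate_count_matrix(config: SyntheticConfig) -> Tuple[pd.DataFrame, TruthRecord]:
    """Draw a gene-by-sample negative-binomial count matrix with planted modules.

    Within each module, gene log-means share the module latent factor so
    that the expected pairwise Pearson correlation on the log scale is
    ``within_module_correlation``; the factor is shifted by
    ``stage_effect_size`` latent SDs in the associated stage's samples.
    Identical seed and config give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design, _ = generate_stage_design(config)
    samples = design["sample"].tolist()
    genes = _gene_names(config.n_genes)

    rho = config.within_module_correlation
    n_noise = config.n_genes - sum(config.module_sizes)
    module_names = [f"module_{m + 1}" for m in range(config.n_modules)]

    gene_module: Dict[str, str] = {}
    log_signal = np.zeros((config.n_genes, config.n_samples))
    latent = {}
    pos = 0
    for name, size in zip(module_names, config.module_sizes):
        z = rng.standard_normal(config.n_samples)
        stage = config.stage_association.get(name)
        if stage is not None:
            z = z + config.stage_effect_size * (design["stage"] == stage).to_numpy()
        latent[name] = z
        # sqrt(rho) loading + sqrt(1-rho) idiosyncratic noise gives
        # pairwise log-scale correlation rho before count noise.
        block = math.sqrt(rho) * z + math.sqrt(1.0 - rho) * rng.standard_normal(
            (size, config.n_samples)
        )
        log_signal[pos : pos + size] = block
        for g in genes[pos : pos + size]:
            gene_module[g] = name
        pos += size
    if n_noise:
        log_signal[pos:] = rng.standard_normal((n_noise, config.n_samples))
        for g in genes[pos:]:
            gene_module[g] = NOISE_MODULE

    baseline = rng.normal(loc=3.0, scale=0.5, size=config.n_genes)
    lo, hi = config.library_size_range
    library = rng.uniform(lo, hi, size=config.n_samples)
    mu = library[None, :] * np.exp(log_signal + baseline[:, None])

    # NB parameterised by size r = dispersion: var = mu + mu^2 / r.
    r = config.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = pd.DataFrame(counts, index=genes, columns=samples)

    truth = TruthRecord(
        gene_module=gene_module,
        module_stage=dict(config.stage_association),
        latent_factors=pd.DataFrame(latent, index=samples).T,
    )
    return matrix, truth


def generate_interaction_network(
    config: SyntheticNetworkConfig,
) -> Tuple[List[Tuple[str, str]], List[str], TruthRecord]:
    """Draw a planted-cluster interaction network with regulatory labels.

    Returns ``(edges, regulatory_labels, truth)`` where *edges* is a
    sorted list of undirected node-name pairs (no self-loops, no
    duplicates) and *regulatory_labels* has exactly ``n_regulatory``
    entries, ``planted_regulatory_per_cluster`` of them inside each
    planted cluster.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.node_names is not None:
        nodes = list(config.node_names)
    else:
        width = max(4, len(str(config.n_nodes)))
        nodes = [f"n{i:0{width}d}" for i in range(1, config.n_nodes + 1)]

    clusters: List[List[str]] = []
    pos = 0
    for _ in range(config.n_planted_clusters):
        clusters.append(nodes[pos : pos + config.planted_cluster_size])
        pos += config.planted_cluster_size

    # plant an exact edge count per cluster so realised density is
    # intra_cluster_edge_prob up to rounding, not a binomial draw
    edge_set = set()
    for members in clusters:
        pairs = [
            tuple(sorted((members[i], members[j])))
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        n_keep = int(round(config.intra_cluster_edge_prob * len(pairs)))
        chosen = rng.choice(len(pairs), size=n_keep, replace=False)
        edge_set.update(pairs[i] for i in chosen)
    if config.background_edge_prob > 0:
        planted_pairs = edge_set.copy()
        n = config.n_nodes
        draws = rng.random(n * (n - 1) // 2)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                if draws[k] < config.background_edge_prob:
                    pair = tuple(sorted((nodes[i], nodes[j])))
                    if pair not in planted_pairs:
                        edge_set.add(pair)
                k += 1

    regulatory: List[str] = []
    for members in clusters:
        regulatory.extend(members[: config.planted_regulatory_per_cluster])
    n_extra = config.n_regulatory - len(regulatory)
    if n_extra > 0:
        unplanted = nodes[config.n_planted_clusters * config.planted_cluster_size :]
        pool = [u for u in unplanted if u not in regulatory]
        if len(pool) < n_extra:
            raise ConfigurationError(
                "not enough non-cluster nodes to place remaining regulatory labels"
            )
        regulatory.extend(sorted(rng.choice(pool, size=n_extra, replace=False)))

    truth = TruthRecord(
        regulatory={node: (node in set(regulatory)) for node in nodes},
        planted_clusters=[list(c) for c in clusters],
    )
    return sorted(edge_set), regulatory, truth
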