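"""End-to-end orchestration: counts → modules → clusters → candidates.

:func:`analyze` runs the full analysis on in-memory inputs and returns
every intermediate product; :func:`run_pipeline` wraps it with file
I/O, artifact writing and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from coexreg import io as creg_io
from coexreg import prioritize as pri
from coexreg.dpcluso import density_sweep
from coexreg.genesets import enrich, read_gmt
from coexreg.preprocess import (
    estimate_size_factors,
    filter_low_counts,
    select_high_variance,
    vst_transform,
)
from coexreg.wgcna import (
    detect_modules,
    merge_close_modules,
    module_eigengenes,
    module_membership,
    module_trait_correlation,
    pick_soft_threshold,
    refine_modules,
    select_hub_genes,
    select_key_modules,
    signed_adjacency,
    tom_similarity,
)

logger = logging.getLogger("coexreg")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All stage parameters with the pipeline defaults, plus input paths."""

    counts: Optional[str] = None
    design: Optional[str] = None
    edges: Optional[str] = None
    labels: Optional[str] = None
    gene_sets: Optional[str] = None
    outdir: str = "coexreg_out"

    min_total_count: int = 10
    variance_quantile: float = 0.95
    pseudocount: float = 1.0
    r2_target: float = 0.80
    power_override: Optional[int] = 12
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    cut_quantile: Optional[float] = None
    min_kme_coherence: float = 0.5
    kme_threshold: float = 0.80
    key_stage: Optional[str] = None
    density_sweep: List[float] = field(default_factory=lambda: [0.5, 0.6, 0.7, 0.8, 0.9])
    cp_min: float = 0.5
    min_cluster_size: int = 2
    alpha: float = 0.05
    restrict_to_hubs: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class AnalysisResult:
    expr: pd.DataFrame
    n_genes_filtered: int
    n_genes_selected: int
    chosen_power: int
    assignment: object
    eigengenes: pd.DataFrame
    trait_r: Optional[pd.DataFrame]
    trait_p: Optional[pd.DataFrame]
    key_modules: Optional[List[str]]
    kme: pd.DataFrame
    hubs: Dict[str, List[str]]
    clustered_graph: nx.Graph
    cluster_sets: Dict[float, object]
    enrichments: Dict[float, list]
    auc_by_density: Dict[float, float]
    best_density: float
    significant: list
    candidates: list
    scores: Dict[str, float]


def analyze(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    graph: nx.Graph,
    labels: Set[str],
    config: Optional[PipelineConfig] = None,
) -> AnalysisResult:
    """Run preprocess → network → modules → clustering → prioritisation."""
    cfg = config or PipelineConfig()

    filtered, n_removed = filter_low_counts(counts, cfg.min_total_count)
    logger.info("filter: kept %d genes, removed %d", len(filtered), n_removed)
    factors = estimate_size_factors(filtered)
    expr = vst_transform(filtered, factors, cfg.pseudocount)
    expr = select_high_variance(expr, cfg.variance_quantile)
    logger.info("selected %d high-variance genes", len(expr))

    if cfg.power_override is not None:
        power = cfg.power_override
    else:
        power = pick_soft_threshold(expr, r2_target=cfg.r2_target).chosen_power
    adj = signed_adjacency(expr, power)
    tom = tom_similarity(adj)
    diss = 1.0 - tom
    assignment = detect_modules(diss, cfg.min_module_size, cfg.cut_quantile)
    assignment = refine_modules(expr, assignment, cfg.min_kme_coherence)
    if assignment.modules:
        assignment = merge_close_modules(expr, assignment, cfg.merge_cut_height)
    logger.info("modules: %s", assignment.sizes())

    me = module_eigengenes(expr, assignment)
    trait_r = trait_p = key_modules = None
    indicator = pd.get_dummies(design.set_index("sample")["stage"]).astype(int)
    indicator = indicator.loc[expr.columns]
    if len(me) and len(indicator.columns):
        trait_r, trait_p = module_trait_correlation(me, indicator)
        if cfg.key_stage is not None:
            key_modules = select_key_modules(trait_r, trait_p, cfg.key_stage, cfg.alpha)
    kme = module_membership(expr, me) if len(me) else pd.DataFrame(index=expr.index)
    hubs = select_hub_genes(kme, assignment, cfg.kme_threshold)

    clustered = graph
    if cfg.restrict_to_hubs:
        hub_union = set().union(*hubs.values()) if hubs else set()
        shared = hub_union & set(graph.nodes)
        if shared:
            clustered = graph.subgraph(shared).copy()
            logger.info("restricted network to %d hub nodes", len(shared))
        else:
            warnings.warn(
                "supplied network shares no node IDs with the hub genes; "
                "clustering the full network",
                stacklevel=2,
            )

    background = set(clustered.nodes)
    reg = labels & background
    if not reg or reg == background:
        raise PipelineError(
            "regulatory labels must cover some but not all network nodes"
        )
    sets = density_sweep(clustered, cfg.density_sweep, cfg.cp_min, cfg.min_cluster_size)
    enrichments, aucs, scores_by_d = {}, {}, {}
    for d, cset in sets.items():
        enr = pri.enrich_cluster_set(cset, reg, background)
        enrichments[d] = enr
        scores = pri.sscore_table(cset, enr, background)
        scores_by_d[d] = scores
        aucs[d] = pri.roc_curve(scores, reg).auc
        logger.info("density %.1f: %d clusters, AUC %.3f", d, len(cset), aucs[d])
    best = pri.select_best_density(aucs)
    sig = pri.significant_clusters(enrichments[best], cfg.alpha)
    candidates = pri.candidate_regulatory_genes(sets[best], sig, reg, scores_by_d[best])
    logger.info(
        "best density %.1f: %d significant clusters, %d candidates",
        best, len(sig), len(candidates),
    )
    return AnalysisResult(
        expr=expr,
        n_genes_filtered=len(filtered),
        n_genes_selected=len(expr),
        chosen_power=power,
        assignment=assignment,
        eigengenes=me,
        trait_r=trait_r,
        trait_p=trait_p,
        key_modules=key_modules,
        kme=kme,
        hubs=hubs,
        clustered_graph=clustered,
        cluster_sets=sets,
        enrichments=enrichments,
        auc_by_density=aucs,
        best_density=best,
        significant=sig,
        candidates=candidates,
        scores=scores_by_d[best],
    )


@dataclass
class RunManifest:
    config: dict
    version: str
    checksums: Dict[str, str]
    stage_counts: Dict[str, object]
    auc_by_density: Dict[str, float]
    best_density: float
    candidates: List[Tuple[str, float, str]]

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """File-based pipeline run: read inputs, analyse, write artifacts."""
    from coexreg import __version__

    for name in ("counts", "design", "edges", "labels"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise PipelineError(f"required input {name!r} missing: {path}")

    counts = creg_io.read_counts(config.counts)
    design = creg_io.read_design(config.design)
    graph = creg_io.read_edges(config.edges)
    labels = creg_io.read_labels(config.labels)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        result = analyze(counts, design, graph, labels, config)
    except Exception:
        (outdir / "FAILED").write_text("analysis stage failed\n")
        raise

    result.expr.to_csv(outdir / "expression_selected.tsv", sep="\t")
    pd.DataFrame(
        {"gene": result.assignment.labels.index, "module": result.assignment.labels.values}
    ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
    result.eigengenes.to_csv(outdir / "eigengenes.tsv", sep="\t")
    if result.trait_r is not None:
        result.trait_r.to_csv(outdir / "module_trait_r.tsv", sep="\t")
        result.trait_p.to_csv(outdir / "module_trait_p.tsv", sep="\t")
    result.kme.to_csv(outdir / "kme.tsv", sep="\t")
    with open(outdir / "clusters.tsv", "w") as fh:
        for d, cset in result.cluster_sets.items():
            for cluster in cset:
                members = "\t".join(cluster.nodes)
                fh.write(f"{d}\t{cluster.cluster_id}\t{cluster.density:.4f}\t{members}\n")
    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("density\tcluster\ta\tb\tc\td\tp_value\n")
        for d, enr in result.enrichments.items():
            for e in enr:
                t = e.table
                fh.write(
                    f"{d}\t{e.cluster_id}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t{e.p_value:.6g}\n"
                )
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("gene\tsscore\tbest_cluster\n")
        for gene, score, cid in result.candidates:
            fh.write(f"{gene}\t{score:.4f}\t{cid}\n")

    if config.gene_sets:
        collection = read_gmt(config.gene_sets)
        universe = set(result.clustered_graph.nodes)
        rows = enrich([g for g, _, _ in result.candidates], collection, universe)
        with open(outdir / "pathway_enrichment.tsv", "w") as fh:
            fh.write(
                "set\toverlap\tset_size\tquery_size\tuniverse\tp\tp_adj\tfactor\n"
            )
            for r in rows:
                fh.write(
                    f"{r.set_name}\t{r.overlap}\t{r.set_size}\t{r.query_size}\t"
                    f"{r.universe_size}\t{r.p_value:.6g}\t{r.p_adjusted:.6g}\t"
                    f"{r.enrichment_factor:.3f}\n"
                )

    checksums = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
    }
    manifest = RunManifest(
        config=asdict(config),
        version=__version__,
        checksums=checksums,
        stage_counts={
            "genes_after_filter": result.n_genes_filtered,
            "genes_selected": result.n_genes_selected,
            "modules": result.assignment.sizes(),
            "clusters_per_density": {
                str(d): len(cset) for d, cset in result.cluster_sets.items()
            },
            "significant_clusters": len(result.significant),
            "candidates": len(result.candidates),
        },
        auc_by_density={str(d): auc for d, auc in result.auc_by_density.items()},
        best_density=result.best_density,
        candidates=list(result.candidates),
    )
    creg_io.write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest
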