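"""Cluster enrichment, gene SScores, ROC/AUC density selection.

Each cluster is tested for over-representation of known regulatory
genes with a one-sided hypergeometric upper tail (Fisher's exact test
on the 2x2 in-cluster/regulatory contingency table). A gene's SScore is
``-log10`` of the smallest p-value among clusters containing it; the
quality of each density's cluster set is the AUC of the ROC curve of
the SScore as a classifier of the known regulatory labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy.stats import hypergeom

from coexreg.dpcluso import ClusterSet


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: cluster membership vs regulatory label."""

    a: int  # regulatory, in cluster
    b: int  # non-regulatory, in cluster
    c: int  # regulatory, not in cluster
    d: int  # non-regulatory, not in cluster

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def cluster_size(self) -> int:
        return self.a + self.b

    @property
    def n_regulatory(self) -> int:
        return self.a + self.c

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ClusterEnrichment:
    cluster_id: str
    table: ContingencyTable
    p_value: float


def hypergeom_upper_tail(a: int, background: int, n_regulatory: int, cluster_size: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=background, K=n_regulatory, n=cluster_size)."""
    if background <= 0:
        raise ValueError("background must be non-empty")
    return float(hypergeom.sf(a - 1, background, n_regulatory, cluster_size))


def cluster_enrichment(
    cluster_nodes: Iterable[str],
    labels: Set[str],
    background: Set[str],
    cluster_id: str = "",
) -> ClusterEnrichment:
    """One-sided regulatory-gene enrichment of one cluster."""
    if not background:
        raise ValueError("background gene set is empty")
    members = set(cluster_nodes)
    if not members <= background:
        raise ValueError("cluster contains genes outside the background")
    reg = labels & background
    a = len(members & reg)
    b = len(members) - a
    c = len(reg) - a
    d = len(background) - a - b - c
    table = ContingencyTable(a, b, c, d)
    p = hypergeom_upper_tail(a, table.background_size, table.n_regulatory, table.cluster_size)
    return ClusterEnrichment(cluster_id, table, p)


def enrich_cluster_set(
    clusters: ClusterSet, labels: Set[str], background: Set[str]
) -> List[ClusterEnrichment]:
    return [
        cluster_enrichment(c.nodes, labels, background, cluster_id=c.cluster_id)
        for c in clusters
    ]


def sscore_table(
    clusters: ClusterSet,
    enrichments: Sequence[ClusterEnrichment],
    background: Iterable[str],
) -> Dict[str, float]:
    """SScore per gene: -log10 of the smallest p over containing clusters.

    Genes covered by no cluster score 0 (equivalently p = 1).
    """
    p_by_id = {e.cluster_id: e.p_value for e in enrichments}
    best_p: Dict[str, float] = {}
    for cluster in clusters:
        p = p_by_id[cluster.cluster_id]
        for node in cluster.nodes:
            if p < best_p.get(node, np.inf):
                best_p[node] = p
    scores = {}
    for gene in background:
        p = best_p.get(gene)
        scores[gene] = 0.0 if p is None else float(-np.log10(p))
    return scores


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_curve(scores: Mapping[str, float], labels: Set[str]) -> ROCResult:
    """ROC of the SScore as a classifier of the regulatory labels.

    Thresholds sweep the unique scores in descending order after a
    sentinel above the maximum; a gene is called positive at threshold
    th when its SScore >= th. The AUC is the trapezoidal area under the
    (FPR, TPR) curve.
    """
    genes = sorted(scores)
    y = np.array([g in labels for g in genes], dtype=bool)
    s = np.array([scores[g] for g in genes], dtype=float)
    n_pos = int(y.sum())
    n_neg = len(genes) - n_pos
    if n_pos == 0:
        raise ValueError("no positive (regulatory) genes among the scores")
    if n_neg == 0:
        raise ValueError("no negative (non-regulatory) genes among the scores")
    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate(([uniq[0] + 1.0], uniq))
    tp = np.array([(y & (s >= th)).sum() for th in thresholds])
    fp = np.array([(~y & (s >= th)).sum() for th in thresholds])
    fn = n_pos - tp
    tn = n_neg - fp
    tpr = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds, tp, fp, tn, fn, tpr, fpr, auc)


def select_best_density(auc_by_density: Mapping[float, float]) -> float:
    """Density with maximal AUC; ties resolved to the smallest density."""
    if not auc_by_density:
        raise ValueError("empty AUC map")
    best = max(sorted(auc_by_density), key=lambda d: (auc_by_density[d], -d))
    return best


def significant_clusters(
    enrichments: Sequence[ClusterEnrichment], alpha: float = 0.05
) -> List[ClusterEnrichment]:
    """Clusters with p strictly below alpha, most significant first."""
    hits = [e for e in enrichments if e.p_value < alpha]
    hits.sort(key=lambda e: (e.p_value, e.cluster_id))
    return hits


def candidate_regulatory_genes(
    clusters: ClusterSet,
    sig_clusters: Sequence[ClusterEnrichment],
    labels: Set[str],
    scores: Mapping[str, float],
) -> List[Tuple[str, float, str]]:
    """Known regulatory genes inside significant clusters, best score first.

    Returns ``(gene, sscore, best_cluster_id)`` tuples ranked by SScore
    descending then gene id; the best cluster is the containing
    significant cluster of smallest p.
    """
    sig_ids = {e.cluster_id: e.p_value for e in sig_clusters}
    best: Dict[str, Tuple[float, str]] = {}
    for cluster in clusters:
        p = sig_ids.get(cluster.cluster_id)
        if p is None:
            continue
        for node in cluster.nodes:
            if node in labels:
                current = best.get(node)
                if current is None or (p, cluster.cluster_id) < current:
                    best[node] = (p, cluster.cluster_id)
    out = [(g, float(scores.get(g, 0.0)), cid) for g, (_, cid) in best.items()]
    out.sort(key=lambda row: (-row[1], row[0]))
    return out
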