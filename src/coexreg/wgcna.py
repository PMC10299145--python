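"""Signed weighted co-expression network, modules, eigengenes, hubs.

The network is a signed weighted one: adjacency between two genes is
``((1 + cor) / 2) ** beta``, so anti-correlated genes get near-zero
weight. The topological overlap measure (TOM) quantifies shared
neighbourhoods and ``1 - TOM`` is the clustering dissimilarity. Modules
are branches of an average-linkage dendrogram cut at a quantile of the
merge heights; each module is summarised by its eigengene (first
principal component of standardised member expression), and hub genes
are members whose expression correlates at least ``kme_threshold`` with
their module eigengene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

GREY = "grey"

# Conventional colour aliases by module size rank (largest first).
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


def _safe_corrcoef(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with zero-variance rows mapped to 0."""
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s); their correlations set to 0",
            stacklevel=3,
        )
    xs = x.copy()
    xs[degenerate] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(xs)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def signed_adjacency(expr: pd.DataFrame, power: int = 12) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor_ij) / 2) ** power, diagonal 1."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    if power < 1:
        raise ValueError("power must be >= 1")
    cor = _safe_corrcoef(expr.to_numpy(dtype=float))
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=expr.index, columns=expr.index)


@dataclass
class SoftThresholdResult:
    powers: List[int]
    r_squared: List[float]
    mean_connectivity: List[float]
    chosen_power: int
    target_met: bool

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "r_squared": self.r_squared,
                "mean_connectivity": self.mean_connectivity,
            }
        )


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Scale-free topology fit index.

    Connectivities are histogrammed into ``n_bins`` equal-width bins;
    the index is the R^2 of the regression of log10(bin frequency) on
    log10(mean connectivity per bin), over non-empty bins.
    """
    k = connectivity[connectivity > 0]
    if k.size == 0:
        raise ValueError("all connectivities are zero")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    edges[-1] += 1e-12
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    log_k, log_freq = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_freq.append(np.log10(members.size / k.size))
    if len(log_k) < 2:
        return 0.0
    r = np.corrcoef(log_k, log_freq)[0, 1]
    if np.isnan(r):
        return 0.0
    return float(r * r)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    r2_target: float = 0.80,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Choose the smallest power whose scale-free fit R^2 meets the target.

    Falls back, with a warning, to the power of maximal R^2 when no
    candidate reaches the target.
    """
    if not powers:
        raise ValueError("powers must be non-empty")
    cor = _safe_corrcoef(expr.to_numpy(dtype=float))
    base = (1.0 + cor) / 2.0
    r2s, mean_ks = [], []
    for p in powers:
        adj = base ** p
        np.fill_diagonal(adj, 1.0)
        k = adj.sum(axis=1) - 1.0
        r2s.append(scale_free_fit(k, n_bins=n_bins))
        mean_ks.append(float(k.mean()))
    chosen, met = None, False
    for p, r2 in zip(powers, r2s):
        if r2 >= r2_target:
            chosen, met = p, True
            break
    if chosen is None:
        chosen = powers[int(np.argmax(r2s))]
        warnings.warn(
            f"no candidate power reached R^2 >= {r2_target}; "
            f"using power {chosen} (R^2 = {max(r2s):.3f})",
            stacklevel=2,
        )
    return SoftThresholdResult(list(powers), r2s, mean_ks, int(chosen), met)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    ``l_ij = sum_{u != i,j} a_iu a_uj`` counts shared weighted
    neighbours; the diagonal is set to 1.
    """
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    # (A @ A)_ij includes u = i and u = j: a_ii a_ij + a_ij a_jj = 2 a_ij
    # for a unit diagonal.
    l = a @ a - 2.0 * a
    k = a.sum(axis=1) - 1.0
    min_k = np.minimum.outer(k, k)
    denom = min_k + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleAssignment:
    """Gene→module labels; ``grey`` collects unassigned genes."""

    labels: pd.Series
    min_module_size: int = 30

    @property
    def modules(self) -> List[str]:
        return [m for m in self.labels.unique() if m != GREY]

    def sizes(self) -> Dict[str, int]:
        counts = self.labels.value_counts()
        return {m: int(counts[m]) for m in counts.index}

    def members(self, module: str) -> List[str]:
        return self.labels.index[self.labels == module].tolist()


def _label_by_size(cluster_ids: pd.Series, min_module_size: int) -> pd.Series:
    """Map raw cluster ids to colour labels by size rank; small → grey."""
    sizes = cluster_ids.value_counts()
    ranked = sorted(
        (cid for cid in sizes.index if sizes[cid] >= min_module_size),
        key=lambda cid: (-sizes[cid], cid),
    )
    mapping = {}
    for rank, cid in enumerate(ranked):
        if rank < len(MODULE_COLORS):
            mapping[cid] = MODULE_COLORS[rank]
        else:
            mapping[cid] = f"module_{rank + 1}"
    return cluster_ids.map(lambda cid: mapping.get(cid, GREY))


def detect_modules(
    diss_tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_quantile: Optional[float] = None,
) -> ModuleAssignment:
    """Average-linkage clustering of the TOM dissimilarity, static cut.

    With ``cut_quantile`` given, the dendrogram is cut at that quantile
    of its merge heights. By default the cut height is chosen by
    scanning merge-height quantiles from 0.50 to 0.99 and keeping the
    cut that yields the most branches of at least ``min_module_size``
    genes (ties: fewest unassigned genes, then the higher cut), which
    adapts the cut to the tree instead of fixing it a priori. Branches
    smaller than ``min_module_size`` fall into the grey (unassigned)
    module; the rest are labelled by size rank using the conventional
    colour order (largest = turquoise).
    """
    genes = diss_tom.index
    if len(genes) < min_module_size:
        warnings.warn(
            f"{len(genes)} genes < min_module_size={min_module_size}; all grey",
            stacklevel=2,
        )
        return ModuleAssignment(pd.Series(GREY, index=genes), min_module_size)
    d = diss_tom.to_numpy(dtype=float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    if cut_quantile is not None:
        quantiles = [cut_quantile]
    else:
        quantiles = [round(q, 2) for q in np.arange(0.50, 0.995, 0.01)]
    best_key, best_labels = None, None
    for q in quantiles:
        cut = float(np.quantile(heights, q))
        raw = fcluster(z, t=cut, criterion="distance")
        labels = _label_by_size(pd.Series(raw, index=genes), min_module_size)
        n_modules = labels.nunique() - int((labels == GREY).any())
        n_grey = int((labels == GREY).sum())
        key = (n_modules, -n_grey, q)
        if best_key is None or key > best_key:
            best_key, best_labels = key, labels
    return ModuleAssignment(best_labels, min_module_size)


def refine_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    min_kme: float = 0.5,
) -> ModuleAssignment:
    """Drop incoherent members: genes whose kME to their own module is
    below ``min_kme`` move to grey, and modules falling below the size
    floor dissolve entirely.

    Average-linkage branches absorb weakly connected genes below the
    cut; this filter removes them using the module's own eigengene as
    the coherence reference. No filtering is applied when the size
    floor is 1, since every branch is then a valid module by contract.
    """
    if assignment.min_module_size <= 1 or not assignment.modules:
        return assignment
    me = module_eigengenes(expr, assignment)
    kme = module_membership(expr, me)
    labels = assignment.labels.copy()
    for gene in labels.index:
        module = labels[gene]
        if module != GREY and kme.loc[gene, module] < min_kme:
            labels[gene] = GREY
    sizes = labels.value_counts()
    for module in sizes.index:
        if module != GREY and sizes[module] < assignment.min_module_size:
            labels[labels == module] = GREY
    return ModuleAssignment(labels, assignment.min_module_size)


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """First principal component per module, unit variance, sign-oriented.

    Gene rows are z-scored before the SVD; each eigengene's sign is
    flipped if needed so it correlates non-negatively with the module's
    mean standardised expression.
    """
    samples = expr.columns
    rows = {}
    for module in assignment.modules:
        members = assignment.members(module)
        sub = expr.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if z.shape[0] == 1:
            me = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            me = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(me, mean_profile) < 0:
            me = -me
        sd_me = me.std(ddof=1)
        if sd_me > 0:
            me = (me - me.mean()) / sd_me
        rows[module] = me
    return pd.DataFrame(rows, index=samples).T


def merge_close_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    merge_cut_height: float = 0.25,
) -> ModuleAssignment:
    """Merge module pairs whose eigengene dissimilarity is below the cut.

    Dissimilarity is ``1 - cor(ME_a, ME_b)``; the closest admissible
    pair merges first and eigengenes are recomputed after every merge.
    """
    labels = assignment.labels.copy()
    while True:
        current = ModuleAssignment(labels, assignment.min_module_size)
        modules = current.modules
        if len(modules) < 2:
            break
        me = module_eigengenes(expr, current)
        cor = np.corrcoef(me.to_numpy())
        best, best_diss = None, merge_cut_height
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                diss = 1.0 - cor[i, j]
                if diss < best_diss:
                    best, best_diss = (modules[i], modules[j]), diss
        if best is None:
            break
        keep, absorb = best
        labels = labels.replace(absorb, keep)
    return ModuleAssignment(labels, assignment.min_module_size)


def module_trait_correlation(
    me: pd.DataFrame, traits: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every (module eigengene, trait) pair.

    p-values come from the t statistic ``r * sqrt((n - 2) / (1 - r^2))``
    on n − 2 degrees of freedom.
    """
    n = me.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples to test a correlation")
    if traits.shape[0] != n:
        raise ValueError("trait matrix sample count does not match eigengenes")
    r = pd.DataFrame(index=me.index, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=me.index, columns=traits.columns, dtype=float)
    for module in me.index:
        x = me.loc[module].to_numpy(dtype=float)
        for trait in traits.columns:
            y = traits[trait].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                rv = 0.0
            else:
                rv = float(np.corrcoef(x, y)[0, 1])
            rv = max(-1.0, min(1.0, rv))
            if abs(rv) >= 1.0:
                pv = 0.0
            else:
                t_stat = rv * np.sqrt((n - 2) / (1.0 - rv * rv))
                pv = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
            r.loc[module, trait] = rv
            p.loc[module, trait] = min(1.0, pv) if pv > 0 else pv
    return r, p


def select_key_modules(
    r: pd.DataFrame, p: pd.DataFrame, stage: str, alpha: float = 0.05
) -> List[str]:
    """Modules positively and significantly correlated with a stage, best first."""
    if stage not in r.columns:
        raise KeyError(f"unknown stage {stage!r}")
    hits = [(m, r.loc[m, stage]) for m in r.index if r.loc[m, stage] > 0 and p.loc[m, stage] < alpha]
    hits.sort(key=lambda pair: -pair[1])
    return [m for m, _ in hits]


def module_membership(expr: pd.DataFrame, me: pd.DataFrame) -> pd.DataFrame:
    """Signed kME: correlation of every gene with every module eigengene."""
    x = expr.to_numpy(dtype=float)
    m = me.to_numpy(dtype=float)
    sd_x = x.std(axis=1)
    degenerate = sd_x == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s); kME set to 0", stacklevel=2
        )
    xc = x - x.mean(axis=1, keepdims=True)
    mc = m - m.mean(axis=1, keepdims=True)
    num = xc @ mc.T
    denom = np.outer(np.linalg.norm(xc, axis=1), np.linalg.norm(mc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = num / denom
    kme = np.nan_to_num(kme, nan=0.0)
    return pd.DataFrame(np.clip(kme, -1, 1), index=expr.index, columns=me.index)


def select_hub_genes(
    kme: pd.DataFrame, assignment: ModuleAssignment, threshold: float = 0.80
) -> Dict[str, List[str]]:
    """Per module, members with kME at or above the threshold (inclusive)."""
    hubs = {}
    for module in assignment.modules:
        if module not in kme.columns:
            continue
        members = assignment.members(module)
        vals = kme.loc[members, module]
        hubs[module] = vals.index[vals >= threshold].tolist()
    return hubs
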