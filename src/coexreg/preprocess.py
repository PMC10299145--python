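"""Count filtering, normalisation, and high-variance gene selection.

Normalisation follows the median-of-ratios convention: per-gene
geometric means across samples define reference expression, each
sample's size factor is the median ratio of its counts to that
reference, and factors are rescaled to geometric mean 1. Counts are then
variance-stabilised by a shifted log2 of the normalised values.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np
import pandas as pd


class PreprocessError(ValueError):
    pass


def filter_low_counts(
    counts: pd.DataFrame, min_total: int = 10
) -> Tuple[pd.DataFrame, int]:
    """Drop genes whose total count across samples is below ``min_total``.

    Returns the filtered matrix (gene order preserved) and the number of
    genes removed. Raises :class:`PreprocessError` if nothing survives.
    """
    if (counts.to_numpy() < 0).any():
        raise PreprocessError("counts must be non-negative")
    keep = counts.sum(axis=1) >= min_total
    filtered = counts.loc[keep]
    n_removed = int((~keep).sum())
    if filtered.empty:
        raise PreprocessError(
            f"all {len(counts)} genes removed at min_total={min_total}; "
            "lower the threshold"
        )
    return filtered, n_removed


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with a zero count in any sample are excluded from the
    reference, as in the standard estimator.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise PreprocessError(
            "no gene has nonzero counts in every sample; "
            "add a pseudocount before estimating size factors"
        )
    ref = x[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geomean[:, None], axis=0))
    factors /= math.exp(np.log(factors).mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst_transform(
    counts: pd.DataFrame, size_factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Shifted-log variance stabilisation of normalised counts.

    value(g, s) = log2(count(g, s) / factor(s) + pseudocount); monotone
    in the counts and finite everywhere for a positive pseudocount.
    """
    if (size_factors <= 0).any():
        raise PreprocessError("size factors must be positive")
    if pseudocount <= 0:
        raise PreprocessError("pseudocount must be positive")
    normalised = counts.div(size_factors.loc[counts.columns], axis=1)
    return np.log2(normalised + pseudocount)


def select_high_variance(
    expr: pd.DataFrame, variance_quantile: float = 0.95
) -> pd.DataFrame:
    """Keep the top ``ceil((1 - q) * G)`` genes by sample variance.

    A top-k count rule, not a quantile threshold, so the output size is
    deterministic under ties; ties broken by gene ID ascending. Sample
    order is preserved.
    """
    if expr.shape[1] < 2:
        raise PreprocessError("variance undefined with fewer than 2 samples")
    if not 0.0 < variance_quantile < 1.0:
        raise PreprocessError("variance_quantile must lie in (0, 1)")
    g = len(expr)
    # round before ceil: (1 - 0.95) * 100 is 5.000000000000004 in floats
    k = math.ceil(round((1.0 - variance_quantile) * g, 9))
    variances = expr.var(axis=1, ddof=1)
    order = (
        pd.DataFrame({"var": variances, "gene": expr.index.astype(str)})
        .sort_values(["var", "gene"], ascending=[False, True])
        .index[:k]
    )
    keep = expr.index.isin(set(order))
    return expr.loc[keep]
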