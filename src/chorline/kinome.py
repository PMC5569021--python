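"""Targeted kinome expression: normalization, tiering, differential analysis.

Counts from a ~487-kinase amplicon panel (genes x samples) are normalized
with the median-of-ratios size-factor estimator, log2-transformed with a
pseudocount of 1, split into high/medium/low expression tiers by
complete-linkage hierarchical clustering under the Chebyshev (maximum
coordinate) distance, and screened for one-vs-rest differential expression
against a single target cell line. No gene-length normalization is applied
(amplicon inserts are of near-constant length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import false_discovery_control, ttest_1samp

TIER_LABELS = ("high", "medium", "low")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq-style estimator).

    For each sample j, the factor is the median over reference genes g of
    count_gj / geometric_mean_g, where the reference excludes any gene
    with a zero count in any sample (its geometric mean would be zero).
    A single-sample matrix gets a unit factor.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer counts, genes as rows, samples as columns.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    nonzero = counts[(counts > 0).all(axis=1)]
    if nonzero.empty:
        raise ValueError("no gene has nonzero counts in every sample")
    log_counts = np.log(nonzero.values.astype(float))
    log_geomean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_log2(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), genes x samples."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        raise ValueError("size factors missing for some samples")
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / factors + 1.0)


@dataclass
class TierAssignment:
    """Gene -> expression tier, labels ordered by descending cluster mean."""

    tiers: pd.Series            # gene -> {high, medium, low}
    cluster_means: dict[str, float]

    def genes(self, tier: str) -> list[str]:
        return sorted(self.tiers.index[self.tiers == tier])


def assign_tiers(expr: pd.DataFrame) -> TierAssignment:
    """Cut a Chebyshev/complete-linkage dendrogram into 3 expression tiers.

    Gene vectors (rows of the log2 expression matrix) are clustered with
    complete linkage under the maximum-coordinate distance and the tree is
    cut into 3 clusters, labeled high/medium/low by descending mean
    expression. Genes are processed in lexicographic order so exact
    merge-height ties resolve deterministically toward the smallest ids.
    """
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 genes to form 3 tiers")
    expr = expr.sort_index()
    dist = pdist(expr.values, metric="chebyshev")
    tree = linkage(dist, method="complete")
    labels = fcluster(tree, t=3, criterion="maxclust")
    if len(np.unique(labels)) != 3:
        raise RuntimeError("tree cut did not yield 3 non-empty clusters")

    cluster_mean = {c: expr.values[labels == c].mean() for c in np.unique(labels)}
    ordered = sorted(cluster_mean, key=cluster_mean.get, reverse=True)
    rename = dict(zip(ordered, TIER_LABELS))
    tiers = pd.Series([rename[c] for c in labels], index=expr.index, name="tier")
    return TierAssignment(tiers, {rename[c]: cluster_mean[c] for c in ordered})


def differential_one_vs_rest(
    expr: pd.DataFrame,
    target_sample: str,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """One-vs-rest differential expression of a single target sample.

    Per gene, log2_fc = expr(target) - mean(others) and the p-value comes
    from a two-sided one-sample t-test of the other samples' values
    against the target's value (df = n_others - 1); with one target
    replicate a two-group test is not possible. A gene is significant when
    p < alpha and |log2_fc| >= log2(fc_threshold). Zero variance among the
    others with a nonzero shift is degenerate: p = 0 by convention.
    p_adj (Benjamini-Hochberg) is reported for transparency but plays no
    part in the significance flag.
    """
    if target_sample not in expr.columns:
        raise KeyError(f"target sample {target_sample!r} not in matrix")
    others = expr.drop(columns=[target_sample])
    if others.shape[1] < 3:
        raise ValueError("need >= 3 non-target samples for a variance estimate")

    target = expr[target_sample].values
    rest = others.values
    log2_fc = target - rest.mean(axis=1)

    pvals = np.empty(len(expr))
    degenerate = rest.std(axis=1) == 0
    for i in range(len(expr)):
        if degenerate[i]:
            pvals[i] = 0.0 if log2_fc[i] != 0 else 1.0
        else:
            pvals[i] = ttest_1samp(rest[i], popmean=target[i]).pvalue

    out = pd.DataFrame({
        "log2_fc": log2_fc,
        "p_value": pvals,
        "p_adj": false_discovery_control(pvals, method="bh"),
        "significant": (pvals < alpha) & (np.abs(log2_fc) >= math.log2(fc_threshold)),
        "degenerate": degenerate & (log2_fc != 0),
    }, index=expr.index)
    return out.sort_values(["p_value", "log2_fc"], ascending=[True, False])


def rank_genes(expr: pd.DataFrame, gene_subset: list[str]) -> pd.DataFrame:
    """Subset of genes sorted by mean expression, high to low (ties by id).

    Used e.g. to order receptor tyrosine kinases on a log2 scale.
    """
    missing = set(gene_subset) - set(expr.index)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)}")
    sub = expr.loc[list(gene_subset)].copy()
    sub["mean_expr"] = sub.mean(axis=1)
    # stable sort on gene id first, then descending mean -> ties stay lexicographic
    return sub.sort_index(kind="mergesort").sort_values(
        "mean_expr", ascending=False, kind="mergesort")
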