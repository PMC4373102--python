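"""Methylation-expression integration.

DMRs are matched to genes by TSS proximity, per-pair correlations are
computed across shared samples, and significance is decided by one global
empirical |r| threshold derived from sample-label permutations at a target
empirical FDR.  A rank-sum test covers two-group expression comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps


def match_dmr_to_genes(
    dmrs: pd.DataFrame, gene_models: pd.DataFrame, max_distance: int = 10_000
) -> pd.DataFrame:
    """Pair each DMR with every gene whose TSS lies within ``max_distance``
    of the DMR interval (distance 0 inside the interval).

    Returns a pair frame (dmr_id, gene_id, distance); attrs carry the
    fraction of DMRs with at least one match.
    """
    pairs = []
    for chrom, genes_c in gene_models.groupby("chrom", sort=False):
        tss = genes_c["tss"].to_numpy()
        order = np.argsort(tss, kind="stable")
        tss_sorted = tss[order]
        ids = genes_c.index.to_numpy()[order]
        sub = dmrs[dmrs["chrom"] == chrom]
        for dmr_id, row in sub.iterrows():
            lo = np.searchsorted(tss_sorted, row["start"] - max_distance, side="left")
            hi = np.searchsorted(tss_sorted, row["end"] + max_distance, side="right")
            for j in range(lo, hi):
                t = tss_sorted[j]
                if t >= row["start"] and t < row["end"]:
                    dist = 0
                elif t < row["start"]:
                    dist = row["start"] - t
                else:
                    dist = t - (row["end"] - 1)
                if dist <= max_distance:
                    pairs.append((dmr_id, ids[j], int(dist)))
    out = pd.DataFrame(pairs, columns=["dmr_id", "gene_id", "distance"])
    matched = out["dmr_id"].nunique() / len(dmrs) if len(dmrs) else 0.0
    out.attrs["matched_fraction"] = float(matched)
    return out


def correlate(
    dmr_means: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation per (DMR, gene) pair across shared samples.

    Pairs with fewer than 5 shared samples are dropped with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    shared = [s for s in dmr_means.columns if s in expression.columns]
    if len(shared) < 5:
        warnings.warn("fewer than 5 shared samples; no pairs correlated",
                      stacklevel=2)
        return pairs.iloc[0:0].assign(r=[])
    m, e = _paired_arrays(dmr_means, expression, pairs, shared, method)
    r = _rowwise_pearson(m, e)
    out = pairs.copy()
    out["r"] = r
    return out


def _paired_arrays(dmr_means, expression, pairs, shared, method):
    m = dmr_means.loc[pairs["dmr_id"], shared].to_numpy(float)
    e = expression.loc[pairs["gene_id"], shared].to_numpy(float)
    if method == "spearman":
        m = sps.rankdata(m, axis=1)
        e = sps.rankdata(e, axis=1)
    return m, e


def _rowwise_pearson(m: np.ndarray, e: np.ndarray) -> np.ndarray:
    zm = m - m.mean(axis=1, keepdims=True)
    ze = e - e.mean(axis=1, keepdims=True)
    denom = np.sqrt((zm**2).sum(axis=1) * (ze**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (zm * ze).sum(axis=1) / denom
    return np.where(denom > 0, r, 0.0)


def empirical_threshold(
    dmr_means: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: pd.DataFrame,
    n_resamples: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
    method: str = "pearson",
) -> dict:
    """Global two-sided |r| significance threshold by expression-label
    permutation.

    The null is built by permuting the expression sample labels
    ``n_resamples`` times and recomputing all pair correlations.  The
    threshold is the smallest observed |r| such that the mean null count
    of |r| exceedances divided by the observed count is at most ``fdr``.
    Returns the threshold, the annotated pair frame, and the fractions
    significant/negative-among-significant.
    """
    if n_resamples < 100:
        warnings.warn("n_resamples < 100: empirical threshold is unstable",
                      stacklevel=2)
    shared = [s for s in dmr_means.columns if s in expression.columns]
    m, e = _paired_arrays(dmr_means, expression, pairs, shared, method)
    r_obs = _rowwise_pearson(m, e)
    abs_obs = np.sort(np.abs(r_obs))[::-1]

    rng = np.random.default_rng(seed)
    n = len(shared)
    null_abs = np.empty((n_resamples, len(pairs)))
    for b in range(n_resamples):
        perm = rng.permutation(n)
        null_abs[b] = np.abs(_rowwise_pearson(m, e[:, perm]))

    threshold = None
    if fdr >= 1:
        threshold = 0.0
    else:
        # walk candidate thresholds from the largest observed |r| down
        for i, t in enumerate(abs_obs):
            n_obs = i + 1
            mean_null = (null_abs >= t).sum() / n_resamples
            if mean_null / n_obs <= fdr:
                threshold = t
            else:
                break
    if threshold is None:
        threshold = np.inf
    out = pairs.copy()
    out["r"] = r_obs
    out["significant"] = np.abs(r_obs) >= threshold
    out["direction"] = np.sign(r_obs).astype(int)
    n_sig = int(out["significant"].sum())
    frac_neg = (
        float((out.loc[out["significant"], "r"] < 0).mean()) if n_sig else np.nan
    )
    return {
        "threshold": float(threshold),
        "pairs": out,
        "fraction_significant": n_sig / len(out) if len(out) else 0.0,
        "fraction_negative_among_significant": frac_neg,
    }


def group_expression_test(values: pd.Series, group: pd.Series):
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test of a gene's expression
    between two groups (tie-corrected)."""
    values, group = values.align(group, join="inner")
    levels = sorted(pd.Series(group.unique()).dropna().tolist())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 group levels, got {levels}")
    a = values[(group == levels[0]).to_numpy()]
    b = values[(group == levels[1]).to_numpy()]
    combined = np.concatenate([a.to_numpy(), b.to_numpy()])
    # exact null when tie-free and small; tie-corrected normal otherwise
    method = (
        "exact" if len(np.unique(combined)) == len(combined) and len(combined) <= 40
        else "asymptotic"
    )
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(u), float(p)
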