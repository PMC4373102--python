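"""Sample subgrouping from DMR methylation and the three-pattern partition.

Stable tumor subgroups come from bootstrap consensus of average-linkage
hierarchical clustering on 1 - Pearson correlation distance between
samples; subgroup-specific DMRs are selected by one-way ANOVA with BH
correction and partitioned into three archetypal methylation patterns
(monotone decreasing / subgroup-3-specific / monotone increasing over
subgroups 1..4).  A k-means consensus variant serves validation-style
probe matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests


@dataclass
class SubgroupAssignment:
    labels: pd.Series  # sample_id -> 1..k
    stability: pd.Series  # mean co-clustering frequency with co-members
    k: int
    settings: dict

    def __post_init__(self) -> None:
        if not self.labels.index.equals(self.stability.index):
            raise ValueError("labels and stability must share an index")


@dataclass
class PatternAssignment:
    labels: pd.Series  # dmr_id -> 1..3
    counts: dict[int, int]


# ---------------------------------------------------------------------------


def select_top_variance(dmr_matrix: pd.DataFrame, fraction: float = 0.25) -> pd.DataFrame:
    """The ``floor(fraction * n)`` DMRs with highest across-sample variance.

    Ties at the cutoff are broken by row (genomic) order, so the result is
    deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(dmr_matrix) < 4:
        raise ValueError("need at least 4 DMRs")
    n_keep = int(np.floor(fraction * len(dmr_matrix)))
    n_keep = max(n_keep, 1)
    var = dmr_matrix.var(axis=1, ddof=1)
    # stable sort descending: highest variance first, original order on ties
    order = np.argsort(-var.to_numpy(), kind="stable")[:n_keep]
    keep = dmr_matrix.index[np.sort(order)]
    return dmr_matrix.loc[keep]


def _corr_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; undefined pairs (constant
    rows) get distance 1."""
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn("constant profile: correlation undefined, distance set to 1",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    d = 1.0 - c
    d[np.isnan(d)] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return (d + d.T) / 2


def bootstrap_hclust(
    dmr_matrix: pd.DataFrame,
    k_range: range | list[int] = range(2, 9),
    B: int = 1000,
    seed: int = 0,
    robustness: float = 0.95,
) -> tuple[SubgroupAssignment, pd.DataFrame]:
    """Bootstrap consensus clustering of samples over DMR features.

    Each of ``B`` resamples draws DMR features with replacement, clusters
    the samples by average linkage on correlation distance, and cuts at
    each candidate k.  The consensus matrix holds pairwise co-clustering
    frequencies; the final assignment is a hierarchical cut of
    1 - consensus at the chosen k.

    k is the largest candidate for which every cluster is robust (mean
    within-cluster co-clustering frequency >= ``robustness``).  On
    hierarchically structured data every coarsening of the true split is
    itself perfectly stable, so simply maximizing a consensus score
    elects the coarsest k; demanding that all clusters stay robust
    instead finds the finest stable partition.  If no candidate
    qualifies, the k maximizing within- minus between-cluster consensus
    is used as a fallback.
    """
    k_range = list(k_range)
    samples = list(dmr_matrix.columns)
    n = len(samples)
    if n < 2 * max(k_range):
        raise ValueError("need at least 2*max(k) samples")
    rng = np.random.default_rng(seed)
    x = dmr_matrix.to_numpy().T  # samples x features
    nf = x.shape[1]

    co = {k: np.zeros((n, n)) for k in k_range}
    for b in range(B):
        feat = rng.integers(0, nf, size=nf) if B > 1 else np.arange(nf)
        d = _corr_distance(x[:, feat])
        z = linkage(squareform(d, checks=False), method="average")
        for k in k_range:
            lab = fcluster(z, t=k, criterion="maxclust")
            co[k] += lab[:, None] == lab[None, :]
    for k in k_range:
        co[k] /= B

    labels_by_k, score_by_k, min_cons_by_k = {}, {}, {}
    off = ~np.eye(n, dtype=bool)
    for k in k_range:
        cons = co[k]
        z = linkage(squareform(np.clip(1 - cons, 0, None), checks=False),
                    method="average")
        lab = fcluster(z, t=k, criterion="maxclust")
        labels_by_k[k] = lab
        same = lab[:, None] == lab[None, :]
        within = cons[same & off]
        between = cons[~same]
        score_by_k[k] = within.mean() - (between.mean() if between.size else 0.0)
        cluster_means = []
        for c in np.unique(lab):
            m = lab == c
            if m.sum() < 2:
                # a singleton is not evidence of a robust subgroup
                cluster_means.append(0.0)
            else:
                sub = cons[np.ix_(m, m)]
                cluster_means.append(
                    float(sub[np.triu_indices(int(m.sum()), 1)].mean())
                )
        min_cons_by_k[k] = min(cluster_means)

    robust = [k for k in k_range if min_cons_by_k[k] >= robustness]
    best_k = max(robust) if robust else max(score_by_k, key=score_by_k.get)
    best_score = score_by_k[best_k]
    best_labels = labels_by_k[best_k]
    cons = co[best_k]
    same = best_labels[:, None] == best_labels[None, :]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        stab = np.where(
            (same & off).sum(axis=1) > 0,
            np.nansum(np.where(same & off, cons, np.nan), axis=1)
            / np.maximum((same & off).sum(axis=1), 1),
            1.0,
        )
    labels = pd.Series(best_labels, index=samples, name="subgroup")
    stability = pd.Series(stab, index=samples, name="stability")
    assignment = SubgroupAssignment(
        labels, stability, best_k,
        {"B": B, "k_range": k_range, "linkage": "average",
         "distance": "1-pearson", "seed": seed, "score": best_score,
         "robustness": robustness,
         "stability_curve": {k: round(min_cons_by_k[k], 4) for k in k_range},
         "score_curve": {k: round(score_by_k[k], 4) for k in k_range}},
    )
    consensus = pd.DataFrame(cons, index=samples, columns=samples)
    return assignment, consensus


def anova_subgroup_dmrs(
    dmr_matrix: pd.DataFrame, subgroups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA per DMR across subgroup labels, BH-corrected.

    Returns the rows of ``dmr_matrix`` with q < alpha, plus columns
    ``anova_p`` and ``anova_q`` as an attached frame (``.attrs['anova']``).
    """
    groups = subgroups.loc[dmr_matrix.columns]
    counts = groups.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"subgroup(s) {bad} have fewer than 2 samples")
    x = dmr_matrix.to_numpy()
    f, p = _anova_f(x, groups.to_numpy())
    _, q, *_ = multipletests(p, method="fdr_bh")
    result = pd.DataFrame({"F": f, "anova_p": p, "anova_q": q},
                          index=dmr_matrix.index)
    keep = result.index[result["anova_q"] < alpha]
    out = dmr_matrix.loc[keep].copy()
    out.attrs["anova"] = result
    return out


def _anova_f(x: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA over rows of x."""
    levels = np.unique(labels)
    n = x.shape[1]
    grand = x.mean(axis=1, keepdims=True)
    ss_between = np.zeros(x.shape[0])
    ss_within = np.zeros(x.shape[0])
    for lv in levels:
        sub = x[:, labels == lv]
        m = sub.mean(axis=1, keepdims=True)
        ss_between += sub.shape[1] * (m[:, 0] - grand[:, 0]) ** 2
        ss_within += ((sub - m) ** 2).sum(axis=1)
    df_b = len(levels) - 1
    df_w = n - len(levels)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    f = np.nan_to_num(f, nan=0.0, posinf=np.inf)
    p = sps.f.sf(f, df_b, df_w)
    return f, p


# ---------------------------------------------------------------------------
# pattern derivation
# ---------------------------------------------------------------------------

#: archetype subgroup-mean profiles over subgroups 1..4 (before centering)
PATTERN_ARCHETYPES = {
    1: np.array([3.0, 2.0, 1.0, 0.0]),  # monotone decreasing
    2: np.array([0.0, 0.0, 1.0, 0.0]),  # subgroup-3 specific
    3: np.array([0.0, 1.0, 2.0, 3.0]),  # monotone increasing
}


def derive_patterns(
    dmr_matrix: pd.DataFrame, subgroups: pd.Series
) -> PatternAssignment:
    """Cluster subgroup-specific DMRs into the three methylation patterns.

    DMRs are clustered (1 - Pearson over samples, Ward linkage) and cut
    into three clusters; each cluster's mean subgroup profile is matched
    to the nearest archetype by cosine similarity of centered profiles.
    The match must be one-to-one or an error is raised.
    """
    if len(dmr_matrix) < 3:
        raise ValueError("need at least 3 DMRs")
    groups = subgroups.loc[dmr_matrix.columns]
    x = dmr_matrix.to_numpy()
    d = _corr_distance(x)
    z = linkage(squareform(d, checks=False), method="ward")
    clusters = fcluster(z, t=3, criterion="maxclust")

    profiles = {}
    for c in (1, 2, 3):
        sub = x[clusters == c]
        prof = np.array(
            [sub[:, (groups == g).to_numpy()].mean() for g in (1, 2, 3, 4)]
        )
        profiles[c] = prof

    def _cos(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return a @ b / denom if denom > 0 else 0.0

    match = {}
    for c, prof in profiles.items():
        sims = {p: _cos(prof, arch) for p, arch in PATTERN_ARCHETYPES.items()}
        ranked = sorted(sims.items(), key=lambda t: -t[1])
        if len(ranked) > 1 and np.isclose(ranked[0][1], ranked[1][1]):
            raise ValueError(
                f"cluster {c}: tie between archetypes {ranked[0][0]} and "
                f"{ranked[1][0]}; inspect profiles manually"
            )
        match[c] = ranked[0][0]
    if len(set(match.values())) != 3:
        raise ValueError(
            f"archetype matching not one-to-one ({match}); inspect cluster "
            "profiles manually"
        )
    labels = pd.Series(
        [match[c] for c in clusters], index=dmr_matrix.index, name="pattern"
    )
    counts = labels.value_counts().to_dict()
    return PatternAssignment(labels, {p: counts.get(p, 0) for p in (1, 2, 3)})


# ---------------------------------------------------------------------------
# k-means consensus (validation-style matrices)
# ---------------------------------------------------------------------------


def kmeans_consensus(
    matrix: pd.DataFrame,
    k: int,
    n_iter: int = 500,
    subsample: float = 0.8,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """Consensus k-means over random sample subsets.

    Rows of ``matrix`` are features, columns are samples.  Co-clustering
    frequencies are computed over iterations where both samples were
    drawn; final labels come from an average-linkage cut of
    1 - consensus.
    """
    samples = list(matrix.columns)
    n = len(samples)
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    rng = np.random.default_rng(seed)
    x = matrix.to_numpy().T
    co = np.zeros((n, n))
    seen = np.zeros((n, n))
    m = max(int(round(subsample * n)), k + 1)
    for it in range(n_iter):
        idx = (
            rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
        )
        km = KMeans(n_clusters=k, n_init=1 if n_iter > 1 else 10,
                    random_state=int(rng.integers(2**31 - 1)))
        lab = km.fit_predict(x[idx])
        pair = lab[:, None] == lab[None, :]
        co[np.ix_(idx, idx)] += pair
        seen[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        cons = np.where(seen > 0, co / np.maximum(seen, 1), 0.0)
    np.fill_diagonal(cons, 1.0)
    if n_iter == 1 and m == n:
        labels = pd.Series(lab + 1, index=samples, name="cluster")
    else:
        z = linkage(squareform(np.clip(1 - cons, 0, None), checks=False),
                    method="average")
        labels = pd.Series(
            fcluster(z, t=k, criterion="maxclust"), index=samples, name="cluster"
        )
    return labels, pd.DataFrame(cons, index=samples, columns=samples)


def clustering_concordance(labels_a: pd.Series, labels_b: pd.Series):
    """Chi-square test of independence of two labelings of the same samples."""
    a, b = labels_a.align(labels_b, join="inner")
    table = pd.crosstab(a, b)
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return chi2, p, table
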