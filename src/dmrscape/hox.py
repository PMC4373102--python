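"""HOX-locus epigenetic switch analysis.

A two-block locus model (anterior = 3' block, posterior = 5' block) is
clustered at the sample level (k-means, k = 3) and clusters are mapped
deterministically to posterior-only / anterior-only / pan methylation
groups by comparing block means against cohort medians.  Group contrasts
use Welch t-tests with BH correction (starburst coordinates for joint
methylation/expression calls), logrank for survival, and pairwise
pattern-level comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .synthetic import DegenerateLocusError

HOX_GROUPS = ("posterior_only", "anterior_only", "pan")


@dataclass
class LocusModel:
    """Ordered locus DMRs split into an anterior and a posterior block.

    ``dmr_ids[:boundary_index]`` is the anterior block, the rest the
    posterior block; both must be non-empty.
    """

    name: str
    dmr_ids: list[str]
    boundary_index: int

    def __post_init__(self) -> None:
        if not 0 < self.boundary_index < len(self.dmr_ids):
            raise DegenerateLocusError(
                f"{self.name}: boundary must split the locus into two "
                "non-empty blocks"
            )

    @property
    def anterior(self) -> list[str]:
        return self.dmr_ids[: self.boundary_index]

    @property
    def posterior(self) -> list[str]:
        return self.dmr_ids[self.boundary_index :]


@dataclass
class HoxAssignment:
    labels: pd.Series  # sample -> posterior_only / anterior_only / pan
    profiles: pd.DataFrame  # group x DMR mean
    profile_sd: pd.DataFrame


def locus_kmeans(
    locus_matrix: pd.DataFrame,
    locus: LocusModel,
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 50,
) -> HoxAssignment:
    """K-means over samples on locus-DMR methylation, relabeled by block
    means.

    For each cluster the anterior/posterior block means are dichotomized
    against the midpoint of the cluster block-mean range: posterior high
    and anterior low is 'posterior_only', the reverse is
    'anterior_only', both high is 'pan'.  Ambiguous mappings (a cluster
    with both blocks low, or a many-to-one mapping) raise with the
    cluster profiles listed.
    """
    missing = [d for d in locus.dmr_ids if d not in locus_matrix.index]
    if missing:
        raise KeyError(f"locus DMRs missing from matrix: {missing}")
    x = locus_matrix.loc[locus.dmr_ids].to_numpy().T  # samples x DMRs
    n_samples = x.shape[0]
    if k > n_samples:
        raise ValueError("k exceeds the number of samples")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(x)

    samples = list(locus_matrix.columns)
    a_ids, p_ids = locus.anterior, locus.posterior
    m_a = locus_matrix.loc[a_ids].mean(axis=0)  # per-sample anterior mean
    m_p = locus_matrix.loc[p_ids].mean(axis=0)

    cluster_a = {c: m_a[np.array(samples)[raw == c]].mean() for c in range(k)}
    cluster_p = {c: m_p[np.array(samples)[raw == c]].mean() for c in range(k)}
    # a block is "high" in a cluster when its mean lies above the midpoint
    # of the cluster block-mean range (robust down to zero noise)
    thr_a = (min(cluster_a.values()) + max(cluster_a.values())) / 2
    thr_p = (min(cluster_p.values()) + max(cluster_p.values())) / 2

    mapping = {}
    profiles = {}
    for c in range(k):
        ca, cp = cluster_a[c], cluster_p[c]
        profiles[c] = (ca, cp)
        high_a, high_p = ca > thr_a, cp > thr_p
        if high_p and not high_a:
            mapping[c] = "posterior_only"
        elif high_a and not high_p:
            mapping[c] = "anterior_only"
        elif high_a and high_p:
            mapping[c] = "pan"
        else:
            raise ValueError(
                f"ambiguous cluster {c}: anterior mean {ca:.3f}, posterior "
                f"mean {cp:.3f} both below cohort medians; cluster profiles: "
                f"{profiles}"
            )
    if len(set(mapping.values())) != k:
        raise ValueError(f"cluster-to-group mapping not one-to-one: {mapping}")

    labels = pd.Series([mapping[c] for c in raw], index=samples, name="hox_group")
    prof_rows, sd_rows = {}, {}
    for g in set(labels):
        sub = locus_matrix.loc[locus.dmr_ids, labels.index[labels == g]]
        prof_rows[g] = sub.mean(axis=1)
        sd_rows[g] = sub.std(axis=1, ddof=1)
    return HoxAssignment(labels, pd.DataFrame(prof_rows).T, pd.DataFrame(sd_rows).T)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def hox_group_tests(
    data: dict[str, pd.DataFrame],
    groups: pd.Series,
    contrast: str,
    reference: str = "posterior_only",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Welch t-tests of ``contrast`` vs ``reference`` groups per feature
    and data level.

    ``data`` maps a level name (e.g. 'methylation', 'expression') to a
    feature x sample frame.  BH correction is applied within each level;
    a feature is *called* when it passes FDR < alpha at every level.
    Starburst coordinates are signed -log10(q) (sign = direction of the
    contrast-group change vs the reference).
    """
    ref_ids = groups.index[groups == reference]
    con_ids = groups.index[groups == contrast]
    if len(ref_ids) < 2 or len(con_ids) < 2:
        raise ValueError("both groups need at least 2 samples")
    frames = []
    for level, df in data.items():
        ref = df[[c for c in ref_ids if c in df.columns]].to_numpy(float)
        con = df[[c for c in con_ids if c in df.columns]].to_numpy(float)
        t, p = sps.ttest_ind(con, ref, axis=1, equal_var=False)
        _, q, *_ = multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")
        sign = np.sign(con.mean(axis=1) - ref.mean(axis=1))
        frames.append(
            pd.DataFrame(
                {
                    f"{level}_t": t,
                    f"{level}_q": q,
                    f"{level}_sign": sign,
                    f"{level}_starburst": sign * -np.log10(np.clip(q, 1e-300, None)),
                    f"{level}_pass": q < alpha,
                },
                index=df.index,
            )
        )
    out = pd.concat(frames, axis=1, join="inner")
    pass_cols = [c for c in out.columns if c.endswith("_pass")]
    out["called"] = out[pass_cols].all(axis=1)
    return out


def concordant_pair_counts(tests: pd.DataFrame) -> dict:
    """Counts of called features and of the canonical methylation-up /
    expression-down direction among them."""
    called = tests[tests["called"]]
    concordant = called[
        (called.get("methylation_sign", 0) > 0) & (called.get("expression_sign", 0) < 0)
    ]
    return {"n_called": int(len(called)), "n_meth_up_expr_down": int(len(concordant))}


def logrank_by_group(survival: pd.DataFrame, groups: pd.Series):
    """K-group logrank test (no covariate adjustment).

    ``survival`` needs columns survival_time and event; samples with
    missing survival are excluded.
    """
    df = survival.join(groups.rename("group"), how="inner")
    df = df.dropna(subset=["survival_time", "event", "group"])
    res = multivariate_logrank_test(
        df["survival_time"], df["group"], df["event"]
    )
    return float(res.test_statistic), float(res.p_value)


def pattern_level_group_comparison(
    dmr_means: pd.DataFrame,
    patterns: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Pairwise Welch t-tests of per-sample pattern mean methylation
    between HOX groups, BH-corrected over all (pattern, pair) tests."""
    shared = [s for s in dmr_means.columns if s in groups.index]
    rows = []
    for pat in sorted(patterns.unique()):
        ids = patterns.index[patterns == pat]
        per_sample = dmr_means.loc[[d for d in ids if d in dmr_means.index], shared].mean(axis=0)
        levels = sorted(groups.loc[shared].unique())
        for i, g1 in enumerate(levels):
            for g2 in levels[i + 1 :]:
                a = per_sample[(groups.loc[shared] == g1).to_numpy()]
                b = per_sample[(groups.loc[shared] == g2).to_numpy()]
                if len(a) < 2 or len(b) < 2:
                    raise ValueError(
                        f"group {g1 if len(a) < 2 else g2} has fewer than 2 samples"
                    )
                t, p = welch_t(a.to_numpy(), b.to_numpy())
                rows.append(
                    {"pattern": pat, "group_a": g1, "group_b": g2,
                     "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                     "t": t, "p": p}
                )
    out = pd.DataFrame(rows)
    if len(out):
        _, out["q"], *_ = multipletests(out["p"], method="fdr_bh")
    return out
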