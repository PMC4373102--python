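import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from dmrscape import subgrouping as sg


def _blobs(n_per=15, k=2, n_feat=40, sep=5.0, seed=0):
    """Well-separated groups sharing a distinct feature *profile* per group
    (separable under both correlation and Euclidean metrics)."""
    rng = np.random.default_rng(seed)
    profiles = rng.normal(0.0, sep, size=(k, n_feat))
    cols, data = [], []
    for g in range(k):
        for i in range(n_per):
            cols.append(f"g{g}_s{i}")
            data.append(profiles[g] + rng.normal(0, 1.0, n_feat))
    return pd.DataFrame(np.array(data).T, columns=cols), np.repeat(range(k), n_per)


def test_select_top_variance_identity_and_floor():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(5453, 6)))
    assert sg.select_top_variance(df, 1.0).equals(df)
    top = sg.select_top_variance(df, 0.25)
    assert len(top) == 1363  # floor(0.25 * 5453)
    # oracle: sort by variance
    var = df.var(axis=1, ddof=1)
    expected = set(var.sort_values(ascending=False).index[:1363])
    assert set(top.index) == expected
    with pytest.raises(ValueError):
        sg.select_top_variance(df, 0.0)


def test_select_top_variance_scaling_invariant():
    df = pd.DataFrame(np.random.default_rng(1).normal(size=(40, 8)))
    a = sg.select_top_variance(df, 0.5).index
    b = sg.select_top_variance(df * 3.0, 0.5).index
    assert list(a) == list(b)


def test_bootstrap_hclust_two_blobs_perfect():
    df, truth = _blobs(n_per=10, k=2, seed=1)
    assign, cons = sg.bootstrap_hclust(df, k_range=[2], B=50, seed=1)
    assert assign.k == 2
    assert adjusted_rand_score(truth, assign.labels.to_numpy()) == 1.0
    assert np.allclose(assign.stability.to_numpy(), 1.0)


def test_bootstrap_hclust_B1_equals_plain_hclust():
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    df, _ = _blobs(n_per=8, k=3, sep=3.0, seed=2)
    assign, _ = sg.bootstrap_hclust(df, k_range=[3], B=1, seed=0)
    d = sg._corr_distance(df.to_numpy().T)
    z = linkage(squareform(d, checks=False), method="average")
    plain = fcluster(z, t=3, criterion="maxclust")
    assert adjusted_rand_score(plain, assign.labels.to_numpy()) == 1.0


def test_bootstrap_hclust_recovers_four_subgroups(default_bundle):
    cfg = default_bundle["config"]
    truth = default_bundle["truth"]
    means = truth.dmr_sample_means[cfg.tumor_ids]
    top = sg.select_top_variance(means, 0.25)
    assign, _ = sg.bootstrap_hclust(top, k_range=range(2, 9), B=200, seed=11)
    assert assign.k == 4
    ari = adjusted_rand_score(
        truth.subgroups.to_numpy(), assign.labels[truth.subgroups.index].to_numpy()
    )
    assert ari >= 0.9


def test_anova_f_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(30, 20))
    labels = np.repeat([1, 2, 3, 4], 5)
    f, p = sg._anova_f(x, labels)
    for i in range(x.shape[0]):
        groups = [x[i, labels == g] for g in (1, 2, 3, 4)]
        grand = x[i].mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ssb / 3) / (ssw / 16)
        assert f[i] == pytest.approx(f_oracle, abs=1e-10)
        assert p[i] == pytest.approx(sps.f_oneway(*groups).pvalue, abs=1e-10)


def test_anova_extreme_separation_retained():
    rng = np.random.default_rng(4)
    labels = pd.Series(np.repeat([1, 2, 3, 4], 6), index=[f"s{i}" for i in range(24)])
    base = rng.normal(0, 0.1, size=(5, 24))
    base[0, (labels == 3).to_numpy()] += 5.0
    df = pd.DataFrame(base, columns=labels.index)
    out = sg.anova_subgroup_dmrs(df, labels)
    assert 0 in out.index
    assert out.attrs["anova"].loc[0, "anova_q"] < 1e-10


def test_anova_null_calibration_and_small_group_error():
    rng = np.random.default_rng(5)
    labels = pd.Series(np.repeat([1, 2, 3, 4], 25), index=[f"s{i}" for i in range(100)])
    df = pd.DataFrame(rng.normal(size=(400, 100)), columns=labels.index)
    out = sg.anova_subgroup_dmrs(df, labels, alpha=0.05)
    assert len(out) / 400 <= 0.075  # BH on null keeps almost nothing
    bad = labels.copy()
    bad.iloc[:] = 1
    bad.iloc[0] = 2
    with pytest.raises(ValueError, match="fewer than 2"):
        sg.anova_subgroup_dmrs(df, bad)


def test_anova_qvalues_monotone_in_p():
    rng = np.random.default_rng(6)
    labels = pd.Series(np.repeat([1, 2, 3, 4], 5), index=[f"s{i}" for i in range(20)])
    df = pd.DataFrame(rng.normal(size=(50, 20)), columns=labels.index)
    res = sg.anova_subgroup_dmrs(df, labels, alpha=1.0).attrs["anova"]
    srt = res.sort_values("anova_p")
    assert (np.diff(srt["anova_q"].to_numpy()) >= -1e-12).all()


def _archetype_matrix(n_rep=10, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = pd.Series(
        np.repeat([1, 2, 3, 4], 5), index=[f"s{i}" for i in range(20)]
    )
    profiles = {1: [3, 2, 1, 0], 2: [0, 0, 1, 0], 3: [0, 1, 2, 3]}
    rows, truth = [], []
    for pat, prof in profiles.items():
        for _ in range(n_rep):
            row = np.repeat(prof, 5) + rng.normal(0, noise, 20)
            rows.append(row)
            truth.append(pat)
    df = pd.DataFrame(rows, columns=labels.index,
                      index=[f"d{i}" for i in range(len(rows))])
    return df, pd.Series(truth, index=df.index), labels


def test_derive_patterns_noiseless_exact():
    df, truth, labels = _archetype_matrix(noise=0.0)
    out = sg.derive_patterns(df, labels)
    assert (out.labels == truth).all()
    assert out.counts == {1: 10, 2: 10, 3: 10}


def test_derive_patterns_input_order_invariance():
    df, truth, labels = _archetype_matrix(noise=0.2, seed=7)
    out1 = sg.derive_patterns(df, labels)
    perm = df.sample(frac=1.0, random_state=0)
    out2 = sg.derive_patterns(perm, labels)
    assert (out2.labels.loc[df.index] == out1.labels).all()


def test_derive_patterns_pattern2_definition():
    # a profile elevated only in subgroup 3 must land in pattern 2
    df, truth, labels = _archetype_matrix(noise=0.05, seed=8)
    out = sg.derive_patterns(df, labels)
    target = df.index[truth == 2]
    assert (out.labels.loc[target] == 2).all()


def test_kmeans_consensus_blobs_block_diagonal():
    df, truth = _blobs(n_per=8, k=3, sep=6.0, seed=9)
    labels, cons = sg.kmeans_consensus(df, k=3, n_iter=60, seed=1)
    same = truth[:, None] == truth[None, :]
    assert np.allclose(cons.to_numpy()[same], 1.0)
    assert np.allclose(cons.to_numpy()[~same], 0.0)
    assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0


def test_kmeans_consensus_seed_stability():
    df, truth = _blobs(n_per=8, k=3, sep=6.0, seed=10)
    l1, _ = sg.kmeans_consensus(df, k=3, n_iter=40, seed=1)
    l2, _ = sg.kmeans_consensus(df, k=3, n_iter=40, seed=2)
    assert adjusted_rand_score(l1.to_numpy(), l2.to_numpy()) >= 0.95


def test_kmeans_consensus_degenerate_is_plain_kmeans():
    from sklearn.cluster import KMeans

    df, truth = _blobs(n_per=6, k=2, sep=8.0, seed=11)
    labels, _ = sg.kmeans_consensus(df, k=2, n_iter=1, subsample=1.0, seed=3)
    plain = KMeans(n_clusters=2, n_init=10, random_state=0).fit_predict(
        df.to_numpy().T
    )
    assert adjusted_rand_score(plain, labels.to_numpy()) == 1.0
    with pytest.raises(ValueError):
        sg.kmeans_consensus(df, k=len(df.columns))


def test_clustering_concordance():
    idx = [f"s{i}" for i in range(30)]
    a = pd.Series(np.repeat([1, 2, 3], 10), index=idx)
    chi2, p, table = sg.clustering_concordance(a, a)
    assert p < 1e-10
    # hand-computed 2x2 chi-square (no continuity correction)
    b1 = pd.Series([1] * 10 + [2] * 10, index=idx[:20])
    b2 = pd.Series([1] * 7 + [2] * 3 + [1] * 2 + [2] * 8, index=idx[:20])
    chi2_2, p_2, tab = sg.clustering_concordance(b1, b2)
    obs = tab.to_numpy()
    row = obs.sum(1, keepdims=True)
    col = obs.sum(0, keepdims=True)
    exp = row @ col / obs.sum()
    chi2_oracle = ((obs - exp) ** 2 / exp).sum()
    assert chi2_2 == pytest.approx(chi2_oracle, abs=1e-10)
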