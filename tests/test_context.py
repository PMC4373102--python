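import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dmrscape import context as ctx


def _frame(rows, label=True):
    cols = ["chrom", "start", "end"] + (["label"] if label else [])
    return pd.DataFrame(rows, columns=cols)


def brute_force_overlap(intervals, track):
    """Per-base loop oracle for basewise_overlap."""
    out = []
    for _, q in intervals.iterrows():
        counts = {}
        for base in range(q["start"], q["end"]):
            for _, t in track.iterrows():
                if t["chrom"] == q["chrom"] and t["start"] <= base < t["end"]:
                    counts[t["label"]] = counts.get(t["label"], 0) + 1
                    break  # merged per label below; count a base once per label
        out.append(counts)
    return out


def test_basewise_overlap_trivial_examples():
    track = _frame([("chr1", 100, 200, 3)])
    q = _frame([("chr1", 100, 200)], label=False)
    res = ctx.basewise_overlap(q, track)
    assert res.iloc[0][3] == 100
    track2 = _frame([("chr1", 0, 150, 1), ("chr1", 150, 300, 2)])
    res2 = ctx.basewise_overlap(_frame([("chr1", 100, 200)], label=False), track2)
    assert res2.iloc[0][1] == 50 and res2.iloc[0][2] == 50


def test_basewise_overlap_unknown_chromosome_counts_zero():
    track = _frame([("chr1", 0, 100, 1)])
    res = ctx.basewise_overlap(_frame([("chr7", 0, 50)], label=False), track)
    assert res.iloc[0].sum() == 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_basewise_overlap_matches_per_base_oracle(seed):
    rng = np.random.default_rng(seed)
    track = _frame(
        [
            ("chr1", s, s + int(rng.integers(1, 60)), int(rng.integers(1, 4)))
            for s in rng.integers(0, 400, size=8)
        ]
    )
    qs = rng.integers(0, 400, size=4)
    queries = _frame(
        [("chr1", int(s), int(s + rng.integers(1, 80))) for s in qs], label=False
    )
    res = ctx.basewise_overlap(queries, track)
    oracle = []
    for _, q in queries.iterrows():
        counts = {}
        for lb in track["label"].unique():
            sub = track[track["label"] == lb]
            n = 0
            for base in range(q["start"], q["end"]):
                if ((sub["start"] <= base) & (base < sub["end"])).any():
                    n += 1
            counts[lb] = n
        oracle.append(counts)
    for i, counts in enumerate(oracle):
        for lb, n in counts.items():
            assert res.iloc[i].get(lb, 0) == n


def test_consensus_state_majority_and_tie():
    assert ctx.consensus_state(pd.Series({3: 400, 13: 100})) == 3
    assert ctx.consensus_state(pd.Series({2: 250, 7: 250})) == 2
    df = pd.DataFrame({2: [250, 10], 7: [250, 400]}, index=["a", "b"])
    out = ctx.consensus_state(df)
    assert out["a"] == 2 and out["b"] == 7
    # random counts vs max-scan oracle
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(0, 100, size=(50, 15)),
                          columns=[str(s) for s in range(1, 16)])
    out = ctx.consensus_state(counts)
    for i in range(50):
        row = counts.iloc[i]
        best = row.max()
        expected = min(int(c) for c in counts.columns if row[c] == best)
        assert out.iloc[i] == expected


def test_chrom_end_features():
    lengths = {"chr1": 30_000_000}
    dmrs = _frame(
        [("chr1", 0, 500), ("chr1", 14_999_750, 15_000_250)], label=False
    )
    out = ctx.chrom_end_features(dmrs, lengths)
    assert out.iloc[0]["dist_to_chrom_end"] == 0 and out.iloc[0]["subtelomeric"]
    assert out.iloc[1]["dist_to_chrom_end"] == 14_999_750
    assert not out.iloc[1]["subtelomeric"]
    # oracle on random intervals
    rng = np.random.default_rng(1)
    starts = rng.integers(0, 29_000_000, size=30)
    rand = _frame([("chr1", int(s), int(s + 500)) for s in starts], label=False)
    out = ctx.chrom_end_features(rand, lengths)
    for i, s in enumerate(starts):
        assert out.iloc[i]["dist_to_chrom_end"] == min(s, 30_000_000 - (s + 500))


def test_repeat_content():
    reps = _frame([("chr1", 0, 5000, "LINE1")])
    dmrs = _frame([("chr1", 2000, 2400)], label=False)
    out = ctx.repeat_content(dmrs, reps, window=2000)
    assert out.iloc[0]["repeat_bases"] == 2000 and out.iloc[0]["repeat_present"]
    empty = ctx.repeat_content(dmrs, _frame([("chr1", 0, 10, "Alu")]), window=2000)
    assert empty.iloc[0]["repeat_bases"] == 0 and not empty.iloc[0]["repeat_present"]


def test_window_profile_full_coverage_and_symmetry():
    track = _frame([("chr1", 0, 10_000)], label=False)
    anchors = _frame([("chr1", 4_000, 4_100)], label=False)
    prof = ctx.window_profile(anchors, track, 400)
    assert np.allclose(prof.frequency, 1.0)
    # symmetric placement around midpoints gives a symmetric profile
    anchors2 = _frame([("chr1", 1000, 1100), ("chr1", 3000, 3100)], label=False)
    track2 = _frame(
        [("chr1", 1000, 1100), ("chr1", 3000, 3100)], label=False
    )  # features centered on the anchors
    prof2 = ctx.window_profile(anchors2, track2, 400)
    assert np.allclose(prof2.frequency, prof2.frequency[::-1])
    with pytest.raises(ValueError):
        ctx.window_profile(anchors, track, 0)


def test_window_profile_minus_strand_flip():
    # feature 100 bp downstream of a minus-strand TSS appears at +100
    anchors = pd.DataFrame(
        {"chrom": ["chr1"], "tss": [5000], "strand": ["-"]}
    )
    track = _frame([("chr1", 4890, 4900)], label=False)  # 100 bp downstream (5'->3' on -)
    prof = ctx.window_profile(anchors, track, 400, oriented=True)
    pos = np.flatnonzero(prof.frequency > 0) - 200
    assert pos.min() == 100 and pos.max() == 109


def test_window_profile_aggregate_equals_row_mean():
    rng = np.random.default_rng(2)
    track = _frame(
        [("chr1", int(s), int(s + rng.integers(10, 200))) for s in
         rng.integers(0, 50_000, size=20)], label=False,
    )
    anchors = _frame(
        [("chr1", int(s), int(s + 300)) for s in rng.integers(500, 40_000, 10)],
        label=False,
    )
    prof = ctx.window_profile(anchors, track, 1000)
    assert np.allclose(prof.frequency, prof.rows.mean(axis=0).to_numpy())


def test_transition_matrix_identity_and_row_sums(small_bundle):
    states = pd.DataFrame(
        {"H1": [3, 3, 13, 2], "alt": [3, 3, 13, 2]},
        index=["a", "b", "c", "d"],
    )
    out = ctx.transition_matrix(states, "H1")["alt"]
    assert np.allclose(np.diag(out.loc[[2, 3, 13], [2, 3, 13]]), 1.0)
    assert np.allclose(out.sum(axis=1), 1.0)


def test_transition_matrix_planted_state3_to_12(default_bundle):
    truth = default_bundle["truth"]
    tracks = default_bundle["tracks"]
    cells = ["H1", "GM12878"]
    cons = {}
    for cell in cells:
        counts = ctx.basewise_overlap(
            truth.dmrs, tracks.intervals[f"chromatin_{cell}"]
        )
        cons[cell] = ctx.consensus_state(counts)
    states = pd.DataFrame(cons)
    out = ctx.transition_matrix(states, "H1", restrict_state=3)["GM12878"]
    assert out.loc[3, 12] >= 0.9


def test_cgi_features_island_vs_shore():
    cgi = _frame([("chr1", 10_000, 11_000, "CGI")])
    dmrs = _frame(
        [
            ("chr1", 10_200, 10_400),  # inside the island
            ("chr1", 11_500, 11_800),  # in the downstream shore
            ("chr1", 20_000, 20_500),  # far away
        ],
        label=False,
    )
    out = ctx.cgi_features(dmrs, cgi)
    assert out["cgi_overlap"].tolist() == [True, False, False]
    assert out["shore_overlap"].tolist() == [False, True, False]


def test_category_enrichment_fisher_examples():
    # a table built from the cohort's mutation-by-subgroup counts prints
    # p = 0.0026
    odds, p = sps.fisher_exact([[12, 6], [22, 58]])
    feature = pd.Series([True] * 12 + [False] * 6 + [True] * 22 + [False] * 58)
    group = pd.Series(["g1"] * 18 + ["rest"] * 80)
    res = ctx.category_enrichment(feature, group)
    row = res[res["group"] == "g1"].iloc[0]
    assert row["p"] == pytest.approx(p)
    assert f"{row['p']:.2g}" == "0.0026"
    # level absent everywhere -> p = 1
    res0 = ctx.category_enrichment(
        pd.Series([False] * 100), pd.Series(["a"] * 10 + ["b"] * 90)
    )
    assert np.allclose(res0["p"], 1.0)


def test_fisher_matches_hypergeometric_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a, b, c, d = rng.integers(0, 12, size=4)
        table = np.array([[a, b], [c, d]])
        if table.sum() == 0:
            continue
        _, p = sps.fisher_exact(table)
        # enumerate all tables with the same margins; two-sided point rule
        n, r1, c1 = table.sum(), a + b, a + c
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        probs = np.array(
            [sps.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)]
        )
        obs = sps.hypergeom.pmf(a, n, c1, r1)
        oracle = probs[probs <= obs * (1 + 1e-9)].sum()
        assert p == pytest.approx(oracle, abs=1e-12)


def test_fisher_invariant_to_simultaneous_swap():
    feature = pd.Series([True] * 9 + [False] * 21 + [True] * 4 + [False] * 16)
    group = pd.Series(["x"] * 30 + ["y"] * 20)
    res = ctx.category_enrichment(feature, group)
    p_x = res[res["group"] == "x"].iloc[0]["p"]
    res_sw = ctx.category_enrichment(~feature, group.map({"x": "y", "y": "x"}))
    assert res_sw[res_sw["group"] == "y"].iloc[0]["p"] == pytest.approx(p_x)


def test_rank_tests_for_continuous_features():
    rng = np.random.default_rng(4)
    vals = pd.Series(np.concatenate([rng.normal(0, 1, 40), rng.normal(2, 1, 40)]))
    group = pd.Series([1] * 40 + [2] * 40)
    res = ctx.category_enrichment(vals, group)
    assert (res[res["test"] == "mannwhitney"]["p"] < 1e-6).all()
    group3 = pd.Series([1] * 30 + [2] * 30 + [3] * 20)
    res3 = ctx.category_enrichment(vals, group3)
    assert "kruskal" in set(res3["test"])


def test_geneset_overlap():
    universe = {f"g{i}" for i in range(100)}
    genes = {f"g{i}" for i in range(20)}
    # signature == universe -> p = 1
    res = ctx.geneset_overlap(genes, {"all": universe}, universe)
    assert res.loc["all", "p"] == pytest.approx(1.0)
    # empty intersection with a small signature -> p near 1
    res2 = ctx.geneset_overlap(genes, {"other": {f"g{i}" for i in range(90, 95)}},
                               universe)
    assert res2.loc["other", "p"] > 0.5
    # enumeration oracle for a random draw
    sig = {f"g{i}" for i in range(10, 40)}
    res3 = ctx.geneset_overlap(genes, {"sig": sig}, universe)
    k = len(genes & sig)
    oracle = sps.hypergeom.sf(k - 1, 100, len(sig), len(genes))
    assert res3.loc["sig", "p"] == pytest.approx(oracle, abs=1e-12)
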