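import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dmrscape import medip
from dmrscape.synthetic import (
    DegenerateLocusError,
    SimConfig,
    SizingError,
    generate_expression,
    generate_hox_locus,
    generate_probe_matrix,
    generate_raw_intensities,
    generate_tracks,
    sample_table_from_counts,
)


def test_config_rejects_invalid_values():
    with pytest.raises(ValueError):
        SimConfig(effect_size=0.0)
    with pytest.raises(ValueError):
        SimConfig(expr_corr_fraction=1.5)
    with pytest.raises(ValueError):
        SimConfig(n_samples_per_subgroup=(0, 5, 5, 5))


def test_zero_noise_pattern2_separation():
    cfg = SimConfig(
        n_dmrs_per_pattern=(2, 2, 2), n_null_probes=100, noise_sd=0.0,
        effect_size=1.0, n_samples_per_subgroup=(3, 3, 3, 3), seed=0,
    )
    pm, truth = generate_probe_matrix(cfg)
    sub = truth.subgroups
    for dmr_id in truth.dmrs.index[truth.dmrs["pattern"] == 2]:
        row = truth.dmr_sample_means.loc[dmr_id, cfg.tumor_ids]
        in3 = row[sub[sub == 3].index]
        rest = row[sub[sub != 3].index]
        assert np.allclose(in3, rest.mean() + 1.0)
        assert np.allclose(rest, 0.0)


def test_determinism_same_seed_identical():
    cfg = SimConfig(n_dmrs_per_pattern=(5, 5, 5), n_null_probes=300, seed=1)
    a, ta = generate_probe_matrix(cfg)
    b, tb = generate_probe_matrix(cfg)
    pd.testing.assert_frame_equal(a.scores, b.scores)
    pd.testing.assert_frame_equal(a.probes, b.probes)
    pd.testing.assert_frame_equal(ta.dmrs, tb.dmrs)


def test_cpg_density_separates_patterns(small_bundle):
    truth = small_bundle["truth"]
    pm = small_bundle["probe_matrix"]
    dens = {}
    probes = pm.probes
    for p in (1, 2):
        ids = truth.dmrs.index[truth.dmrs["pattern"] == p]
        vals = []
        for dmr_id in ids:
            row = truth.dmrs.loc[dmr_id]
            sel = (
                (probes["chrom"] == row["chrom"])
                & (probes["start"] >= row["start"])
                & (probes["end"] <= row["end"])
            )
            vals.append(probes.loc[sel, "cpg_count"].sum() / (row["end"] - row["start"]))
        dens[p] = np.array(vals)
    assert np.median(dens[2]) > np.median(dens[1])
    p = sps.mannwhitneyu(dens[1], dens[2]).pvalue
    assert p < 0.01


def test_truth_invariants(small_bundle):
    cfg = small_bundle["config"]
    truth = small_bundle["truth"]
    for _, row in truth.dmrs.iterrows():
        assert 0 <= row["start"] < row["end"] <= cfg.chrom_lengths[row["chrom"]]
    assert list(truth.subgroups.index) == cfg.tumor_ids
    assert set(truth.subgroups.unique()) == {1, 2, 3, 4}


def test_sizing_error_on_tiny_chromosome():
    with pytest.raises(SizingError):
        generate_probe_matrix(
            SimConfig(chrom_lengths={"chr1": 1_000_000}, seed=0)
        )


def test_normalization_preserves_planted_ordering():
    """Raw-signal mode: after the five-step normalization the subgroup mean
    rank order within each pattern matches the planted order (effect =
    5 * noise)."""
    cfg = SimConfig(
        n_dmrs_per_pattern=(8, 8, 8), n_null_probes=1000,
        n_samples_per_subgroup=(8, 8, 8, 8), n_normals=0,
        effect_size=1.0, noise_sd=0.2, seed=3,
    )
    pm, truth = generate_probe_matrix(cfg)
    ip, inp = generate_raw_intensities(cfg, pm, cpg_slope=0.05)
    norm = medip.normalize(ip, inp, pm.probes)
    means = medip.summarize_dmrs(norm, {
        d: [p for p in pm.probes.index
            if pm.probes.loc[p, "chrom"] == truth.dmrs.loc[d, "chrom"]
            and truth.dmrs.loc[d, "start"] <= pm.probes.loc[p, "start"]
            and pm.probes.loc[p, "end"] <= truth.dmrs.loc[d, "end"]]
        for d in truth.dmrs.index
    })
    sub = truth.subgroups
    expected = {1: [1, 2, 3, 4], 3: [4, 3, 2, 1]}  # descending methylation
    for pat, order in expected.items():
        ids = truth.dmrs.index[truth.dmrs["pattern"] == pat]
        prof = np.array([
            [means.loc[d, sub[sub == g].index].mean() for g in (1, 2, 3, 4)]
            for d in ids
        ]).mean(axis=0)
        assert list(np.argsort(-prof) + 1) == order


def test_planted_offset_removed_by_median_centering():
    cfg = SimConfig(n_dmrs_per_pattern=(2, 2, 2), n_null_probes=500,
                    n_samples_per_subgroup=(3, 3, 3, 3), seed=4)
    pm, _ = generate_probe_matrix(cfg)
    offsets = np.full(len(pm.sample_ids), 0.7)
    ip, inp = generate_raw_intensities(cfg, pm, offsets=offsets, cpg_slope=0.0)
    params = medip.NormalizationParams(steps_enabled=(True, True, False, False, False))
    norm = medip.normalize(ip, inp, pm.probes, params)
    med = np.median(norm.scores.to_numpy(), axis=0)
    assert np.all(np.abs(med) < 1e-9)


def test_tracks_pattern_constructions(small_bundle):
    truth = small_bundle["truth"]
    tracks = small_bundle["tracks"]
    cgi = tracks.intervals["cgi"]
    p2 = truth.dmrs[truth.dmrs["pattern"] == 2]
    for _, row in p2.iterrows():
        contained = (
            (cgi["chrom"] == row["chrom"])
            & (cgi["start"] <= row["start"])
            & (cgi["end"] >= row["end"])
        )
        assert contained.any()
    p1 = truth.dmrs[truth.dmrs["pattern"] == 1]
    lengths = p1["chrom"].map(tracks.chrom_lengths)
    dist = np.minimum(p1["start"], lengths - p1["end"])
    assert (dist <= 5_000_000).mean() == 1.0


def test_tracks_chromosome_mismatch_raises(small_config):
    pm, truth = generate_probe_matrix(small_config)
    truth.dmrs.loc[truth.dmrs.index[0], "chrom"] = "chr9"
    with pytest.raises(ValueError, match="chr9"):
        generate_tracks(small_config, truth)


def test_expression_limits():
    base = dict(n_dmrs_per_pattern=(0, 0, 10), n_null_probes=200,
                n_samples_per_subgroup=(5, 5, 5, 5), seed=5)
    # perfect planted correlation in the noiseless limit
    cfg = SimConfig(expr_corr_fraction=1.0, expr_target_abs_r=1.0, **base)
    pm, truth = generate_probe_matrix(cfg)
    generate_tracks(cfg, truth)
    expr = generate_expression(cfg, truth)
    for _, pair in truth.planted_pairs.iterrows():
        r = np.corrcoef(
            truth.dmr_sample_means.loc[pair["dmr_id"], cfg.tumor_ids],
            expr.loc[pair["gene_id"]],
        )[0, 1]
        assert r == pytest.approx(-1.0)
    # no planted correlations: empirical |r| in the null range
    cfg0 = SimConfig(expr_corr_fraction=0.0, **base)
    pm0, truth0 = generate_probe_matrix(cfg0)
    generate_tracks(cfg0, truth0)
    expr0 = generate_expression(cfg0, truth0)
    assert truth0.planted_pairs.empty
    rs = [
        np.corrcoef(truth0.dmr_sample_means.loc[d, cfg0.tumor_ids],
                    expr0.loc[g])[0, 1]
        for d, g in truth0.gene_map.items() if g in expr0.index
    ]
    # null |r| for n=20 samples: 95th percentile ~ 0.44
    assert np.max(np.abs(rs)) < 0.7


def test_hox_locus_zero_noise_blocks_exact():
    cfg = SimConfig(noise_sd=0.0, effect_size=1.0, seed=6)
    means, labels, locus = generate_hox_locus(cfg)
    for sid in labels.index:
        a = means.loc[locus.anterior, sid]
        p = means.loc[locus.posterior, sid]
        expect = {
            "posterior_only": (0.0, 1.0),
            "anterior_only": (1.0, 0.0),
            "pan": (1.0, 1.0),
        }[labels[sid]]
        assert np.allclose(a, expect[0]) and np.allclose(p, expect[1])


def test_hox_locus_degenerate_boundary():
    with pytest.raises(DegenerateLocusError):
        generate_hox_locus(SimConfig(n_anterior_dmrs=0, n_posterior_dmrs=12))


def test_clinical_table_injection_passthrough():
    table = sample_table_from_counts()
    assert len(table) == 98
    assert (table["subgroup"].value_counts().sort_index() == [18, 21, 24, 35]).all()
    # marginals reproduce the packaged counts exactly
    sub3 = table[table["subgroup"] == 3]
    assert (sub3["grade"] == "3").sum() == 19
    assert (sub3["fgfr3"] == "mut").sum() == 1


def test_clinical_no_association_gives_uniform_fisher(small_config):
    """With association strength 0, one-vs-rest Fisher p-values are not
    systematically small."""
    from dmrscape.stats import one_vs_rest_fisher
    from dmrscape.synthetic import generate_clinical_and_survival

    pvals = []
    for s in range(30):
        cfg = SimConfig(clinical_association_strength=0.0, seed=400 + s)
        sub = cfg.subgroup_labels()

        class T:
            subgroups = sub

        clin = generate_clinical_and_survival(cfg, T)
        rep = one_vs_rest_fisher(clin, sub, "grade", "3", 3)
        pvals.append(rep.p)
    # discrete p-values are super-uniform; just check they are not enriched
    assert np.mean(np.array(pvals) < 0.05) <= 0.15
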