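# dmrscape

Between-tumor differential DNA methylation analysis for
methylation-enrichment (MeDIP-style) tiling arrays, written for cancer
epigenomics groups who want the full path from probe-level enrichment
scores to biologically annotated methylation subgroups: DMR calling with a
CpG-density-matched permutation null, consensus subgrouping, chromatin- and
regulatory-factor context annotation, methylation–expression integration,
and locus-level "epigenetic switch" classification for HOX-like gene
clusters — together with a synthetic cohort generator so every stage is
testable end to end without any external download.

## The statistics at the core

**DMR calling.** Enrichment scores are log-ratios, not beta values, so
between-tumor DMRs are defined through variance. For probe *i* with scores
*x*<sub>i1..n</sub> across *n* tumors, compute the unbiased variance
*s*<sub>i</sub><sup>2</sup>. Candidate regions are maximal runs of ≥ 4
consecutive probes (inter-probe gap ≤ 500 bp, span ≥ 500 bp) whose
variances all exceed the 90th percentile of all probe variances. Because
enrichment variance is intrinsically coupled to local CpG density, each
candidate's statistic (the mean member-probe variance) is compared against
*B* = 1000 random same-size probe sets drawn from the candidate's CpG
density decile, giving

&nbsp;&nbsp;&nbsp;&nbsp;*p* = (1 + #{null ≥ observed}) / (1 + *B*),

followed by Benjamini–Hochberg control at *q* ≤ 0.05 and merging of
adjacent survivors. Normalization of raw two-channel intensities is a
five-step scheme (log2 IP/input → per-array median centering → quantile
normalization → per-array loess removal of the CpG-count trend → running
mean over adjacent probes), each step individually switchable.

**Subgrouping and patterns.** Samples are clustered by average linkage on
1 − Pearson correlation over bootstrap resamples of DMR features; k is the
largest candidate at which every cluster's mean within-cluster
co-clustering frequency stays ≥ 0.95. Subgroup-specific DMRs (one-way
ANOVA, BH-corrected) are partitioned into three patterns by Ward
clustering and nearest-archetype matching: monotone decreasing over
subgroups 1→4, subgroup-3-specific, and monotone increasing.

**Integration.** DMRs are matched to genes by TSS proximity (≤ 10 kb) and
per-pair correlations are thresholded at one global empirical |r| cutoff
derived from expression-label permutations at a target empirical FDR.
Locus-level switching (anterior vs posterior block methylation) is
classified by k-means (k = 3) with a deterministic block-mean labeling
rule, and groups are compared by Welch t-tests (starburst coordinates),
logrank survival tests, and exact one-vs-rest Fisher tests against
clinical annotations.

## Worked example

```python
from dmrscape import medip, stats
from dmrscape.synthetic import SimConfig, generate_probe_matrix
from dmrscape.subgrouping import bootstrap_hclust

cfg = SimConfig(n_dmrs_per_pattern=(15, 15, 15), n_null_probes=8000,
                n_samples_per_subgroup=(10, 10, 10, 10), n_normals=0, seed=1)
pm, truth = generate_probe_matrix(cfg)
print(f"probes: {pm.n_probes}, samples: {len(pm.sample_ids)}")

dmrs = medip.call_dmrs(pm, medip.DmrCallParams(seed=1))
print(f"called DMRs: {len(dmrs)} (planted: {len(truth.dmrs)})")
r = dmrs.regions
print(f"median size: {r['length'].median():.0f} bp, "
      f"range {r['length'].min()}-{r['length'].max()} bp")

assign, _ = bootstrap_hclust(dmrs.means, k_range=range(2, 7), B=200, seed=1)
print(f"selected k: {assign.k}; mean stability: {assign.stability.mean():.3f}")

table = stats.sample_table_from_counts()
rep = stats.one_vs_rest_fisher(table, table["subgroup"], "fgfr3", "mut", 1)
print(f"subgroup 1 vs rest, FGFR3 mutation: OR={rep.odds_ratio:.2f}, p={rep.p:.4f}")
```

prints

```
probes: 8407, samples: 40
called DMRs: 45 (planted: 45)
median size: 729 bp, range 508-2005 bp
selected k: 4; mean stability: 1.000
subgroup 1 vs rest, FGFR3 mutation: OR=5.27, p=0.0026
```

All 45 planted regions are recovered with no false calls, the four planted
subgroups are found at perfect bootstrap stability, and the exact Fisher
test on the packaged cohort counts shows the mutation enrichment of
subgroup 1 (odds ratio 5.3).

A command-line layer covers the simulation/calling/subgrouping/enrichment
workflow:

```bash
dmrscape simulate --config sim.yaml --out cohort/ --seed 1
dmrscape call-dmrs --matrix cohort/probes.tsv --out dmrs --seed 1
dmrscape subgroup --dmr-matrix dmrs.means.tsv --k-range 2:8 -B 1000 --seed 1 --out subgroups.json
dmrscape enrich --samples cohort/samples.tsv --subgroups subgroups.json --out enrichment.tsv
```

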