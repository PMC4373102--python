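# Methods

This note documents the models and procedures dmrscape implements, the
parameters that matter, what the synthetic cohort does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Data model

Probe-level methylation-enrichment scores (log2 IP/input ratios after
normalization) for a tumor cohort, with per-probe genomic coordinates
(0-based, half-open throughout) and CpG counts. Scores are relative
enrichment values, not absolute methylation fractions: all downstream
statistics are variance- and correlation-based, never threshold the score
scale directly, and are invariant to adding a constant to the whole
matrix.

## Normalization (five steps)

1. **log2(IP/input)** per probe and array; non-positive intensities are a
   hard error naming the probe.
2. **Per-array median centering** — removes array-level offsets (tested:
   a planted +0.7 offset is removed to |median| < 1e-9).
3. **Across-array quantile normalization** — each array's order
   statistics are replaced by the cross-array mean order statistics;
   arrays with identical sorted values are a fixed point.
4. **CpG-count bias removal** — per array, a loess fit (span 0.3) of
   score on probe CpG count is subtracted; this removes the
   enrichment-efficiency trend with local CpG density.
5. **Running mean** over 3 adjacent probes within 500 bp gaps; windows
   truncate at chromosome/run boundaries (warning, not error).

The exact published scheme this reconstructs is not itself available as a
specification; each step is therefore individually switchable
(`NormalizationParams.steps_enabled`) so alternates can be substituted
without touching the caller.

## DMR calling

* Per-probe across-sample variance (unbiased, ddof = 1).
* Candidates: maximal runs of ≥ `min_probes` (4) consecutive probes with
  gap ≤ `max_gap_bp` (500), every variance ≥ the `variance_percentile`
  (90th, ties included) of all probe variances, and span ≥ `min_length`
  (500 bp — matching the smallest region the assay can support).
* Statistic: mean member-probe variance. Null: `n_permutations` (1000)
  random same-size probe sets drawn from the candidate's CpG-density
  decile (density = cpg_count / probe length, deciles over **all**
  probes; a candidate uses its dominant member bin; sparse bins widen to
  adjacent bins with a warning). Empirical p uses the add-one estimator,
  so p ≥ 1/(B+1) and BH remains valid.
* BH at `fdr_alpha` (0.05); surviving regions closer than
  `merge_distance_bp` (200) merge, keeping the smallest member p/q.
* Per-sample DMR scores are arithmetic means of member-probe scores.

Calling is invariant to sample order, probe-ID relabeling, and constants
added to the whole matrix. It is **not** invariant to shifting a single
sample — across-sample variance responds to that by construction; a
per-array offset is an artifact the normalization (step 2) removes before
calling.

Under the null, the permutation p-value of a *fixed* probe set is uniform
(property-tested by KS). Selected candidates are by definition
high-variance, so the run-formation filters (probe count, gap, span,
percentile) carry most of the specificity; the permutation null guards
against CpG-density-driven variance inflation.

## Subgrouping

Feature-bootstrap consensus clustering: B resamples of DMR features (with
replacement), samples clustered by average linkage on 1 − Pearson
correlation; co-clustering frequencies accumulate per candidate k; final
labels cut the consensus dissimilarity (1 − consensus) at the selected k.

**Choice of k.** On hierarchically structured data every coarsening of
the true partition is itself perfectly stable, so "maximize a consensus
score" degenerates to the coarsest k. dmrscape instead selects the
largest k at which *every* cluster is robust — mean within-cluster
consensus ≥ 0.95, singletons never counting as robust — and falls back to
the within-minus-between consensus score when no k qualifies. Both
curves are reported in the assignment settings so the decision is
inspectable.

Subgroup-specific regions: one-way ANOVA across subgroup labels
(vectorized sums of squares; q-values by BH; keep q < 0.05). Patterns:
Ward clustering of significant DMRs on 1 − Pearson correlation, cut at 3;
clusters are labeled by cosine similarity of their centered mean subgroup
profile to three archetypes (monotone decreasing, group-3-specific,
monotone increasing); the cluster→archetype map must be one-to-one, else
an error asks for manual inspection. A k-means consensus variant
(repeated k-means on 80% sample subsets) serves validation-style probe
matrices, and labeling agreement between two clusterings is tested by
chi-square on the contingency table.

Top-variance selection uses floor(fraction · n) with ties broken by
genomic order. Feature bootstrap needs a reasonable feature count to be
stable; with only a handful of DMRs, cluster on the full matrix rather
than a 25% subset.

## Genomic context

* `basewise_overlap`: exact overlapping-base counts per interval and
  track label, via binary search on per-(chromosome, label) merged sorted
  interval arrays; half-open semantics; verified against per-base loops.
* `consensus_state`: majority vote over chromatin-state base counts; ties
  resolve to the lowest state number (deterministic; rare under real
  tilings).
* CGI shores: 2-kb island flanks minus any island bases (interval
  subtraction against the merged islands). 2 kb is the community
  convention.
* `window_profile`: per-base occupancy over windows centered on DMR
  midpoints or TSSs (strand-flipped when oriented); the per-position
  denominator is the number of anchors whose window covers that position
  (edge truncation); per-anchor rows are kept with a total-occupancy sort
  key for heat-strip export. The aggregate equals the row mean exactly.
* `transition_matrix`: for DMRs with reference-cell consensus state s,
  the row-normalized distribution of consensus states in each other cell
  line, optionally restricted to one reference state.
* Region features: DMR CpG density = Σ probe cpg_count / region length
  (the density the probe design affords); repeat content = LINE1/LTR
  bases in a 2-kb midpoint window; distance to nearest chromosome end
  = min(start, length − end) with a ≤ 5 Mb subtelomere flag.
* Enrichment: exact two-sided Fisher (point-probability rule) for binary
  features, Mann-Whitney / Kruskal-Wallis with tie correction for
  continuous ones, one-sided hypergeometric with BH for gene-set
  overlaps.

## Regulatory-factor occupancy

Binary DMR × (RF, cell line) matrix: 1 iff ≥ 1 bp overlap with any peak
(half-open: an abutting peak does not count). Co-binding:
`any_cell_same_cell` = all named RFs overlap in at least one common cell
line; `all_cells` = the set overlaps in every cell line (the former is
implied by the latter, property-tested). Pattern-wise enrichment is
one-vs-rest Fisher with direction from the odds ratio. Display ordering
clusters rows/columns by average linkage on Jaccard distance (all-zero
profile pairs get distance 0, i.e. identical).

## Methylation–expression integration

DMR–gene pairs: every gene whose TSS lies within 10 kb of the DMR
interval (distance 0 inside; the window is configurable and many-to-many
matches are kept). Correlations (Pearson default, Spearman available)
across shared samples; pairs with < 5 shared samples drop with a warning.
Significance uses one global two-sided |r| threshold: expression sample
labels are permuted `n_resamples` times, and the threshold is the
smallest observed |r| at which (mean null exceedance count)/(observed
exceedance count) ≤ the target FDR, walking candidates from the largest
observed |r| down and stopping at the first violation. This controls the
empirical FDR within 2× nominal on null data (tested) while keeping one
interpretable cohort-wide cutoff.

## HOX-locus switch

A locus is an ordered DMR list split by a boundary index into an anterior
(3′) and posterior (5′) block; both blocks must be non-empty (degenerate
loci are an error). Samples are clustered by k-means (k = 3, 50 restarts,
best inertia) on their locus-DMR methylation vectors. Clusters map to
labels by dichotomizing each cluster's anterior/posterior block mean
against the midpoint of the cluster block-mean range: posterior-high +
anterior-low → posterior_only; the reverse → anterior_only; both high →
pan; both low, or a many-to-one map, is an error listing the cluster
profiles. (A cohort-median rule was considered and rejected: at zero
noise the median coincides with the high level and strict comparison
misclassifies the pan cluster.)

Group contrasts: Welch t-tests per feature vs the posterior_only
reference, BH within each data level (methylation, expression); a pair is
called when both levels pass FDR < 0.01; starburst coordinates are signed
−log10(q) and reproduce the calls exactly. Survival: k-group logrank
(lifelines), no covariate adjustment. Pattern-level comparisons: Welch
t-tests of per-sample pattern mean methylation between groups, BH over
all (pattern, pair) tests.

## Clinical enrichment

One-vs-rest exact two-sided Fisher tests of subgroup membership against
each annotation level. Samples with NA in the tested annotation are
excluded from that test only; recorded-but-uninformative levels (e.g.
stage Tx) remain in the rest — this convention reproduces the packaged
cohort's printed p-values. The packaged `table1.tsv` fixture carries the
cohort's per-subgroup annotation counts; `sample_table_from_counts`
expands them into a per-sample table whose per-annotation margins are
exact (the joint structure across annotations is arbitrary, which is
immaterial for one-annotation-at-a-time tests).

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, on
a 3 × 30 Mb genome (small enough for brute-force oracles, large enough
for 5-Mb subtelomere logic):

* **Cohort**: subgroups of 18/21/24/35 tumors + 4 normals.
* **Regions**: 672/650/1375 DMRs for patterns 1–3 (scalable); lengths
  500 bp + Exp(280 bp) capped at 4610 bp (median ≈ 700 bp); probes 50 bp
  at 100 bp spacing, with a final probe flushed to the region end so the
  probe footprint spans the region; ≥ 4 probes per region guaranteed.
  Null background probes lie in 10-probe blocks so consecutive-probe runs
  exist under the null as on a real tiling design.
* **Scores**: pattern 1 subgroup means step down 1, 2/3, 1/3, 0 (normals
  high); pattern 2 is subgroup-3-only; pattern 3 steps up (normals low);
  plus iid Gaussian noise. Defaults effect_size = 1.0, noise_sd = 0.2
  (effect = 5 × noise). Equal spacing encodes the monotone trends without
  inventing magnitudes.
* **CpG counts**: Poisson per probe with means 1.4/4.8/2.2/1.1 for
  patterns 1/2/3/background, chosen so region-level densities land near
  0.014 / 0.048 / 0.022 / 0.011 CpG per bp.
* **Placement**: pattern 1 within 5 Mb of chromosome ends; patterns 2–3
  and background in the interior with ≥ 2 kb spacing; background
  annotation intervals (decoys) go beyond the used extent so they never
  touch planted regions.
* **Tracks**: pattern-2 DMRs sit inside CGIs, state-3 (poised promoter)
  segments, EZH2/CTCF/RAD21 peaks, and DHS peaks centered on their
  midpoints; a 30% subset carries REST peaks in all five RF cell lines;
  pattern-1 DMRs sit in state-13 filler with LINE1/LTR repeats at their
  midpoints; pattern-3 DMRs are CGI shores (island adjacent within
  2 kb) with POLR2A/TBP/TAF1 peaks flanking but not covering their
  midpoints; in the 8 alternate cell-line segmentations state 3 resolves
  to state 12. Per-track random peaks hit 0.3% of DMRs, giving a
  pattern-1 any-peak fraction near the observed ~25% across 90 tracks.
* **Expression**: for 30% of gene-matched pattern-3 DMRs (fractions
  configurable), gene expression = −z(DMR methylation) + noise sized for
  |r| ≈ 0.8; all other genes iid standard normal. Genes sit within 5 kb
  upstream of their DMR; 30% of pattern-1/2 DMRs also get genes.
* **Clinical/survival**: annotations drawn per subgroup from the packaged
  cohort frequencies, with an association-strength dial interpolating to
  the cohort marginal (0 = no association, calibration-tested);
  exponential survival with subgroup hazard ratios (default 1/1/2/3 over
  a 1/2000 per-day baseline) and exponential censoring at a 30% fraction.
* **HOX locus**: 7 anterior + 5 posterior DMRs; sample groups of 36/27/35
  (rescaled proportionally for other cohort sizes) with block means
  high/low per group label plus noise.
* **Raw-signal mode**: two-channel pseudo-intensities whose log-ratio is
  the score plus a per-array offset and a CpG-linear trend, to exercise
  the normalization steps against ground truth.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic sequence content, probe
cross-hybridization, copy-number structure, batch effects beyond the
simple array-bias model, correlated noise between neighboring probes,
cell-type admixture, and the long-tailed effect-size spectrum of real
tumors. Recovery rates on the synthetic cohort are upper bounds; the
value of the tests is calibration (null behavior, FDR control,
invariances) and direction, not absolute performance.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own working scale: caller calibration uses 100
(suite) / 50 (script) null matrices of 2,000 probes × 40 samples and
planted runs of 45 DMRs over 8,000 background probes (planted probes stay
well below the 90th-percentile variance mass, as on a real array);
subgroup/pattern/context/HOX recovery runs on the full default cohort
(2,697 DMRs, 98 tumors, B = 1000); expression calibration uses 20 null
cohorts of ~60 pattern-3 DMRs with 300–500 resamples; survival power uses
two groups of 36 vs 62 samples, HR 3, 20% censoring, 100 simulations
(the design is sized so the demonstration is adequately powered for its
≥ 90% rejection bar at true power ≈ 0.955).

## Known limitations

* The permutation null conditions on the genome-wide density deciles; if
  planted/true DMRs dominate a density stratum (tiny backgrounds), the
  null inflates and power drops — visible in scaled-down runs, mitigated
  by realistic background fractions.
* The empirical |r| threshold is global; pair-class-specific thresholds
  (e.g. by distance) are not implemented.
* Ward linkage is applied to correlation distances (standard practice,
  though Ward's variance interpretation strictly assumes Euclidean
  input).
* `bootstrap_hclust` stability is reported per sample as mean consensus
  with co-members; it is not a significance statement.
* The logrank test is unadjusted; no proportional-hazards diagnostics or
  multivariable models are provided.
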