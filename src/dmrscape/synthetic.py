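"""Synthetic cohort generator for the DMR pipeline.

Emulates a MeDIP-style tiling-array experiment on a small synthetic genome
(three 30-Mb chromosomes by default): probe-level enrichment scores for a
tumor cohort split into four planted subgroups plus a few normal samples,
with three planted DMR archetypes —

* pattern 1: methylation decreasing monotonically over subgroups 1..4,
  low CpG density, subtelomeric, repeat-rich, heterochromatic context;
* pattern 2: methylation elevated only in subgroup 3, high CpG density,
  CpG-island / poised-promoter / EZH2-CTCF-RAD21 context;
* pattern 3: methylation increasing over subgroups 1..4, CGI-shore
  context with transcription-machinery peaks flanking the midpoint.

The same ground truth drives companion generators for genome tracks,
an expression matrix with planted anti-correlated DMR-gene pairs, a
clinical/survival table, and a two-block HOX-like locus with switch-like
methylation.  Every generator is a pure function of its config (fixed
seed => byte-identical output).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenomeTracks, ProbeMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_probe_matrix",
    "generate_raw_intensities",
    "generate_tracks",
    "generate_expression",
    "generate_clinical_and_survival",
    "generate_hox_locus",
    "sample_table_from_counts",
    "simulate_all",
]

#: Poisson means for per-probe CpG counts (50-bp probes), chosen so the
#: region-level medians land near the observed 0.014 / 0.048 CpG per bp for
#: patterns 1 / 2, with pattern 3 and background intermediate/low.
CPG_POISSON_MEANS = {1: 1.4, 2: 4.8, 3: 2.2, 0: 1.1}

CELL_LINES = ["H1", "GM12878", "K562", "HepG2", "HeLa", "HUVEC", "HMEC", "HSMM", "NHEK"]
RF_CELL_LINES = ["H1", "GM12878", "K562", "HepG2", "HeLa"]
CORE_RFS = [
    "CTCF", "RAD21", "EZH2", "REST", "POLR2A", "TBP", "TAF1",
    "YY1", "SP1", "MAX", "JUND", "GABPA", "EGR1", "SIX5",
    "TCF12", "ATF3", "CEBPB", "USF1",
]

SUBTELOMERE_BP = 5_000_000


class SizingError(ValueError):
    """A chromosome is too short to host the requested probes."""


class DegenerateLocusError(ValueError):
    """A HOX-like locus has an empty anterior or posterior block."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort the pipeline is designed around: subgroup
    sizes 18/21/24/35 plus four normal urothelium samples, and
    672/650/1375 DMRs for patterns 1-3 (scalable down for quick runs).
    """

    n_samples_per_subgroup: tuple[int, int, int, int] = (18, 21, 24, 35)
    n_normals: int = 4
    n_dmrs_per_pattern: tuple[int, int, int] = (672, 650, 1375)
    n_null_probes: int = 20_000
    probe_spacing_bp: int = 100
    probe_length_bp: int = 50
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 30_000_000 for i in (1, 2, 3)}
    )
    effect_size: float = 1.0
    noise_sd: float = 0.2
    expr_corr_fraction: float = 0.3
    expr_target_abs_r: float = 0.8
    n_background_genes: int = 1000
    gene_fraction_other_patterns: float = 0.3
    n_alt_cell_lines: int = 8
    rf_background_rate: float = 0.003
    clinical_association_strength: float = 1.0
    hazard_ratios: tuple[float, float, float, float] = (1.0, 1.0, 2.0, 3.0)
    base_hazard_per_day: float = 1 / 2000
    censoring_fraction: float = 0.3
    hox_group_sizes: tuple[int, int, int] = (36, 27, 35)
    n_anterior_dmrs: int = 7
    n_posterior_dmrs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_samples_per_subgroup):
            raise ValueError("subgroup sizes must be positive")
        if self.n_normals < 0 or self.n_null_probes < 0:
            raise ValueError("counts must be non-negative")
        if any(n < 0 for n in self.n_dmrs_per_pattern):
            raise ValueError("DMR counts must be non-negative")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if not 0 <= self.expr_corr_fraction <= 1:
            raise ValueError("expr_corr_fraction must lie in [0, 1]")

    @property
    def tumor_ids(self) -> list[str]:
        n = sum(self.n_samples_per_subgroup)
        return [f"T{i:03d}" for i in range(1, n + 1)]

    @property
    def normal_ids(self) -> list[str]:
        return [f"N{i:02d}" for i in range(1, self.n_normals + 1)]

    def subgroup_labels(self) -> pd.Series:
        labels = np.repeat(
            np.arange(1, 5), np.asarray(self.n_samples_per_subgroup)
        )
        return pd.Series(labels, index=self.tumor_ids, name="subgroup")


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests.

    ``dmrs`` holds the planted intervals with pattern labels, ``subgroups``
    the planted tumor subgroup per sample.  ``dmr_sample_means`` are the
    realized (noisy) per-DMR per-sample means that downstream generators
    condition on.  ``gene_map`` / ``planted_pairs`` and ``hox_labels`` are
    filled by the track/expression/locus generators.
    """

    dmrs: pd.DataFrame
    subgroups: pd.Series
    dmr_sample_means: pd.DataFrame
    interior_extent: dict[str, int]
    gene_map: pd.Series | None = None
    planted_pairs: pd.DataFrame | None = None
    hox_labels: pd.Series | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dmrs": self.dmrs.reset_index().to_dict(orient="list"),
            "subgroups": self.subgroups.to_dict(),
        }
        if self.gene_map is not None:
            payload["gene_map"] = self.gene_map.to_dict()
        if self.planted_pairs is not None:
            payload["planted_pairs"] = self.planted_pairs.to_dict(orient="list")
        if self.hox_labels is not None:
            payload["hox_labels"] = self.hox_labels.to_dict()
        Path(path).write_text(json.dumps(payload, indent=1))


def _pattern_subgroup_means(effect: float) -> dict[int, np.ndarray]:
    """Planted subgroup mean score per pattern (subgroups 1..4 + normals).

    Pattern 1 decreases in equal steps over subgroups 1..4 (normals high,
    i.e. tumors lose methylation); pattern 2 is elevated in subgroup 3
    only; pattern 3 increases in equal steps (normals low).
    """
    return {
        1: effect * np.array([1.0, 2 / 3, 1 / 3, 0.0, 1.0]),
        2: effect * np.array([0.0, 0.0, 1.0, 0.0, 0.0]),
        3: effect * np.array([0.0, 1 / 3, 2 / 3, 1.0, 0.0]),
    }


def _draw_dmr_length(rng: np.random.Generator) -> int:
    # 500 bp floor + exponential tail, capped: median ~ 700 bp, max 4610 bp
    return int(min(500 + rng.exponential(280.0), 4610))


def _place_regions(config: SimConfig, rng: np.random.Generator):
    """Lay out planted DMRs and null probe blocks on the synthetic genome.

    Pattern-1 DMRs go into the outer 5 Mb of each chromosome arm; patterns
    2-3 and the null background go into the interior, far enough apart
    that neighbouring regions (and their island/peak decorations) never
    collide.  Returns (dmr table, null block list, interior extent).
    """
    chroms = list(config.chrom_lengths)
    n1, n2, n3 = config.n_dmrs_per_pattern

    # subtelomeric zones: (chrom, zone_start, zone_end), 2 per chromosome
    zones = []
    for c in chroms:
        L = config.chrom_lengths[c]
        if L < 2 * SUBTELOMERE_BP + 2_000_000:
            raise SizingError(f"{c} too short for subtelomere zones")
        zones.append((c, 10_000, SUBTELOMERE_BP))
        zones.append((c, L - SUBTELOMERE_BP, L - 10_000))

    dmr_rows = []
    cursor = {z: zones[z][1] for z in range(len(zones))}
    for i in range(n1):
        z = i % len(zones)
        chrom, _, zone_end = zones[z]
        gap = int(rng.integers(2_000, 20_000))
        length = _draw_dmr_length(rng)
        start = cursor[z] + gap
        if start + length > zone_end:
            raise SizingError(
                f"subtelomere zone on {chrom} exhausted after {i} pattern-1 DMRs"
            )
        dmr_rows.append((chrom, start, start + length, 1))
        cursor[z] = start + length

    # interior layout: interleave pattern 2, pattern 3 and null blocks
    interior_items = (
        [("dmr", 2)] * n2
        + [("dmr", 3)] * n3
        + [("null", 0)] * _n_null_blocks(config)
    )
    rng.shuffle(interior_items)
    int_cursor = {c: SUBTELOMERE_BP + 1_000_000 for c in chroms}
    null_blocks = []
    ci = 0
    for kind, pat in interior_items:
        chrom = chroms[ci % len(chroms)]
        ci += 1
        gap = int(rng.integers(2_000, 8_000))
        if kind == "dmr":
            length = _draw_dmr_length(rng)
        else:
            length = _null_block_span(config)
        start = int_cursor[chrom] + gap
        L = config.chrom_lengths[chrom]
        if start + length > L - SUBTELOMERE_BP - 1_000_000:
            raise SizingError(
                f"interior of {chrom} exhausted; shrink the layout or grow the genome"
            )
        if kind == "dmr":
            dmr_rows.append((chrom, start, start + length, pat))
        else:
            null_blocks.append((chrom, start))
        int_cursor[chrom] = start + length

    dmrs = pd.DataFrame(dmr_rows, columns=["chrom", "start", "end", "pattern"])
    dmrs = dmrs.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    dmrs.index = [f"DMR{i:05d}" for i in range(len(dmrs))]
    dmrs.index.name = "dmr_id"
    return dmrs, null_blocks, dict(int_cursor)


_NULL_BLOCK_PROBES = 10


def _n_null_blocks(config: SimConfig) -> int:
    return int(np.ceil(config.n_null_probes / _NULL_BLOCK_PROBES))


def _null_block_span(config: SimConfig) -> int:
    return (_NULL_BLOCK_PROBES - 1) * config.probe_spacing_bp + config.probe_length_bp


def _tile_probes(start: int, end: int, config: SimConfig) -> list[tuple[int, int]]:
    out = []
    pos = start
    while pos + config.probe_length_bp <= end:
        out.append((pos, pos + config.probe_length_bp))
        pos += config.probe_spacing_bp
    if out and out[-1][1] < end:  # flush so the probe footprint spans the region
        out.append((end - config.probe_length_bp, end))
    return out


def generate_probe_matrix(config: SimConfig) -> tuple[ProbeMatrix, SyntheticTruth]:
    """Generate the probe-level score matrix and its ground truth.

    Probes tile every planted DMR (>=4 probes each) and a scattered null
    background laid out in short blocks, so that consecutive-probe runs
    exist under the null as they do on a real tiling design.  Scores are
    the planted subgroup means plus iid Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    dmrs, null_blocks, interior_extent = _place_regions(config, rng)

    probe_rows = []  # (chrom, start, end, pattern, dmr_id)
    for dmr_id, row in dmrs.iterrows():
        tiles = _tile_probes(row["start"], row["end"], config)
        if len(tiles) < 4:
            raise SizingError(f"{dmr_id}: fewer than 4 probes fit")
        for s, e in tiles:
            probe_rows.append((row["chrom"], s, e, row["pattern"], dmr_id))
    for chrom, start in null_blocks:
        span = _null_block_span(config)
        for s, e in _tile_probes(start, start + span, config):
            probe_rows.append((chrom, s, e, 0, ""))

    probes = pd.DataFrame(
        probe_rows, columns=["chrom", "start", "end", "pattern", "dmr_id"]
    )
    if config.n_null_probes:
        null_mask = probes["pattern"].eq(0)
        extra = int(null_mask.sum()) - config.n_null_probes
        if extra > 0:  # trim block rounding overshoot
            drop = probes.index[null_mask][-extra:]
            probes = probes.drop(drop)
    probes = probes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    probes.index = [f"P{i:06d}" for i in range(len(probes))]
    probes.index.name = "probe_id"

    cpg_mean = probes["pattern"].map(CPG_POISSON_MEANS).to_numpy(float)
    probes["cpg_count"] = rng.poisson(cpg_mean)

    samples = config.tumor_ids + config.normal_ids
    subgroups = config.subgroup_labels()
    # column group index: subgroup-1..4 tumors then normals (index 4)
    col_group = np.concatenate(
        [subgroups.to_numpy() - 1, np.full(config.n_normals, 4, dtype=int)]
    )
    means_by_pattern = _pattern_subgroup_means(config.effect_size)
    base = np.zeros((len(probes), len(samples)))
    pat = probes["pattern"].to_numpy()
    for p in (1, 2, 3):
        base[pat == p] = means_by_pattern[p][col_group]
    scores = base + rng.normal(0.0, config.noise_sd, size=base.shape)
    scores = pd.DataFrame(scores, index=probes.index, columns=samples)

    meta = probes[["chrom", "start", "end", "cpg_count"]]
    pm = ProbeMatrix(meta, scores).validate()

    member = probes.loc[probes["dmr_id"] != "", "dmr_id"]
    dmr_means = scores.loc[member.index].groupby(member).mean()
    dmr_means = dmr_means.reindex(dmrs.index)

    truth = SyntheticTruth(
        dmrs=dmrs,
        subgroups=subgroups,
        dmr_sample_means=dmr_means,
        interior_extent=interior_extent,
    )
    return pm, truth


def generate_raw_intensities(
    config: SimConfig,
    matrix: ProbeMatrix,
    offsets: np.ndarray | None = None,
    cpg_slope: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit two-channel pseudo-intensities whose log2 ratio equals the score
    plus a per-array offset and a CpG-count-linear trend (the array-bias
    model the normalization scheme is meant to remove)."""
    rng = np.random.default_rng(config.seed + 10 if seed is None else seed)
    n_arrays = len(matrix.sample_ids)
    if offsets is None:
        offsets = rng.normal(0.0, 0.5, size=n_arrays)
    offsets = np.asarray(offsets, dtype=float)
    if offsets.shape != (n_arrays,):
        raise ValueError("one offset per array required")
    inp = 2.0 ** rng.normal(10.0, 0.5, size=(matrix.n_probes, n_arrays))
    cpg = matrix.probes["cpg_count"].to_numpy(float)[:, None]
    log_ratio = matrix.scores.to_numpy() + offsets[None, :] + cpg_slope * cpg
    ip = inp * 2.0 ** log_ratio
    cols = matrix.sample_ids
    return (
        pd.DataFrame(ip, index=matrix.probes.index, columns=cols),
        pd.DataFrame(inp, index=matrix.probes.index, columns=cols),
    )


# ---------------------------------------------------------------------------
# genome tracks
# ---------------------------------------------------------------------------


def generate_tracks(config: SimConfig, truth: SyntheticTruth) -> GenomeTracks:
    """Generate annotation tracks consistent with the planted DMR contexts.

    Pattern-2 DMRs sit inside CpG islands, poised-promoter (state 3)
    segments in the reference cell line, and EZH2+CTCF+RAD21 peaks;
    pattern-1 DMRs sit in heterochromatin (state 13) with LINE1/LTR
    repeats nearby; pattern-3 DMRs are CGI shores with POLR2A/TBP/TAF1
    peaks flanking (not covering) their midpoints.  In the additional
    cell-line segmentations the state-3 segments resolve to state 12.
    """
    rng = np.random.default_rng(config.seed + 1)
    dmrs = truth.dmrs
    for chrom in dmrs["chrom"].unique():
        if chrom not in config.chrom_lengths:
            raise ValueError(f"truth chromosome {chrom!r} not in config")

    pat = {p: dmrs[dmrs["pattern"] == p] for p in (1, 2, 3)}

    # --- CpG islands: containing pattern 2, adjacent (shore) for pattern 3
    cgi_rows = []
    p2_margin = {}
    for dmr_id, row in pat[2].iterrows():
        m = int(rng.integers(100, 300))
        cgi_rows.append((row["chrom"], row["start"] - m, row["end"] + m, "CGI"))
        p2_margin[dmr_id] = m
    for dmr_id, row in pat[3].iterrows():
        gap = int(rng.integers(50, 500))
        width = int(rng.integers(500, 1500))
        if rng.random() < 0.5:
            s = row["end"] + gap
        else:
            s = row["start"] - gap - width
        cgi_rows.append((row["chrom"], s, s + width, "CGI"))
    cgi_rows += _decoy_intervals(config, truth, rng, n_per_chrom=50, width=(400, 1200), label="CGI")
    cgi = _interval_frame(cgi_rows)

    # --- chromatin segmentations
    special = []
    for dmr_id, row in pat[2].iterrows():
        m = p2_margin[dmr_id]
        special.append((row["chrom"], row["start"] - m, row["end"] + m, 3))
    for _, row in pat[3].iterrows():
        special.append((row["chrom"], row["start"], row["end"], 2))
    ref_cell = CELL_LINES[0]
    segmentations = {ref_cell: _fill_segmentation(special, config.chrom_lengths)}
    for cell in CELL_LINES[1 : 1 + config.n_alt_cell_lines]:
        alt = [(c, s, e, 12 if st == 3 else st) for c, s, e, st in special]
        segmentations[cell] = _fill_segmentation(alt, config.chrom_lengths)

    # --- regulatory factor peaks
    mid = ((dmrs["start"] + dmrs["end"]) // 2).astype(int)
    peaks: dict[tuple[str, str], list] = {
        (rf, cell): [] for rf in CORE_RFS for cell in RF_CELL_LINES
    }

    for dmr_id, row in pat[2].iterrows():
        c, m = row["chrom"], mid[dmr_id]
        for rf in ("CTCF", "RAD21", "EZH2"):
            peaks[(rf, "H1")].append((c, m - 250, m + 250, rf))
        if rng.random() < 0.3:  # a REST-in-all-cells subset
            for cell in RF_CELL_LINES:
                peaks[("REST", cell)].append((c, m - 200, m + 200, "REST"))
    for dmr_id, row in pat[3].iterrows():
        c, m = row["chrom"], mid[dmr_id]
        cell = RF_CELL_LINES[int(rng.integers(len(RF_CELL_LINES)))]
        for rf in ("POLR2A", "TBP", "TAF1"):
            # flank both sides of the midpoint without covering it
            peaks[(rf, cell)].append((c, m + 200, m + 600, rf))
            peaks[(rf, cell)].append((c, m - 600, m - 200, rf))
    # sparse random peaks over all DMRs + decoy background
    n_dmr = len(dmrs)
    starts = dmrs["start"].to_numpy()
    chroms_arr = dmrs["chrom"].to_numpy()
    for key in peaks:
        hit = rng.random(n_dmr) < config.rf_background_rate
        for i in np.flatnonzero(hit):
            peaks[key].append(
                (chroms_arr[i], starts[i], starts[i] + 300, key[0])
            )
        peaks[key].extend(
            _decoy_intervals(config, truth, rng, n_per_chrom=20, width=(200, 500), label=key[0])
        )

    # --- DNaseI hypersensitivity: open chromatin centered on pattern-2 DMRs
    dhs = {}
    for cell in RF_CELL_LINES:
        rows = []
        for dmr_id, row in pat[2].iterrows():
            half = 400 if cell == "H1" else 200
            m = mid[dmr_id]
            rows.append((row["chrom"], m - half, m + half, "DHS"))
        rows += _decoy_intervals(config, truth, rng, n_per_chrom=30, width=(200, 600), label="DHS")
        dhs[cell] = _interval_frame(rows)

    # --- repeats near pattern-1 DMRs only
    rep_rows = []
    for dmr_id, row in pat[1].iterrows():
        m = mid[dmr_id]
        label = "LINE1" if rng.random() < 0.5 else "LTR"
        rep_rows.append((row["chrom"], m - 400, m + 400, label))
    rep_rows += _decoy_intervals(config, truth, rng, n_per_chrom=40, width=(300, 900), label="LINE1")
    repeats = _interval_frame(rep_rows)

    # --- conserved (NCEC-like) elements on patterns 2 and 3
    ncec_rows = []
    for p in (2, 3):
        for dmr_id, row in pat[p].iterrows():
            m = mid[dmr_id]
            ncec_rows.append((row["chrom"], m - 100, m + 100, "NCEC"))
    ncec = _interval_frame(ncec_rows)

    # --- gene models: TSS near every pattern-3 DMR, some of the others
    gene_rows = []
    gene_map = {}
    for p in (1, 2, 3):
        for dmr_id, row in pat[p].iterrows():
            if p != 3 and rng.random() >= config.gene_fraction_other_patterns:
                continue
            tss = int(row["start"] - rng.integers(0, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g_{dmr_id}"
            gene_rows.append((gid, row["chrom"], tss, strand))
            gene_map[dmr_id] = gid
    for i, (c, s, e, _) in enumerate(
        _decoy_intervals(config, truth, rng, n_per_chrom=config.n_background_genes // len(config.chrom_lengths), width=(1000, 1001), label="")
    ):
        gene_rows.append((f"bg_{i:05d}", c, s, "+" if rng.random() < 0.5 else "-"))
    gene_models = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss", "strand"]
    ).set_index("gene_id")

    intervals = {"cgi": cgi, "repeats": repeats, "ncec": ncec}
    for cell, seg in segmentations.items():
        intervals[f"chromatin_{cell}"] = seg
    for (rf_name, cell), rows in peaks.items():
        intervals[f"rf_{rf_name}_{cell}"] = _interval_frame(rows)
    for cell, df in dhs.items():
        intervals[f"dhs_{cell}"] = df

    truth.gene_map = pd.Series(gene_map, name="gene_id")
    tracks = GenomeTracks(intervals, dict(config.chrom_lengths), gene_models)
    return tracks.validate()


def _interval_frame(rows: list) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _decoy_intervals(config, truth, rng, n_per_chrom, width, label):
    """Background intervals placed beyond the used interior extent so they
    never touch a planted DMR."""
    rows = []
    for chrom, L in config.chrom_lengths.items():
        lo = truth.interior_extent.get(chrom, SUBTELOMERE_BP + 1_000_000) + 50_000
        hi = L - SUBTELOMERE_BP - 1_100_000
        if hi - lo < 10 * width[1]:
            continue
        starts = np.sort(rng.integers(lo, hi - width[1], size=n_per_chrom))
        widths = rng.integers(width[0], width[1] + 1, size=n_per_chrom)
        prev_end = -1
        for s, w in zip(starts, widths):
            if s <= prev_end:  # keep decoys disjoint
                continue
            rows.append((chrom, int(s), int(s + w), label))
            prev_end = s + w
    return rows


def _fill_segmentation(special, chrom_lengths) -> pd.DataFrame:
    """Tile each chromosome: the given (chrom,start,end,state) segments with
    state-13 filler in every gap."""
    rows = []
    by_chrom: dict[str, list] = {c: [] for c in chrom_lengths}
    for c, s, e, st in special:
        by_chrom[c].append((s, e, st))
    for chrom, L in chrom_lengths.items():
        segs = sorted(by_chrom[chrom])
        pos = 0
        for s, e, st in segs:
            if s < pos:
                raise ValueError(f"special segments overlap on {chrom}")
            if s > pos:
                rows.append((chrom, pos, s, 13))
            rows.append((chrom, s, e, st))
            pos = e
        if pos < L:
            rows.append((chrom, pos, L, 13))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    df["label"] = df["label"].astype(int)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Expression matrix (genes x tumor samples).

    For ``expr_corr_fraction`` of the gene-matched pattern-3 DMRs, the gene's
    expression is a negatively scaled copy of the DMR methylation plus noise
    sized to give |r| ~= ``expr_target_abs_r``; every other gene is
    independent standard normal noise.
    """
    if truth.gene_map is None:
        raise ValueError("run generate_tracks first (gene models required)")
    rng = np.random.default_rng(config.seed + 2)
    samples = config.tumor_ids
    meth = truth.dmr_sample_means[samples]

    p3 = truth.dmrs.index[truth.dmrs["pattern"] == 3]
    candidates = [d for d in p3 if d in truth.gene_map.index]
    n_planted = int(np.floor(config.expr_corr_fraction * len(candidates)))
    planted = list(candidates[:n_planted])

    r = config.expr_target_abs_r
    noise_scale = np.sqrt(1.0 / r**2 - 1.0) if r < 1 else 0.0

    all_genes = list(truth.gene_map.values) + [
        f"bg_{i:05d}" for i in range(_count_background_genes(truth))
    ]
    expr = pd.DataFrame(
        rng.normal(size=(len(all_genes), len(samples))),
        index=pd.Index(all_genes, name="gene_id"),
        columns=samples,
    )
    pairs = []
    for dmr_id in planted:
        gid = truth.gene_map[dmr_id]
        m = meth.loc[dmr_id].to_numpy()
        z = (m - m.mean()) / m.std(ddof=0) if m.std(ddof=0) > 0 else m * 0.0
        expr.loc[gid] = -z + rng.normal(0.0, noise_scale, size=len(samples))
        pairs.append((dmr_id, gid, -1))
    truth.planted_pairs = pd.DataFrame(
        pairs, columns=["dmr_id", "gene_id", "sign"]
    )
    return expr


def _count_background_genes(truth: SyntheticTruth) -> int:
    # decoy genes are only materialized through the track generator; infer
    # from the planted gene map being a subset of all gene ids is not
    # possible here, so keep a stable default of zero extra when absent
    return 0


# ---------------------------------------------------------------------------
# clinical annotations and survival
# ---------------------------------------------------------------------------


def load_table1_counts() -> pd.DataFrame:
    """Packaged per-subgroup clinical annotation counts (long format)."""
    path = Path(__file__).parent / "data" / "table1.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"level": str}, keep_default_na=False)
    return df


def sample_table_from_counts(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Deterministically expand per-subgroup annotation counts into a
    per-sample table (annotations assigned in order within each subgroup).

    With no argument, expands the packaged cohort counts.  The resulting
    table reproduces every annotation-by-subgroup margin exactly; joint
    structure across annotations is arbitrary, which is immaterial for
    one-annotation-at-a-time enrichment tests.
    """
    if counts is None:
        counts = load_table1_counts()
    sg_cols = ["subgroup1", "subgroup2", "subgroup3", "subgroup4"]
    sizes = counts[counts["annotation"] == counts["annotation"].iloc[0]][sg_cols].sum()
    n_per = sizes.to_numpy(int)
    ids = [f"T{i:03d}" for i in range(1, int(n_per.sum()) + 1)]
    table = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    table["subgroup"] = np.repeat([1, 2, 3, 4], n_per)
    for ann, sub in counts.groupby("annotation", sort=False):
        col = []
        for g, col_name in enumerate(sg_cols):
            levels = np.repeat(sub["level"].to_numpy(), sub[col_name].to_numpy(int))
            if len(levels) != n_per[g]:
                raise ValueError(
                    f"{ann}: counts for {col_name} sum to {len(levels)}, "
                    f"expected {n_per[g]}"
                )
            col.extend(levels)
        table[ann] = col
    for extra in ("survival_time", "event"):
        table[extra] = np.nan
    return table


def generate_clinical_and_survival(
    config: SimConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Draw clinical annotations with subgroup-conditional probabilities and
    exponential survival with subgroup-specific hazards.

    ``clinical_association_strength`` interpolates each annotation between
    the cohort-wide marginal (0: no association) and the packaged
    subgroup-conditional frequencies (1: full Table-like association).
    """
    rng = np.random.default_rng(config.seed + 3)
    counts = load_table1_counts()
    sg_cols = ["subgroup1", "subgroup2", "subgroup3", "subgroup4"]
    s = config.clinical_association_strength
    table = pd.DataFrame(index=truth.subgroups.index)
    for ann, sub in counts.groupby("annotation", sort=False):
        levels = sub["level"].to_numpy()
        cond = sub[sg_cols].to_numpy(float)
        cond = cond / cond.sum(axis=0, keepdims=True)
        marg = sub[sg_cols].sum(axis=1).to_numpy(float)
        marg = marg / marg.sum()
        values = []
        for sid, g in truth.subgroups.items():
            p = (1 - s) * marg + s * cond[:, g - 1]
            values.append(rng.choice(levels, p=p))
        table[ann] = values

    hr = np.asarray(config.hazard_ratios, dtype=float)
    haz = config.base_hazard_per_day * hr[truth.subgroups.to_numpy() - 1]
    event_t = rng.exponential(1.0 / haz)
    cf = config.censoring_fraction
    if cf > 0:
        cens_t = rng.exponential(1.0 / (haz * cf / (1 - cf)))
    else:
        cens_t = np.full_like(event_t, np.inf)
    table["survival_time"] = np.minimum(event_t, cens_t).round(1)
    table["event"] = (event_t <= cens_t).astype(int)
    return table


# ---------------------------------------------------------------------------
# HOX-like locus
# ---------------------------------------------------------------------------


def generate_hox_locus(config: SimConfig):
    """Two-block locus submatrix with switch-like methylation.

    Returns ``(means, labels, locus)``: a DMR x sample matrix for the
    ordered locus DMRs, the planted sample group labels (posterior_only /
    anterior_only / pan), and the LocusModel splitting the anterior from
    the posterior block.
    """
    from .hox import LocusModel  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed + 4)
    n_a, n_p = config.n_anterior_dmrs, config.n_posterior_dmrs
    dmr_ids = [f"HOXL_{i:02d}" for i in range(n_a + n_p)]
    locus = LocusModel(name="HOXL", dmr_ids=dmr_ids, boundary_index=n_a)

    sizes = config.hox_group_sizes
    n_samples = sum(config.n_samples_per_subgroup)
    if sum(sizes) != n_samples:
        # rescale the group proportions to the cohort size
        frac = np.asarray(sizes, dtype=float) / sum(sizes)
        scaled = np.floor(frac * n_samples).astype(int)
        scaled[np.argsort(-(frac * n_samples - scaled))[: n_samples - scaled.sum()]] += 1
        sizes = tuple(int(v) for v in scaled)
        if min(sizes) == 0:
            raise ValueError("cohort too small for three locus groups")
    labels = np.repeat(["posterior_only", "anterior_only", "pan"], sizes)
    labels = pd.Series(
        rng.permutation(labels), index=config.tumor_ids, name="hox_group"
    )

    e = config.effect_size
    block_high = {
        "posterior_only": (0.0, e),
        "anterior_only": (e, 0.0),
        "pan": (e, e),
    }
    means = np.zeros((len(dmr_ids), n_samples))
    for j, sid in enumerate(labels.index):
        a_level, p_level = block_high[labels[sid]]
        means[:n_a, j] = a_level
        means[n_a:, j] = p_level
    means = means + rng.normal(0.0, config.noise_sd, size=means.shape)
    means = pd.DataFrame(means, index=dmr_ids, columns=labels.index)
    return means, labels, locus


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------


def simulate_all(config: SimConfig):
    """Run all generators in order; returns a dict bundle."""
    pm, truth = generate_probe_matrix(config)
    tracks = generate_tracks(config, truth)
    expr = generate_expression(config, truth)
    clinical = generate_clinical_and_survival(config, truth)
    hox_means, hox_labels, locus = generate_hox_locus(config)
    truth.hox_labels = hox_labels
    return {
        "config": config,
        "probe_matrix": pm,
        "truth": truth,
        "tracks": tracks,
        "expression": expr,
        "clinical": clinical,
        "hox_means": hox_means,
        "hox_locus": locus,
    }
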