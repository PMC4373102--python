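"""Normalization of two-channel enrichment signals and variance-based DMR
calling with a CpG-density-matched permutation null.

The caller targets *between-tumor* differential methylation: a candidate
region is a run of consecutive high-variance probes, and its mean probe
variance is compared against random probe sets drawn from the same local
CpG-density decile, so that the intrinsic variance/CpG-density coupling of
enrichment scores does not masquerade as differential methylation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import ProbeMatrix

logger = logging.getLogger("dmrscape")


@dataclass
class NormalizationParams:
    """Settings for the five-step normalization scheme.

    Steps (individually switchable): (1) per-probe log2(IP/input);
    (2) per-array median centering; (3) across-array quantile
    normalization; (4) per-array removal of the CpG-count bias by
    subtracting a loess fit of score on probe CpG count; (5) running mean
    over ``smoothing_window_probes`` adjacent probes within ``gap_bp``.
    """

    smoothing_window_probes: int = 3
    cpg_bias_span: float = 0.3
    gap_bp: int = 500
    steps_enabled: tuple[bool, bool, bool, bool, bool] = (True,) * 5

    def __post_init__(self) -> None:
        if self.smoothing_window_probes < 1 or self.smoothing_window_probes % 2 == 0:
            raise ValueError("smoothing window must be a positive odd integer")
        if not 0 < self.cpg_bias_span <= 1:
            raise ValueError("cpg_bias_span must lie in (0, 1]")


@dataclass
class DmrCallParams:
    min_probes: int = 4
    min_length: int = 500
    max_gap_bp: int = 500
    variance_percentile: float = 90.0
    n_permutations: int = 1000
    cpg_density_bins: int = 10
    fdr_alpha: float = 0.05
    merge_distance_bp: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_probes, self.max_gap_bp, self.n_permutations,
               self.cpg_density_bins, self.min_length) <= 0:
            raise ValueError("all caller sizes must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")


@dataclass
class DMRSet:
    """Called regions plus per-sample mean scores.

    ``regions`` is indexed by dmr_id with columns chrom, start, end,
    n_probes, length, cpg_per_bp, empirical_p, fdr_q; ``probe_ids`` maps
    dmr_id to its member probes; ``means`` is the DMR x sample matrix of
    arithmetic means of member-probe scores.
    """

    regions: pd.DataFrame
    probe_ids: dict[str, list[str]]
    means: pd.DataFrame

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize(
    ip: pd.DataFrame,
    input_: pd.DataFrame,
    probes: pd.DataFrame,
    params: NormalizationParams | None = None,
) -> ProbeMatrix:
    """Apply the five-step normalization to two-channel intensities.

    ``ip`` and ``input_`` are probe x array intensity frames aligned with
    the ``probes`` coordinate table (sorted by chrom, start).
    """
    params = params or NormalizationParams()
    if not ip.index.equals(input_.index) or not ip.columns.equals(input_.columns):
        raise ValueError("IP and input frames must be aligned")
    s1, s2, s3, s4, s5 = params.steps_enabled

    if s1:
        bad = (ip.to_numpy() <= 0) | (input_.to_numpy() <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"nonpositive intensity for probe {ip.index[i]!r} "
                f"array {ip.columns[j]!r}"
            )
        scores = np.log2(ip.to_numpy() / input_.to_numpy())
    else:
        scores = ip.to_numpy(dtype=float).copy()

    if s2:
        scores = scores - np.median(scores, axis=0, keepdims=True)

    if s3:
        scores = _quantile_normalize(scores)

    if s4:
        cpg = probes["cpg_count"].to_numpy(float)
        for j in range(scores.shape[1]):
            fit = lowess(
                scores[:, j], cpg, frac=params.cpg_bias_span, return_sorted=False
            )
            scores[:, j] = scores[:, j] - np.nan_to_num(fit, nan=0.0)

    out = pd.DataFrame(scores, index=ip.index, columns=ip.columns)
    if s5:
        out = _smooth_runs(out, probes, params)
    return ProbeMatrix(probes.copy(), out).validate()


def _quantile_normalize(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, axis=0, kind="stable")
    sorted_x = np.take_along_axis(x, order, axis=0)
    ref = sorted_x.mean(axis=1)  # mean of each order statistic across arrays
    ranks = np.argsort(order, axis=0, kind="stable")
    return ref[ranks]


def _smooth_runs(
    scores: pd.DataFrame, probes: pd.DataFrame, params: NormalizationParams
) -> pd.DataFrame:
    run_id = probe_runs(probes, params.gap_bp)
    w = params.smoothing_window_probes
    pieces = []
    for _, idx in scores.groupby(run_id, sort=False).groups.items():
        block = scores.loc[idx]
        if len(block) < w:
            warnings.warn(
                f"run of {len(block)} probes shorter than smoothing window {w}; "
                "window truncated",
                stacklevel=2,
            )
        pieces.append(block.rolling(w, center=True, min_periods=1).mean())
    return pd.concat(pieces).loc[scores.index]


def probe_runs(probes: pd.DataFrame, gap_bp: int) -> np.ndarray:
    """Label maximal runs of adjacent probes: same chromosome, inter-probe
    gap (next start minus previous end) at most ``gap_bp``."""
    chrom = probes["chrom"].to_numpy()
    start = probes["start"].to_numpy()
    end = probes["end"].to_numpy()
    new_run = np.ones(len(probes), dtype=bool)
    if len(probes) > 1:
        same = chrom[1:] == chrom[:-1]
        close = (start[1:] - end[:-1]) <= gap_bp
        new_run[1:] = ~(same & close)
    return np.cumsum(new_run)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------


def call_dmrs(matrix: ProbeMatrix, params: DmrCallParams | None = None) -> DMRSet:
    """Call between-tumor DMRs from a normalized probe matrix.

    Candidates are maximal runs of >= ``min_probes`` consecutive probes
    (gap <= ``max_gap_bp``) whose across-sample variance exceeds the
    ``variance_percentile`` of all probe variances (ties included), with
    span >= ``min_length``.  Each candidate's mean probe variance is
    compared to ``n_permutations`` same-size random probe sets drawn from
    the candidate's CpG-density decile; empirical p-values (add-one
    estimator) are BH-corrected, survivors closer than
    ``merge_distance_bp`` merged, and per-sample means attached.
    """
    params = params or DmrCallParams()
    if len(matrix.sample_ids) < 8:
        raise ValueError("at least 8 samples required for between-tumor calling")
    probes = matrix.probes
    x = matrix.scores.to_numpy()
    variances = x.var(axis=1, ddof=1)
    if np.allclose(variances, 0):
        return _empty_dmrset(matrix)

    threshold = np.percentile(variances, params.variance_percentile)
    above = variances >= threshold

    candidates = _candidate_runs(probes, above, params)
    if not candidates:
        return _empty_dmrset(matrix)

    density = probes["cpg_count"].to_numpy(float) / (
        probes["end"].to_numpy() - probes["start"].to_numpy()
    )
    bins = _density_bins(density, params.cpg_density_bins)

    rng = np.random.default_rng(params.seed)
    bin_vars = {b: variances[bins == b] for b in np.unique(bins)}
    pvals = np.empty(len(candidates))
    stats = np.empty(len(candidates))
    for i, idx in enumerate(candidates):
        obs = variances[idx].mean()
        stats[i] = obs
        cand_bins = bins[idx]
        b = int(np.bincount(cand_bins).argmax())  # dominant bin of the run
        pool = _pool_for_bin(bin_vars, b, len(idx))
        draws = rng.choice(pool, size=(params.n_permutations, len(idx)))
        null = draws.mean(axis=1)
        pvals[i] = (1 + np.count_nonzero(null >= obs)) / (1 + params.n_permutations)

    reject, qvals, *_ = multipletests(pvals, alpha=params.fdr_alpha, method="fdr_bh")
    keep = np.flatnonzero(qvals <= params.fdr_alpha)
    if keep.size == 0:
        return _empty_dmrset(matrix)

    kept = [(candidates[i], pvals[i], qvals[i]) for i in keep]
    merged = _merge_regions(kept, probes, params.merge_distance_bp)

    rows, probe_map = [], {}
    for n, (idx, p, q) in enumerate(merged):
        sub = probes.iloc[idx]
        chrom = sub["chrom"].iloc[0]
        start, end = int(sub["start"].min()), int(sub["end"].max())
        dmr_id = f"DMR{n:05d}"
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_probes": len(idx),
                "length": end - start,
                "cpg_per_bp": sub["cpg_count"].sum() / (end - start),
                "empirical_p": p,
                "fdr_q": q,
            }
        )
        probe_map[dmr_id] = list(sub.index)
    regions = pd.DataFrame(rows, index=pd.Index(probe_map.keys(), name="dmr_id"))
    means = summarize_dmrs(matrix, probe_map)
    return DMRSet(regions, probe_map, means)


def _empty_dmrset(matrix: ProbeMatrix) -> DMRSet:
    regions = pd.DataFrame(
        columns=[
            "chrom", "start", "end", "n_probes", "length",
            "cpg_per_bp", "empirical_p", "fdr_q",
        ],
        index=pd.Index([], name="dmr_id"),
    )
    means = pd.DataFrame(columns=matrix.sample_ids)
    return DMRSet(regions, {}, means)


def _candidate_runs(
    probes: pd.DataFrame, above: np.ndarray, params: DmrCallParams
) -> list[np.ndarray]:
    """Maximal runs of consecutive above-threshold probes satisfying the
    probe-count, gap and span constraints."""
    runs = probe_runs(probes, params.max_gap_bp)
    # break runs additionally at below-threshold probes
    group = np.cumsum(
        np.concatenate([[True], (runs[1:] != runs[:-1]) | ~above[1:] | ~above[:-1]])
    )
    start = probes["start"].to_numpy()
    end = probes["end"].to_numpy()
    out = []
    order = np.arange(len(probes))
    for _, idx in pd.Series(order).groupby(group):
        idx = idx.to_numpy()
        if not above[idx[0]]:
            continue
        if len(idx) < params.min_probes:
            continue
        span = end[idx[-1]] - start[idx[0]]
        if span < params.min_length:
            continue
        out.append(idx)
    return out


def _density_bins(density: np.ndarray, n_bins: int) -> np.ndarray:
    """Decile (or coarser, under ties) bins of local CpG density over all
    probes."""
    try:
        binned = pd.qcut(density, n_bins, labels=False, duplicates="drop")
    except ValueError:
        binned = np.zeros(len(density), dtype=int)
    return np.asarray(binned, dtype=int)


def _pool_for_bin(bin_vars: dict, b: int, m: int) -> np.ndarray:
    """Variance pool for a density bin, widened to adjacent bins when too
    small to support same-size resampling."""
    pool = bin_vars.get(b, np.empty(0))
    radius = 1
    max_bin = max(bin_vars)
    while len(pool) < max(2 * m, 20) and radius <= max_bin + 1:
        neighbours = [bin_vars.get(b - radius), bin_vars.get(b + radius)]
        pool = np.concatenate([pool] + [n for n in neighbours if n is not None])
        if radius == 1 and len(pool) >= max(2 * m, 20):
            warnings.warn(f"sparse CpG-density bin {b}; widened to adjacent bins",
                          stacklevel=2)
        radius += 1
    return pool


def _merge_regions(kept, probes: pd.DataFrame, merge_distance_bp: int):
    """Merge surviving candidate runs closer than ``merge_distance_bp`` on
    the same chromosome; merged regions keep the smallest member p/q."""
    chrom = probes["chrom"].to_numpy()
    start = probes["start"].to_numpy()
    end = probes["end"].to_numpy()
    kept = sorted(kept, key=lambda t: (chrom[t[0][0]], start[t[0][0]]))
    merged = []
    for idx, p, q in kept:
        if merged:
            pidx, pp, pq = merged[-1]
            same = chrom[pidx[-1]] == chrom[idx[0]]
            if same and start[idx[0]] - end[pidx[-1]] < merge_distance_bp:
                merged[-1] = (
                    np.concatenate([pidx, idx]),
                    min(pp, p),
                    min(pq, q),
                )
                continue
        merged.append((idx, p, q))
    return merged


def summarize_dmrs(
    matrix: ProbeMatrix, probe_ids: dict[str, list[str]] | DMRSet
) -> pd.DataFrame:
    """Arithmetic mean of member-probe scores per DMR and sample.

    Rows follow the given DMR order (genomic order when produced by
    :func:`call_dmrs`).
    """
    if isinstance(probe_ids, DMRSet):
        probe_ids = probe_ids.probe_ids
    rows = []
    for dmr_id, pids in probe_ids.items():
        missing = [p for p in pids if p not in matrix.scores.index]
        if missing:
            raise KeyError(f"DMR {dmr_id!r}: probes missing from matrix: {missing[:3]}")
        rows.append(matrix.scores.loc[pids].mean(axis=0).rename(dmr_id))
    if not rows:
        return pd.DataFrame(columns=matrix.sample_ids)
    out = pd.DataFrame(rows)
    out.index.name = "dmr_id"
    return out
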