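"""Genomic-context annotation of DMRs.

Basewise track overlaps, majority-vote consensus chromatin states,
CGI/shore flags, repeat and subtelomere features, midpoint/TSS-centered
aggregation profiles, chromatin-state transition matrices across cell
lines, and enrichment statistics (exact Fisher for flags, rank tests for
continuous features, hypergeometric for gene sets).

The overlap engine works on sorted interval arrays with binary search;
half-open [start, end) semantics throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import GenomeTracks

logger = logging.getLogger("dmrscape")

SUBTELOMERE_BP = 5_000_000
SHORE_FLANK_BP = 2_000


@dataclass
class AggregationProfile:
    """Per-base occupancy around a set of anchors.

    ``frequency`` has one value per window position (covering-anchor
    denominator at chromosome edges); ``rows`` holds the per-anchor
    basewise occupancy (uint8) for heat-strip export, with ``sort_key``
    the total occupied bases per anchor.
    """

    window_bp: int
    frequency: np.ndarray
    n_anchors: int
    rows: pd.DataFrame
    sort_key: pd.Series

    def sorted_rows(self) -> pd.DataFrame:
        return self.rows.loc[self.sort_key.sort_values(ascending=False).index]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge overlapping/adjacent sorted intervals."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s), np.asarray(out_e)


class _ChromIndex:
    """Per-(chrom, label) merged sorted intervals for fast overlap sums."""

    def __init__(self, track: pd.DataFrame, by_label: bool = True):
        self.data: dict = {}
        keys = ["chrom", "label"] if by_label and "label" in track.columns else ["chrom"]
        for key, sub in track.groupby(keys, sort=False):
            if len(keys) == 1:
                key = (key[0] if isinstance(key, tuple) else key, None)
            s, e = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
            self.data[key] = (s, e, np.concatenate([[0], np.cumsum(e - s)]))

    def labels(self, chrom: str) -> list:
        return [lb for (c, lb) in self.data if c == chrom]

    def overlap_bases(self, chrom: str, label, qs: int, qe: int) -> int:
        key = (chrom, label)
        if key not in self.data:
            return 0
        s, e, cum = self.data[key]
        lo = np.searchsorted(e, qs, side="right")
        hi = np.searchsorted(s, qe, side="left")
        if hi <= lo:
            return 0
        total = int(cum[hi] - cum[lo])
        total -= max(0, qs - s[lo])
        total -= max(0, e[hi - 1] - qe)
        return total


def basewise_overlap(
    intervals: pd.DataFrame, track: pd.DataFrame
) -> pd.DataFrame:
    """Exact overlapping-base counts per interval and track label.

    ``intervals`` needs chrom/start/end (index preserved); ``track`` needs
    chrom/start/end and optionally label (labelless tracks count under a
    single ``''`` column).  Unknown chromosomes count 0 with a warning.
    """
    work = track if "label" in track.columns else track.assign(label="")
    index = _ChromIndex(work)
    labels = sorted(work["label"].unique(), key=str)
    known = set(work["chrom"].unique())
    out = np.zeros((len(intervals), len(labels)), dtype=np.int64)
    col = {lb: j for j, lb in enumerate(labels)}
    for i, (chrom, qs, qe) in enumerate(
        zip(intervals["chrom"], intervals["start"], intervals["end"])
    ):
        if chrom not in known:
            logger.warning("chromosome %s absent from track; counted as 0", chrom)
            continue
        for lb in index.labels(chrom):
            out[i, col[lb]] = index.overlap_bases(chrom, lb, qs, qe)
    return pd.DataFrame(out, index=intervals.index, columns=labels)


def consensus_state(state_base_counts: pd.DataFrame | pd.Series):
    """Majority-vote chromatin state; ties resolve to the lowest state
    number."""
    if isinstance(state_base_counts, pd.Series):
        counts = state_base_counts
        best = counts.max()
        return int(min(int(s) for s, v in counts.items() if v == best))
    cols = np.array([int(c) for c in state_base_counts.columns])
    order = np.argsort(cols, kind="stable")
    x = state_base_counts.to_numpy()[:, order]
    winners = cols[order][np.argmax(x, axis=1)]  # argmax takes first (lowest) tie
    return pd.Series(winners, index=state_base_counts.index, name="consensus_state")


def chrom_end_features(
    dmrs: pd.DataFrame, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Distance to the nearest chromosome end and subtelomeric flag
    (<= 5 Mb)."""
    lengths = dmrs["chrom"].map(chrom_lengths)
    if lengths.isna().any():
        missing = dmrs.loc[lengths.isna(), "chrom"].unique()
        raise KeyError(f"chromosome length unknown for {list(missing)}")
    dist = np.minimum(dmrs["start"], lengths - dmrs["end"]).astype(int)
    return pd.DataFrame(
        {"dist_to_chrom_end": dist, "subtelomeric": dist <= SUBTELOMERE_BP},
        index=dmrs.index,
    )


def repeat_content(
    dmrs: pd.DataFrame,
    repeat_track: pd.DataFrame,
    window: int = 2000,
    labels: tuple[str, ...] = ("LINE1", "LTR"),
) -> pd.DataFrame:
    """LINE1/LTR bases within a window centered on each DMR midpoint."""
    sub = repeat_track[repeat_track["label"].isin(labels)]
    mid = (dmrs["start"] + dmrs["end"]) // 2
    win = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": np.maximum(mid - window // 2, 0),
            "end": mid + window // 2,
        },
        index=dmrs.index,
    )
    counts = basewise_overlap(win, sub.drop(columns="label"))
    bases = counts.sum(axis=1).astype(int)
    return pd.DataFrame(
        {"repeat_bases": bases, "repeat_present": bases > 0}, index=dmrs.index
    )


def shore_track(cgi_track: pd.DataFrame, flank_bp: int = SHORE_FLANK_BP) -> pd.DataFrame:
    """CGI shores: ``flank_bp`` flanks of each island minus any island bases."""
    rows = []
    for chrom, sub in cgi_track.groupby("chrom", sort=False):
        isl_s, isl_e = _merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
        flanks = []
        for s, e in zip(isl_s, isl_e):
            flanks.append((max(s - flank_bp, 0), s))
            flanks.append((e, e + flank_bp))
        fs, fe = _merge_intervals(
            np.array([f[0] for f in flanks]), np.array([f[1] for f in flanks])
        )
        for s, e in zip(fs, fe):
            # subtract island bases from the flank interval
            pos = s
            for js, je in zip(isl_s, isl_e):
                if je <= pos or js >= e:
                    continue
                if js > pos:
                    rows.append((chrom, pos, js, "shore"))
                pos = max(pos, je)
            if pos < e:
                rows.append((chrom, pos, e, "shore"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def cgi_features(dmrs: pd.DataFrame, cgi_track: pd.DataFrame) -> pd.DataFrame:
    """CGI overlap and shore overlap (2-kb flanks, islands excluded)."""
    cgi_bases = basewise_overlap(dmrs, cgi_track).sum(axis=1)
    shores = shore_track(cgi_track)
    shore_bases = basewise_overlap(dmrs, shores).sum(axis=1)
    return pd.DataFrame(
        {"cgi_overlap": cgi_bases > 0, "shore_overlap": shore_bases > 0},
        index=dmrs.index,
    )


def window_profile(
    anchors: pd.DataFrame,
    track: pd.DataFrame,
    window_bp: int,
    chrom_lengths: dict[str, int] | None = None,
    oriented: bool = False,
) -> AggregationProfile:
    """Per-base occupancy frequency across windows centered on anchors.

    ``anchors`` rows carry chrom plus either start/end (midpoint anchors)
    or tss (+ strand when ``oriented``).  Windows are truncated at
    chromosome edges; the frequency denominator at each position is the
    number of anchors whose window covers it.
    """
    if window_bp <= 0 or window_bp % 2:
        raise ValueError("window_bp must be a positive even integer")
    half = window_bp // 2
    if "tss" in anchors.columns:
        centers = anchors["tss"].to_numpy(int)
    else:
        centers = ((anchors["start"] + anchors["end"]) // 2).to_numpy(int)
    strands = (
        anchors["strand"].to_numpy()
        if oriented and "strand" in anchors.columns
        else np.array(["+"] * len(anchors))
    )
    index = _ChromIndex(track.assign(label=""), by_label=False)

    occ = np.zeros((len(anchors), window_bp), dtype=np.uint8)
    covered = np.zeros((len(anchors), window_bp), dtype=bool)
    for i, (chrom, c, strand) in enumerate(
        zip(anchors["chrom"], centers, strands)
    ):
        ws, we = c - half, c + half
        lo = max(ws, 0)
        hi = we if chrom_lengths is None else min(we, chrom_lengths.get(chrom, we))
        if hi <= lo:
            continue
        covered[i, lo - ws : hi - ws] = True
        key = (chrom, None)
        if key not in index.data:
            continue
        s, e, _ = index.data[key]
        a = np.searchsorted(e, lo, side="right")
        b = np.searchsorted(s, hi, side="left")
        for j in range(a, b):
            left = max(s[j], lo) - ws
            right = min(e[j], hi) - ws
            occ[i, left:right] = 1
        if strand == "-":
            occ[i] = occ[i][::-1]
            covered[i] = covered[i][::-1]
    denom = covered.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, occ.sum(axis=0) / np.maximum(denom, 1), 0.0)
    rows = pd.DataFrame(occ, index=anchors.index,
                        columns=np.arange(-half, half))
    sort_key = rows.sum(axis=1).rename("occupied_bases")
    return AggregationProfile(window_bp, freq, len(anchors), rows, sort_key)


def transition_matrix(
    consensus_states: pd.DataFrame,
    reference: str,
    restrict_state: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Reference-state by alternate-state co-occurrence frequencies.

    ``consensus_states``: DMR x cell-line consensus chromatin states.
    Returns one row-normalized matrix per non-reference cell line; with
    ``restrict_state`` only DMRs in that reference state are counted
    (single-row matrices).
    """
    if reference not in consensus_states.columns:
        raise KeyError(f"reference cell line {reference!r} absent")
    ref = consensus_states[reference]
    out = {}
    for cell in consensus_states.columns:
        if cell == reference:
            continue
        sub = consensus_states[[cell]].assign(ref=ref)
        if restrict_state is not None:
            sub = sub[sub["ref"] == restrict_state]
        table = pd.crosstab(sub["ref"], sub[cell])
        table = table.div(table.sum(axis=1), axis=0)
        out[cell] = table
    return out


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------


def category_enrichment(
    feature: pd.Series, group: pd.Series
) -> pd.DataFrame:
    """One-vs-rest enrichment of a per-DMR feature across group labels.

    Boolean features get an exact two-sided Fisher test with odds ratio;
    numeric features get Mann-Whitney (one-vs-rest) and a global
    Kruskal-Wallis row when there are 3+ groups.
    """
    feature, group = feature.align(group, join="inner")
    rows = []
    if feature.dtype == bool or set(feature.unique()) <= {0, 1, True, False}:
        f = feature.astype(bool)
        for g in sorted(group.unique()):
            ing = group == g
            a = int((f & ing).sum())
            b = int((~f & ing).sum())
            c = int((f & ~ing).sum())
            d = int((~f & ~ing).sum())
            odds, p = sps.fisher_exact([[a, b], [c, d]])
            rows.append(
                {"group": g, "test": "fisher", "statistic": odds, "p": p,
                 "table": ((a, b), (c, d)),
                 "direction": "enriched" if odds > 1 else "depleted"}
            )
    else:
        x = feature.astype(float)
        for g in sorted(group.unique()):
            ing = (group == g).to_numpy()
            u, p = sps.mannwhitneyu(x[ing], x[~ing], alternative="two-sided")
            rows.append({"group": g, "test": "mannwhitney", "statistic": u, "p": p,
                         "table": None,
                         "direction": "higher" if x[ing].median() > x[~ing].median()
                         else "lower"})
        if group.nunique() >= 3:
            samples = [x[(group == g).to_numpy()] for g in sorted(group.unique())]
            h, p = sps.kruskal(*samples)
            rows.append({"group": "all", "test": "kruskal", "statistic": h, "p": p,
                         "table": None, "direction": ""})
    return pd.DataFrame(rows)


def geneset_overlap(
    genes: set | list,
    signatures: dict[str, set],
    universe: set | list,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list in signature
    sets, BH-corrected across signatures."""
    universe = set(universe)
    genes = set(genes) & universe
    rows = []
    for name, sig in signatures.items():
        sig = set(sig) & universe
        k = len(genes & sig)
        p = sps.hypergeom.sf(k - 1, len(universe), len(sig), len(genes))
        rows.append({"signature": name, "overlap": k, "set_size": len(sig), "p": p})
    out = pd.DataFrame(rows).set_index("signature")
    if len(out):
        _, out["q"], *_ = multipletests(out["p"], method="fdr_bh")
    return out
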