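"""Regulatory-factor occupancy at DMRs.

Builds the binary DMR x (RF, cell line) peak-overlap matrix, evaluates
co-binding definitions (same-cell and all-cells), tests pattern-wise
enrichment, and orders the matrix for heatmap display.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .context import _ChromIndex


def build_rf_matrix(
    dmrs: pd.DataFrame, peak_tracks: dict[tuple[str, str], pd.DataFrame]
) -> pd.DataFrame:
    """Binary matrix of DMR / ChIP-seq peak overlaps.

    ``peak_tracks`` maps (RF name, cell line) to a peak interval frame.
    An entry is 1 iff at least one base overlaps (half-open semantics: a
    peak abutting the DMR end does not count).  Attrs carry the fraction
    of DMRs with any overlapping peak.
    """
    cols = pd.MultiIndex.from_tuples(sorted(peak_tracks), names=["rf", "cell"])
    out = np.zeros((len(dmrs), len(cols)), dtype=np.int8)
    for j, key in enumerate(cols):
        track = peak_tracks[key]
        if track is None:
            raise ValueError(f"missing peak track for {key}")
        index = _ChromIndex(track.assign(label=""), by_label=False)
        for i, (chrom, s, e) in enumerate(
            zip(dmrs["chrom"], dmrs["start"], dmrs["end"])
        ):
            out[i, j] = index.overlap_bases(chrom, None, int(s), int(e)) > 0
    mat = pd.DataFrame(out, index=dmrs.index, columns=cols)
    mat.attrs["fraction_any_peak"] = float((mat.sum(axis=1) > 0).mean())
    return mat


def fraction_with_peak(rf_matrix: pd.DataFrame, patterns: pd.Series | None = None):
    """Fraction of DMRs with >=1 overlapping peak, overall and per pattern."""
    any_peak = rf_matrix.sum(axis=1) > 0
    out = {"all": float(any_peak.mean())}
    if patterns is not None:
        pat = patterns.loc[rf_matrix.index]
        for p in sorted(pat.unique()):
            out[p] = float(any_peak[(pat == p).to_numpy()].mean())
    return out


def cobinding(
    rf_matrix: pd.DataFrame, rfs: list[str], mode: str = "any_cell_same_cell"
) -> pd.Series:
    """Per-DMR co-binding flag for a set of RFs.

    ``any_cell_same_cell``: all named RFs overlap in at least one common
    cell line.  ``all_cells``: the full RF set overlaps in every cell
    line.
    """
    cells = rf_matrix.columns.get_level_values("cell").unique()
    missing = [rf for rf in rfs if rf not in rf_matrix.columns.get_level_values("rf")]
    if missing:
        raise KeyError(f"RF(s) {missing} absent from matrix")
    per_cell = []
    for cell in cells:
        sub = rf_matrix.loc[:, [(rf, cell) for rf in rfs]]
        per_cell.append(sub.all(axis=1))
    stacked = pd.concat(per_cell, axis=1)
    if mode == "any_cell_same_cell":
        return stacked.any(axis=1).rename("cobinding")
    if mode == "all_cells":
        return stacked.all(axis=1).rename("cobinding")
    raise ValueError(f"unknown mode {mode!r}")


def pattern_rf_enrichment(flags: pd.Series, patterns: pd.Series) -> pd.DataFrame:
    """One-vs-rest Fisher test of a binding flag per methylation pattern,
    with enrichment/depletion direction from the odds ratio."""
    flags, patterns = flags.align(patterns, join="inner")
    rows = []
    for p in sorted(patterns.unique()):
        ing = (patterns == p).to_numpy()
        f = flags.to_numpy(bool)
        table = [
            [int((f & ing).sum()), int((~f & ing).sum())],
            [int((f & ~ing).sum()), int((~f & ~ing).sum())],
        ]
        odds, pval = sps.fisher_exact(table)
        rows.append(
            {"pattern": p, "odds_ratio": odds, "p": pval,
             "direction": "enriched" if odds > 1 else
             ("depleted" if odds < 1 else "none"),
             "table": tuple(map(tuple, table))}
        )
    return pd.DataFrame(rows).set_index("pattern")


def cluster_rf_matrix(rf_matrix: pd.DataFrame):
    """Hierarchical ordering of DMR rows and (RF, cell) columns.

    Jaccard distance on the binary profiles, average linkage; leaf order
    is deterministic (scipy's left-to-right ordering, input order on
    ties).  Returns (row_order, column_order) as index objects.
    """
    x = rf_matrix.to_numpy(bool)
    row_order = rf_matrix.index[_leaf_order(x)]
    col_order = rf_matrix.columns[_leaf_order(x.T)]
    return row_order, col_order


def _leaf_order(x: np.ndarray) -> np.ndarray:
    if x.shape[0] < 3:
        return np.arange(x.shape[0])
    with np.errstate(invalid="ignore"):
        d = pdist(x, metric="jaccard")
    d = np.nan_to_num(d, nan=0.0)  # all-zero profile pairs: identical
    z = linkage(d, method="average")
    return leaves_list(z)
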