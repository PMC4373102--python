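"""Clinical-annotation enrichment and validation-workflow statistics.

One-vs-rest Fisher tests of subgroup against clinical/molecular
annotations (with the packaged cohort count fixture), probe-variability
comparison for DMR-overlap validation, tumor-normal methylation deltas per
pattern, and branch-wise enrichment for probe dendrograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .context import _ChromIndex
from .synthetic import load_table1_counts, sample_table_from_counts  # noqa: F401

__all__ = [
    "EnrichmentReport",
    "one_vs_rest_fisher",
    "enrichment_scan",
    "compare_probe_sd",
    "tumor_normal_delta",
    "branch_enrichment",
    "load_table1_counts",
    "sample_table_from_counts",
]


@dataclass
class EnrichmentReport:
    subgroup: object
    annotation: str
    level: str
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float
    p: float
    direction: str

    def __post_init__(self) -> None:
        (a, b), (c, d) = self.table
        if min(a, b, c, d) < 0:
            raise ValueError("negative count")


def one_vs_rest_fisher(
    sample_table: pd.DataFrame,
    subgroups: pd.Series,
    annotation: str,
    level: str,
    subgroup,
) -> EnrichmentReport:
    """Exact two-sided Fisher test of one subgroup vs the rest for one
    annotation level.

    Samples whose annotation is NA are excluded from this test only; all
    other levels (including 'unknown-but-recorded' categories such as
    stage Tx) stay in the rest.
    """
    ann = sample_table[annotation].astype(str)
    keep = ann != "NA"
    ann = ann[keep]
    sg = subgroups.loc[ann.index]
    in_sub = sg == subgroup
    if not in_sub.any():
        raise ValueError(f"subgroup {subgroup!r} empty after NA exclusion")
    has = ann == str(level)
    a = int((in_sub & has).sum())
    b = int((in_sub & ~has).sum())
    c = int((~in_sub & has).sum())
    d = int((~in_sub & ~has).sum())
    odds, p = sps.fisher_exact([[a, b], [c, d]])
    return EnrichmentReport(
        subgroup=subgroup,
        annotation=annotation,
        level=str(level),
        table=((a, b), (c, d)),
        odds_ratio=float(odds),
        p=float(p),
        direction="enriched" if odds > 1 else ("depleted" if odds < 1 else "none"),
    )


def enrichment_scan(
    sample_table: pd.DataFrame, subgroups: pd.Series, annotations: list[str]
) -> pd.DataFrame:
    """All (subgroup, annotation level) one-vs-rest Fisher tests."""
    rows = []
    for ann in annotations:
        levels = [lv for lv in sample_table[ann].astype(str).unique() if lv != "NA"]
        for sub in sorted(subgroups.unique()):
            for lv in sorted(levels):
                rep = one_vs_rest_fisher(sample_table, subgroups, ann, lv, sub)
                rows.append(
                    {"subgroup": sub, "annotation": ann, "level": lv,
                     "odds_ratio": rep.odds_ratio, "p": rep.p,
                     "direction": rep.direction, "table": rep.table}
                )
    return pd.DataFrame(rows)


def compare_probe_sd(probe_matrix, dmr_regions: pd.DataFrame):
    """Standard deviation of DMR-overlapping vs non-overlapping probes,
    with a two-sided Mann-Whitney test.

    Returns (frame with per-probe sd + overlap flag, U statistic, p).
    """
    index = _ChromIndex(dmr_regions.assign(label=""), by_label=False)
    probes = probe_matrix.probes
    flags = np.array(
        [
            index.overlap_bases(c, None, int(s), int(e)) > 0
            for c, s, e in zip(probes["chrom"], probes["start"], probes["end"])
        ]
    )
    sd = probe_matrix.scores.std(axis=1, ddof=1)
    if flags.sum() < 2 or (~flags).sum() < 2:
        raise ValueError("need at least 2 probes in each overlap group")
    u, p = sps.mannwhitneyu(sd[flags], sd[~flags], alternative="two-sided")
    out = pd.DataFrame({"sd": sd, "in_dmr": flags}, index=probes.index)
    return out, float(u), float(p)


def tumor_normal_delta(
    means: pd.DataFrame,
    tumor_ids: list[str],
    normal_ids: list[str],
    patterns: pd.Series | None = None,
) -> pd.DataFrame:
    """mean(tumors) - mean(normals) per feature, summarized per pattern.

    Returns the per-feature deltas; with patterns given, attrs carry the
    per-pattern mean delta and its sign.
    """
    delta = means[tumor_ids].mean(axis=1) - means[normal_ids].mean(axis=1)
    out = pd.DataFrame({"delta": delta})
    if patterns is not None:
        pat = patterns.loc[out.index]
        summary = out.groupby(pat)["delta"].mean()
        out.attrs["per_pattern"] = summary.to_dict()
        out.attrs["per_pattern_sign"] = {
            k: int(np.sign(v)) for k, v in summary.items()
        }
    return out


def branch_enrichment(branches: pd.Series, flags: pd.Series) -> pd.DataFrame:
    """Per-branch one-vs-rest Fisher test of a membership flag (e.g. a
    methylation-pattern overlap) across dendrogram branches."""
    branches, flags = branches.align(flags, join="inner")
    f = flags.astype(bool).to_numpy()
    rows = []
    for b in sorted(branches.unique()):
        ing = (branches == b).to_numpy()
        table = [
            [int((f & ing).sum()), int((~f & ing).sum())],
            [int((f & ~ing).sum()), int((~f & ~ing).sum())],
        ]
        odds, p = sps.fisher_exact(table)
        rows.append({"branch": b, "odds_ratio": odds, "p": p,
                     "table": tuple(map(tuple, table))})
    return pd.DataFrame(rows).set_index("branch")
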