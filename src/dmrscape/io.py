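"""Readers, writers, and validation for every on-disk format the pipeline touches.

All genomic coordinates are 0-based half-open (BED dialect), both in memory
and on disk.  Matrices travel as tab-separated text, tracks as BED3/BED4
(the name column holds a chromatin-state number or a feature label), and
configuration as YAML.  Missing values are encoded as the literal string
``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("dmrscape")

AUTOSOMES = frozenset(f"chr{i}" for i in range(1, 23))

STAGE_LEVELS = frozenset({"Ta", "T1", "MI", "Tx", "NA"})
GRADE_LEVELS = frozenset({"1", "2", "3", "NA"})
MUTATION_LEVELS = frozenset({"mut", "wt", "NA"})
EPITYPE_LEVELS = frozenset({"A", "B", "C", "D", "NA"})

#: columns a sample table must carry (besides the sample_id index)
SAMPLE_TABLE_COLUMNS = (
    "stage",
    "grade",
    "tp53",
    "fgfr3",
    "lund_subtype",
    "epitype",
    "survival_time",
    "event",
)


class ValidationError(ValueError):
    """An on-disk file or in-memory object violates a format invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ProbeMatrix:
    """Probe-level methylation enrichment scores with genomic coordinates.

    Attributes
    ----------
    probes : pandas.DataFrame
        Indexed by ``probe_id``, with columns ``chrom``, ``start``, ``end``
        (0-based half-open) and ``cpg_count`` (CpG dinucleotides within the
        probe footprint).  Sorted by (chrom, start).
    scores : pandas.DataFrame
        Same index as ``probes``; one float column per sample.
    """

    probes: pd.DataFrame
    scores: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def validate(self) -> "ProbeMatrix":
        p = self.probes
        for col in ("chrom", "start", "end", "cpg_count"):
            if col not in p.columns:
                raise ValidationError(f"probe table missing column {col!r}")
        if p.index.has_duplicates:
            dup = p.index[p.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id {dup!r}")
        if not (p["end"] > p["start"]).all():
            raise ValidationError("probe with end <= start")
        if (p["cpg_count"] < 0).any():
            raise ValidationError("negative cpg_count")
        order = p.sort_values(["chrom", "start"], kind="stable").index
        if not order.equals(p.index):
            raise ValidationError("probes not sorted by (chrom, start)")
        if not self.scores.index.equals(p.index):
            raise ValidationError("scores index does not match probe table")
        if self.scores.isna().any().any():
            raise ValidationError("missing scores")
        return self

    def sorted(self) -> "ProbeMatrix":
        order = self.probes.sort_values(["chrom", "start"], kind="stable").index
        return ProbeMatrix(self.probes.loc[order], self.scores.loc[order])

    def filter_autosomes(self) -> "ProbeMatrix":
        """Drop probes whose chromosome is not one of chr1..chr22."""
        keep = self.probes["chrom"].isin(AUTOSOMES)
        return ProbeMatrix(self.probes.loc[keep], self.scores.loc[keep.values])


@dataclass
class GenomeTracks:
    """Named interval collections plus chromosome sizes and gene models.

    ``intervals`` maps a track name to a DataFrame with columns ``chrom``,
    ``start``, ``end`` and ``label``.  Tracks whose name starts with
    ``chromatin_`` are treated as 15-state segmentations: integer labels in
    1..15, tiling each chromosome without overlap.  ``gene_models`` is
    indexed by ``gene_id`` with columns ``chrom``, ``tss`` and ``strand``.
    """

    intervals: dict[str, pd.DataFrame] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    gene_models: pd.DataFrame | None = None

    def segmentation_names(self) -> list[str]:
        return [n for n in self.intervals if n.startswith("chromatin_")]

    def validate(self) -> "GenomeTracks":
        for name, df in self.intervals.items():
            for col in ("chrom", "start", "end"):
                if col not in df.columns:
                    raise ValidationError(f"track {name!r} missing column {col!r}")
            if not (df["end"] > df["start"]).all():
                raise ValidationError(f"track {name!r} has an empty interval")
            if (df["start"] < 0).any():
                raise ValidationError(f"track {name!r} has a negative start")
            if self.chrom_lengths:
                for chrom, sub in df.groupby("chrom", sort=False):
                    if chrom not in self.chrom_lengths:
                        raise ValidationError(
                            f"track {name!r} uses unknown chromosome {chrom!r}"
                        )
                    if (sub["end"] > self.chrom_lengths[chrom]).any():
                        raise ValidationError(
                            f"track {name!r} extends past the end of {chrom}"
                        )
            if name.startswith("chromatin_"):
                _validate_segmentation(name, df)
        if self.gene_models is not None:
            gm = self.gene_models
            if not set(gm["strand"].unique()) <= {"+", "-"}:
                raise ValidationError("gene strand must be '+' or '-'")
        return self


def _validate_segmentation(name: str, df: pd.DataFrame) -> None:
    labels = df["label"]
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValidationError(f"segmentation {name!r} labels must be integers")
    if not labels.between(1, 15).all():
        raise ValidationError(f"segmentation {name!r} labels outside 1..15")
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
            raise ValidationError(f"segmentation {name!r} overlaps on {chrom}")


def validate_sample_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical/molecular annotation table against its closed categories."""
    for col in SAMPLE_TABLE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"sample table missing column {col!r}")
    checks = {
        "stage": STAGE_LEVELS,
        "grade": GRADE_LEVELS,
        "tp53": MUTATION_LEVELS,
        "fgfr3": MUTATION_LEVELS,
        "epitype": EPITYPE_LEVELS,
    }
    for col, levels in checks.items():
        bad = set(df[col].astype(str).unique()) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} category {sorted(bad)}")
    t = pd.to_numeric(df["survival_time"], errors="coerce")
    if (t.dropna() < 0).any():
        raise ValidationError("negative survival_time")
    ev = df["event"].dropna()
    if not set(pd.to_numeric(ev, errors="coerce").dropna().unique()) <= {0, 1}:
        raise ValidationError("event must be 0 or 1")
    return df


# ---------------------------------------------------------------------------
# probe matrix TSV
# ---------------------------------------------------------------------------

_PROBE_META = ["probe_id", "chrom", "start", "end", "cpg_count"]


def read_probe_matrix(path: str | Path, autosomes_only: bool = False) -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _PROBE_META if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df.set_index("probe_id")
    probes = df[["chrom", "start", "end", "cpg_count"]]
    scores = df.drop(columns=["chrom", "start", "end", "cpg_count"]).astype(float)
    pm = ProbeMatrix(probes, scores)
    if autosomes_only:
        n_before = pm.n_probes
        pm = pm.filter_autosomes()
        logger.info("autosome filter: %d -> %d probes", n_before, pm.n_probes)
    return pm.validate()


def write_probe_matrix(pm: ProbeMatrix, path: str | Path) -> None:
    out = pd.concat([pm.probes, pm.scores], axis=1)
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, kind: str = "intervals") -> pd.DataFrame:
    """Read a BED3/BED4 file.

    ``kind='segmentation'`` casts the name column to integer chromatin
    states (1..15) and rejects overlapping segments; ``kind='intervals'``
    keeps string labels (absent name column becomes an empty label).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: expected >=3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad coordinate") from exc
            label = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], start, end, label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    if kind == "segmentation":
        try:
            df["label"] = df["label"].astype(int)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer chromatin state") from exc
        _validate_segmentation(str(path), df)
    elif kind != "intervals":
        raise ValueError(f"unknown BED kind {kind!r}")
    if (df["end"] <= df["start"]).any():
        bad = df.index[(df["end"] <= df["start"])][0]
        raise ValidationError(f"{path}: interval {bad} has end <= start")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["label"] if "label" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression and sample tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate gene ids")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype=str, na_values=[])
    df = df.fillna("NA")
    df["survival_time"] = pd.to_numeric(df["survival_time"].replace("NA", np.nan))
    df["event"] = pd.to_numeric(df["event"].replace("NA", np.nan))
    return validate_sample_table(df)


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# tracks directory (one BED per track + sidecar tables)
# ---------------------------------------------------------------------------


def write_tracks(tracks: GenomeTracks, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tracks.intervals.items():
        write_bed(df, outdir / f"{name}.bed")
    pd.Series(tracks.chrom_lengths, name="length").rename_axis("chrom").to_csv(
        outdir / "chrom_lengths.tsv", sep="\t"
    )
    if tracks.gene_models is not None:
        gm = tracks.gene_models.copy()
        gm.index.name = "gene_id"
        gm.to_csv(outdir / "gene_models.tsv", sep="\t")


def read_tracks(indir: str | Path) -> GenomeTracks:
    indir = Path(indir)
    lengths = pd.read_csv(indir / "chrom_lengths.tsv", sep="\t", index_col=0)[
        "length"
    ].to_dict()
    intervals = {}
    for bed in sorted(indir.glob("*.bed")):
        name = bed.stem
        kind = "segmentation" if name.startswith("chromatin_") else "intervals"
        intervals[name] = read_bed(bed, kind=kind)
    gene_path = indir / "gene_models.tsv"
    genes = (
        pd.read_csv(gene_path, sep="\t", index_col="gene_id")
        if gene_path.exists()
        else None
    )
    return GenomeTracks(intervals, lengths, genes).validate()


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML pipeline configuration (one block per stage)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg
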