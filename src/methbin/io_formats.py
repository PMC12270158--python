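"""Readers and writers for the standard files the pipeline touches.

All internal coordinates are 0-based half-open (BED convention); 1-based
report formats are converted at the parser boundary. CpG dyads are collapsed
onto the plus-strand C by default, summing counts from both strands.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SEXES = ("male", "female")
SAMPLE_TYPES = ("tissue", "cfDNA")

#: columns of the canonical in-memory methylation table
RECORD_COLUMNS = ("chrom", "pos", "n_meth", "n_unmeth", "sample_id")


class FormatError(ValueError):
    """A file violated its format contract."""


class MethylationRecord(NamedTuple):
    """One CpG site's read counts for one sample.

    ``pos`` is the 0-based position of the C of the CpG on the plus strand.
    """

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int
    sample_id: str

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def beta(self) -> float:
        """Methylated fraction; NaN when the site has no coverage."""
        cov = self.coverage
        return self.n_meth / cov if cov > 0 else float("nan")


_CHR_NUM = re.compile(r"^(?:chr)?(\d+)$")


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key giving chr1..chr22, chrX, chrY, chrM, then others."""
    m = _CHR_NUM.match(chrom)
    if m:
        return (0, int(m.group(1)), "")
    tail = chrom[3:] if chrom.startswith("chr") else chrom
    special = {"X": 1, "Y": 2, "M": 3, "MT": 3}
    if tail in special:
        return (special[tail], 0, "")
    return (4, 0, chrom)


def sort_chroms(chroms: Iterable[str]) -> list[str]:
    return sorted(set(chroms), key=chrom_sort_key)


def _collapse_and_sort(
    counts: dict[tuple[str, int], list[int]], sample_id: str
) -> list[MethylationRecord]:
    keys = sorted(counts, key=lambda k: (chrom_sort_key(k[0]), k[1]))
    return [
        MethylationRecord(c, p, counts[(c, p)][0], counts[(c, p)][1], sample_id)
        for c, p in keys
    ]


def read_cytosine_report(
    path: str | Path,
    sample_id: str,
    collapse_strands: bool = True,
) -> list[MethylationRecord]:
    """Parse a Bismark-style cytosine report.

    Lines are whitespace-separated: chrom, 1-based position, strand,
    methylated count, unmethylated count, context (and optionally the
    trinucleotide). Only CpG-context rows are consumed. Minus-strand rows
    are collapsed onto the plus-strand C at position-2 (1-based) by summing
    counts, unless ``collapse_strands`` is False, in which case each strand
    keeps its own position.
    """
    counts: dict[tuple[str, int], list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 6 fields, got {len(fields)}"
                )
            chrom, pos_s, strand, nm_s, nu_s, context = fields[:6]
            if context.upper() not in ("CG", "CPG"):
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            try:
                pos1 = int(pos_s)
                n_meth = int(nm_s)
                n_unmeth = int(nu_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError(f"{path}: line {lineno}: negative counts")
            if pos1 < 1:
                raise FormatError(f"{path}: line {lineno}: position must be >= 1")
            if strand == "+":
                pos = pos1 - 1
            else:
                pos = pos1 - 2 if collapse_strands else pos1 - 1
            cell = counts.setdefault((chrom, pos), [0, 0])
            cell[0] += n_meth
            cell[1] += n_unmeth
    return _collapse_and_sort(counts, sample_id)


def read_bedmethyl(
    path: str | Path,
    sample_id: str,
    collapse_strands: bool = True,
) -> list[MethylationRecord]:
    """Parse a bedMethyl (BED9+2) file into methylation records.

    Column 10 is read coverage and column 11 the percentage of methylated
    reads; ``n_meth`` is recovered as ``round(coverage * percent / 100)``.
    Zero-coverage rows are retained with zero counts (beta undefined).
    """
    counts: dict[tuple[str, int], list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 11:
                raise FormatError(
                    f"{path}: line {lineno}: bedMethyl needs >= 11 fields, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                coverage = int(fields[9])
                percent = float(fields[10])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            strand = fields[5]
            if coverage < 0:
                raise FormatError(f"{path}: line {lineno}: negative coverage")
            if not 0.0 <= percent <= 100.0:
                raise FormatError(
                    f"{path}: line {lineno}: percent {percent} outside [0, 100]"
                )
            n_meth = int(round(coverage * percent / 100.0))
            n_unmeth = coverage - n_meth
            pos = start - 1 if (strand == "-" and collapse_strands) else start
            cell = counts.setdefault((chrom, pos), [0, 0])
            cell[0] += n_meth
            cell[1] += n_unmeth
    return _collapse_and_sort(counts, sample_id)


def write_bedmethyl(records: Sequence[MethylationRecord], path: str | Path) -> None:
    """Write records as plus-strand bedMethyl rows (percent to 6 decimals)."""
    with open(path, "w") as fh:
        for r in records:
            cov = r.coverage
            pct = 100.0 * r.n_meth / cov if cov > 0 else 0.0
            score = min(cov, 1000)
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t.\t{score}\t+\t"
                f"{r.pos}\t{r.pos + 1}\t0,0,0\t{cov}\t{pct:.6f}\n"
            )


def write_cytosine_report(records: Sequence[MethylationRecord], path: str | Path) -> None:
    """Write records as plus-strand CpG-context cytosine-report rows (1-based)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos + 1}\t+\t{r.n_meth}\t{r.n_unmeth}\tCG\tCGN\n")


def records_to_frame(records: Sequence[MethylationRecord]) -> pd.DataFrame:
    return pd.DataFrame.from_records(records, columns=list(RECORD_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[MethylationRecord]:
    return [MethylationRecord(*row) for row in df[list(RECORD_COLUMNS)].itertuples(index=False)]


# ---------------------------------------------------------------------------
# feature tracks


@dataclass
class FeatureTrack:
    """A sorted set of genomic intervals of one kind.

    ``df`` columns: chrom, start, end, name, strand, state (and ``tss`` for
    gene tracks with strand). Coordinates are 0-based half-open.
    """

    df: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "cpg_island", "chromhmm"):
            raise ValueError(f"unknown track kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.df)

    def chroms(self) -> list[str]:
        return sort_chroms(self.df["chrom"])

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


def make_feature_track(rows: pd.DataFrame, kind: str) -> FeatureTrack:
    """Validate, sort and normalize interval rows into a FeatureTrack."""
    df = rows.copy()
    for col, default in (("name", "."), ("strand", "."), ("state", "")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] < 0).any():
        raise FormatError("negative interval start")
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"interval with start >= end: {df.iloc[i]['chrom']}:"
            f"{df.iloc[i]['start']}-{df.iloc[i]['end']}"
        )
    key = [chrom_sort_key(c) for c in df["chrom"]]
    order = pd.DataFrame({"k": key, "s": df["start"]}).sort_values(["k", "s"]).index
    if not (order.to_numpy() == np.arange(len(df))).all():
        warnings.warn("feature intervals were unsorted; sorting", stacklevel=2)
        df = df.loc[order]
    df = df.reset_index(drop=True)
    if kind == "gene":
        # strand-aware transcription start: leftmost base for +, rightmost for -
        df["tss"] = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    return FeatureTrack(df=df, kind=kind)


def read_feature_bed(path: str | Path, kind: str) -> FeatureTrack:
    """Read a BED3+ file as a feature track.

    Column 4 is the name (for chromHMM tracks, the state label, preserved
    verbatim); column 6 the strand.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: BED needs >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            rows.append((fields[0], start, end, name, strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    if kind == "chromhmm":
        df["state"] = df["name"]
    return make_feature_track(df, kind)


def write_feature_bed(track: FeatureTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            name = row.state if track.kind == "chromhmm" and row.state else row.name
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# sample metadata

REQUIRED_METADATA_COLUMNS = ("sample_id", "subject_id", "sex", "sample_type", "fibrosis_stage")


def base_group(sex: str, sample_type: str) -> str:
    """The sex x sample-type stratum a sample belongs to, e.g. ``male_tissue``."""
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    if sample_type not in SAMPLE_TYPES:
        raise ValueError(f"sample_type must be one of {SAMPLE_TYPES}, got {sample_type!r}")
    return f"{sex}_{sample_type}"


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in metadata")
    if not df["sex"].isin(SEXES).all():
        raise FormatError(f"sex values must be in {SEXES}")
    if not df["sample_type"].isin(SAMPLE_TYPES).all():
        raise FormatError(f"sample_type values must be in {SAMPLE_TYPES}")
    stages = df["fibrosis_stage"].astype(int)
    if not stages.isin(range(5)).all():
        raise FormatError("fibrosis_stage must be an integer in 0..4")
    out = df.copy()
    out["fibrosis_stage"] = stages
    out["base_group"] = [base_group(s, t) for s, t in zip(out["sex"], out["sample_type"])]
    return out


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV (header required)."""
    return validate_metadata(pd.read_csv(path, sep="\t"))


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in df.columns if c != "base_group"]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene lists


def write_gene_list(genes: Iterable[str], path: str | Path) -> list[str]:
    """Write a deduplicated, alphabetically sorted gene list, one per line."""
    out = sorted(set(genes))
    if not out:
        warnings.warn(f"writing empty gene list to {path}", stacklevel=2)
    with open(path, "w") as fh:
        for g in out:
            fh.write(g + "\n")
    return out


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
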