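"""Gap-based clustering of CpG sites into bins and the bin x sample beta matrix.

Adjacent CpG sites closer than ``max_gap`` (default 65 bp) are merged into a
bin; bins are numbered by a single genome-wide index so that the same index
refers to the same interval in every sample and stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methbin.io_formats import (
    MethylationRecord,
    RECORD_COLUMNS,
    records_to_frame,
    sort_chroms,
)

log = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 65


@dataclass(frozen=True)
class Bin:
    """A genomic interval holding a cluster of CpG sites.

    ``start``/``end`` are 0-based half-open and cover the member CpG dyads
    (end = last CpG position + 2).
    """

    bin_index: int
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


def build_bins(
    cpg_positions_by_chrom: Mapping[str, Sequence[int]],
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[Bin]:
    """Partition CpG sites into bins by the adjacency-gap rule.

    Two adjacent sites on the same chromosome are merged when their distance
    is strictly less than ``max_gap``; equivalently a new bin starts at every
    gap >= ``max_gap``. Singleton bins are allowed. ``bin_index`` increases in
    genomic order across chromosomes (natural chromosome ordering).
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    bins: list[Bin] = []
    idx = 0
    for chrom in sort_chroms(cpg_positions_by_chrom.keys()):
        pos = np.asarray(cpg_positions_by_chrom[chrom], dtype=np.int64)
        if pos.size == 0:
            continue
        diffs = np.diff(pos)
        if (diffs <= 0).any():
            raise ValueError(f"positions on {chrom} are not sorted and unique")
        # split where the gap to the previous site is >= max_gap
        breaks = np.flatnonzero(diffs >= max_gap) + 1
        for chunk in np.split(pos, breaks):
            bins.append(
                Bin(
                    bin_index=idx,
                    chrom=chrom,
                    start=int(chunk[0]),
                    end=int(chunk[-1]) + 2,
                    cpg_positions=tuple(int(p) for p in chunk),
                )
            )
            idx += 1
    return bins


@dataclass
class BinBetaMatrix:
    """Per-bin, per-sample methylation summary.

    ``beta`` is ``n_meth / n_total`` (read-count pooling over member CpGs)
    where ``n_total > 0`` and NaN elsewhere.
    """

    bins: list[Bin]
    samples: list[str]
    n_meth: np.ndarray  # (n_bins, n_samples) int64
    n_total: np.ndarray  # (n_bins, n_samples) int64
    beta: np.ndarray  # (n_bins, n_samples) float64, NaN = missing

    def __post_init__(self) -> None:
        shape = (len(self.bins), len(self.samples))
        for name in ("n_meth", "n_total", "beta"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if (self.n_meth < 0).any() or (self.n_meth > self.n_total).any():
            raise ValueError("need 0 <= n_meth <= n_total")

    @property
    def bin_index(self) -> np.ndarray:
        return np.array([b.bin_index for b in self.bins], dtype=np.int64)

    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.beta, index=self.bin_index, columns=self.samples).rename_axis(
            "bin_index"
        )


def _site_lookup(bins: Sequence[Bin]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chromosome: (sorted site positions, bin row of each site)."""
    lookup: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for row, b in enumerate(bins):
        pos = np.asarray(b.cpg_positions, dtype=np.int64)
        lookup.setdefault(b.chrom, []).append((pos, np.full(pos.size, row, dtype=np.int64)))
    out = {}
    for chrom, parts in lookup.items():
        pos = np.concatenate([p for p, _ in parts])
        rows = np.concatenate([r for _, r in parts])
        order = np.argsort(pos, kind="stable")
        out[chrom] = (pos[order], rows[order])
    return out


def compute_bin_beta(
    records_by_sample: Mapping[str, Sequence[MethylationRecord] | pd.DataFrame],
    bins: Sequence[Bin],
    mode: str = "pooled",
) -> BinBetaMatrix:
    """Aggregate per-CpG records into the bin x sample matrix.

    ``mode='pooled'`` (default) computes beta as summed methylated reads over
    summed total reads; ``mode='site_mean'`` averages per-CpG betas over the
    covered member sites instead. A record at a position not covered by any
    bin raises, since it indicates the bins were built from a different site
    set.
    """
    if mode not in ("pooled", "site_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = list(records_by_sample.keys())
    lookup = _site_lookup(bins)
    n_bins = len(bins)
    n_meth = np.zeros((n_bins, len(samples)), dtype=np.int64)
    n_total = np.zeros((n_bins, len(samples)), dtype=np.int64)
    site_beta_sum = np.zeros((n_bins, len(samples))) if mode == "site_mean" else None
    site_covered = np.zeros((n_bins, len(samples)), dtype=np.int64) if mode == "site_mean" else None

    for col, sample in enumerate(samples):
        recs = records_by_sample[sample]
        df = recs if isinstance(recs, pd.DataFrame) else records_to_frame(recs)
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in lookup:
                raise ValueError(f"sample {sample}: records on {chrom} match no bin")
            site_pos, site_row = lookup[chrom]
            pos = sub["pos"].to_numpy(dtype=np.int64)
            i = np.searchsorted(site_pos, pos)
            ok = (i < site_pos.size) & (site_pos[np.minimum(i, site_pos.size - 1)] == pos)
            if not ok.all():
                bad = pos[~ok][0]
                raise ValueError(
                    f"sample {sample}: record at {chrom}:{bad} is not a member of any bin"
                )
            rows = site_row[i]
            nm = sub["n_meth"].to_numpy(dtype=np.int64)
            nu = sub["n_unmeth"].to_numpy(dtype=np.int64)
            if (nm < 0).any() or (nu < 0).any():
                raise ValueError(f"sample {sample}: negative counts")
            np.add.at(n_meth[:, col], rows, nm)
            np.add.at(n_total[:, col], rows, nm + nu)
            if mode == "site_mean":
                cov = nm + nu
                has = cov > 0
                with np.errstate(invalid="ignore"):
                    sb = np.where(has, nm / np.maximum(cov, 1), 0.0)
                np.add.at(site_beta_sum[:, col], rows[has], sb[has])
                np.add.at(site_covered[:, col], rows[has], 1)

    with np.errstate(invalid="ignore"):
        if mode == "pooled":
            beta = np.where(n_total > 0, n_meth / np.maximum(n_total, 1), np.nan)
        else:
            beta = np.where(
                site_covered > 0, site_beta_sum / np.maximum(site_covered, 1), np.nan
            )
    return BinBetaMatrix(bins=list(bins), samples=samples, n_meth=n_meth, n_total=n_total, beta=beta)


# ---------------------------------------------------------------------------
# on-disk formats


def bins_to_bed(bins: Sequence[Bin], path: str | Path) -> None:
    """Write bins as BED4 (chrom, start, end, bin_index)."""
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.bin_index}\n")


def write_matrix(matrix: BinBetaMatrix, outdir: str | Path, prefix: str = "bins") -> dict[str, Path]:
    """Write bins.bed plus wide TSVs for beta (NA = missing) and counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bed": outdir / f"{prefix}.bed",
        "beta": outdir / f"{prefix}.beta.tsv",
        "n_meth": outdir / f"{prefix}.n_meth.tsv",
        "n_total": outdir / f"{prefix}.n_total.tsv",
    }
    bins_to_bed(matrix.bins, paths["bed"])
    matrix.beta_frame().to_csv(paths["beta"], sep="\t", na_rep="NA", float_format="%.8g")
    for key in ("n_meth", "n_total"):
        pd.DataFrame(
            getattr(matrix, key), index=matrix.bin_index, columns=matrix.samples
        ).rename_axis("bin_index").to_csv(paths[key], sep="\t")
    return paths


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    """Read a wide beta TSV (rows bins, columns samples, NA = missing)."""
    df = pd.read_csv(path, sep="\t", index_col="bin_index", na_values="NA")
    df.index = df.index.astype(np.int64)
    return df


def read_bins_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "bin_index"], header=None
    )
    return df
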