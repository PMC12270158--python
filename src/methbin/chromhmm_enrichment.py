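"""Chromatin-state transition enrichment for intergenic bins.

For each bin the states assigned in two cell types form a transition
(state in cell type A -> state in cell type B). Transition proportions among
fibrosis-associated intergenic bins are compared against non-associated
intergenic background bins; cells exceeding a fold threshold are flagged,
with low-support and absent cells marked separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Core 15-state mnemonics (TssA .. Quies)
CORE15_STATES = (
    "1_TssA",
    "2_TssAFlnk",
    "3_TxFlnk",
    "4_Tx",
    "5_TxWk",
    "6_EnhG",
    "7_Enh",
    "8_ZNF/Rpts",
    "9_Het",
    "10_TssBiv",
    "11_BivFlnk",
    "12_EnhBiv",
    "13_ReprPC",
    "14_ReprPCWk",
    "15_Quies",
)

DEFAULT_FOLD = 1.5
DEFAULT_MIN_BINS = 30


@dataclass
class TransitionTable:
    """Counts of (state in cell type A, state in cell type B) over a bin set."""

    counts: pd.DataFrame  # rows: states in A, columns: states in B
    group: str  # "associated" or "background"
    n_excluded: int = 0  # bins dropped for an NA state in either cell type

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def proportions(self) -> pd.DataFrame:
        total = self.total
        if total == 0:
            raise ValueError("transition table is empty")
        return self.counts / total


def build_transition_table(
    states_a: Sequence[str],
    states_b: Sequence[str],
    group: str,
    states: Sequence[str] = CORE15_STATES,
) -> TransitionTable:
    """Tally state transitions over bins; NA in either cell type excludes the bin."""
    if len(states_a) != len(states_b):
        raise ValueError("state vectors must have equal length")
    sa = np.asarray(states_a, dtype=object)
    sb = np.asarray(states_b, dtype=object)
    ok = (sa != "NA") & (sb != "NA")
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.info("%s: excluded %d bins with an NA state", group, n_excluded)
    sa, sb = sa[ok], sb[ok]
    if sa.size == 0:
        raise ValueError("no bins left after excluding NA states")
    unknown = (set(sa) | set(sb)) - set(states)
    if unknown:
        raise ValueError(f"states not on the label grid: {sorted(unknown)}")
    counts = pd.crosstab(pd.Series(sa), pd.Series(sb))
    counts = counts.reindex(index=list(states), columns=list(states), fill_value=0)
    counts.index.name = "state_a"
    counts.columns.name = "state_b"
    return TransitionTable(counts=counts.astype(np.int64), group=group, n_excluded=n_excluded)


@dataclass
class EnrichmentResult:
    """Cellwise fold ratios of associated over background transition proportions."""

    ratio: pd.DataFrame  # associated proportion / background proportion
    n_assoc: pd.DataFrame  # associated-group counts per cell
    enriched: pd.DataFrame  # finite ratio > fold
    low_support: pd.DataFrame  # n_assoc < min_bins (and > 0)
    absent: pd.DataFrame  # n_assoc == 0
    infinite: pd.DataFrame  # background proportion 0 with n_assoc > 0
    fold: float
    min_bins: int

    def flagged(self) -> pd.DataFrame:
        """Enriched cells with adequate support (the reportable calls)."""
        return self.enriched & ~self.low_support


def compute_enrichment(
    assoc: TransitionTable,
    background: TransitionTable,
    fold: float = DEFAULT_FOLD,
    min_bins: int = DEFAULT_MIN_BINS,
) -> EnrichmentResult:
    """Compare associated against background transition proportions cellwise."""
    if not assoc.counts.index.equals(background.counts.index) or not assoc.counts.columns.equals(
        background.counts.columns
    ):
        raise ValueError("transition tables are on different label grids")
    if background.total == 0:
        raise ValueError("background table is empty")
    pa = assoc.proportions
    pb = background.proportions
    n_assoc = assoc.counts
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_arr = pa.to_numpy() / pb.to_numpy()
    infinite = (pb.to_numpy() == 0) & (n_assoc.to_numpy() > 0)
    ratio_arr = np.where((pb.to_numpy() == 0) & (n_assoc.to_numpy() == 0), np.nan, ratio_arr)
    ratio = pd.DataFrame(ratio_arr, index=pa.index, columns=pa.columns)
    enriched = pd.DataFrame(
        np.isfinite(ratio_arr) & (ratio_arr > fold), index=pa.index, columns=pa.columns
    )
    absent = n_assoc == 0
    low_support = (n_assoc < min_bins) & ~absent
    return EnrichmentResult(
        ratio=ratio,
        n_assoc=n_assoc,
        enriched=enriched,
        low_support=low_support,
        absent=absent,
        infinite=pd.DataFrame(infinite, index=pa.index, columns=pa.columns),
        fold=fold,
        min_bins=min_bins,
    )


def enriched_gene_list(
    enrichment: EnrichmentResult,
    bin_states: pd.DataFrame,
    annotations: pd.DataFrame,
    state_columns: tuple[str, str],
) -> list[str]:
    """Nearest genes of associated bins in enriched, adequately supported cells.

    ``bin_states`` holds the associated bins with their per-cell-type state
    columns; ``annotations`` supplies ``nearest_gene`` by ``bin_index``.
    """
    flagged = enrichment.flagged()
    a, b = state_columns
    cells = {
        (ia, ib)
        for ia in flagged.index
        for ib in flagged.columns
        if bool(flagged.loc[ia, ib])
    }
    if not cells:
        warnings.warn("no enriched, adequately supported transition cells", stacklevel=2)
        return []
    hits = bin_states[
        [ (ra, rb) in cells for ra, rb in zip(bin_states[a], bin_states[b]) ]
    ]
    merged = hits.merge(annotations[["bin_index", "nearest_gene"]], on="bin_index", how="left")
    genes = sorted(set(merged["nearest_gene"].dropna()))
    if not genes:
        warnings.warn("enriched cells contain no bins with a nearest gene", stacklevel=2)
    return genes


def write_enrichment(result: EnrichmentResult, outdir: str | Path, prefix: str = "chromhmm") -> dict:
    """Write the ratio matrix and a long-format flags table as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ratio": outdir / f"{prefix}.ratio.tsv",
        "flags": outdir / f"{prefix}.flags.tsv",
    }
    result.ratio.to_csv(paths["ratio"], sep="\t", na_rep="NA", float_format="%.6g")
    rows = []
    for ia in result.ratio.index:
        for ib in result.ratio.columns:
            rows.append(
                (
                    ia,
                    ib,
                    int(result.n_assoc.loc[ia, ib]),
                    result.ratio.loc[ia, ib],
                    bool(result.enriched.loc[ia, ib]),
                    bool(result.low_support.loc[ia, ib]),
                    bool(result.absent.loc[ia, ib]),
                    bool(result.infinite.loc[ia, ib]),
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "state_a",
            "state_b",
            "n_assoc",
            "ratio",
            "enriched",
            "low_support",
            "absent",
            "infinite",
        ],
    ).to_csv(paths["flags"], sep="\t", index=False, na_rep="NA", float_format="%.6g")
    return paths
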