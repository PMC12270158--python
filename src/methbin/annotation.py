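"""Placement of bins relative to genes, TSSs, CpG islands and chromatin states.

Distances between intervals are gap lengths in the half-open convention
(0 for overlapping or book-ended intervals); the sign is negative when the
gene lies 5' of the bin in reference orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methbin.association import BASE_GROUPS
from methbin.binning import Bin
from methbin.group_intersection import LABEL_GROUPS
from methbin.io_formats import FeatureTrack, FormatError

log = logging.getLogger(__name__)

DEFAULT_TSS_WINDOW = 1500

PATHWAY_MODES = ("tissue_strict", "or_relaxed", "extended")


@dataclass(frozen=True)
class Transcript:
    """A transcript with exon structure, for first-exon/first-intron calls."""

    gene: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def first_exon_intron_span(self) -> tuple[int, int]:
        """Union of the 5'-most exon and the first intron, as one interval.

        For a plus-strand transcript this runs from the first exon's start to
        the second exon's start; for minus strand, from the second-to-last
        exon's end to the last exon's end. Single-exon transcripts yield the
        exon itself.
        """
        exons = sorted(self.exons)
        if len(exons) == 1:
            return exons[0]
        if self.strand == "-":
            return exons[-2][1], exons[-1][1]
        return exons[0][0], exons[1][0]


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between half-open intervals; 0 when overlapping or touching."""
    return max(b_start - a_end, a_start - b_end, 0)


def nearest_gene(
    bin_: Bin, gene_track: FeatureTrack
) -> tuple[str | None, int | None]:
    """The nearest gene to a bin and the signed gap distance.

    Distance 0 means overlap (or adjacency); negative sign means the gene is
    5' of the bin (lower coordinates). Ties are broken by smaller absolute
    distance, then alphabetical gene symbol. Returns ``(None, None)`` with a
    warning when the chromosome holds no gene.
    """
    genes = gene_track.on_chrom(bin_.chrom)
    if genes.empty:
        warnings.warn(f"no gene on {bin_.chrom}; nearest-gene annotation missing", stacklevel=2)
        return None, None
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    names = genes["name"].to_numpy()
    gaps = np.maximum(np.maximum(starts - bin_.end, bin_.start - ends), 0)
    order = sorted(range(len(genes)), key=lambda i: (gaps[i], names[i]))
    i = order[0]
    signed = int(gaps[i]) if starts[i] >= bin_.end else -int(gaps[i])
    if gaps[i] == 0 and not (starts[i] >= bin_.end or ends[i] <= bin_.start):
        signed = 0
    return str(names[i]), signed


def _tss_distance(bin_: Bin, tss: np.ndarray) -> np.ndarray:
    """Distance from a bin interval to TSS points (0 when the TSS is inside)."""
    d = np.zeros(tss.shape, dtype=np.int64)
    left = tss < bin_.start
    right = tss >= bin_.end
    d[left] = bin_.start - tss[left]
    d[right] = tss[right] - (bin_.end - 1)
    return d


def assign_chromhmm_state(bin_: Bin, chromhmm_track: FeatureTrack) -> str:
    """The chromatin state of the segment with the largest overlap.

    Ties go to the segment with the smaller start; a bin with no overlapping
    segment gets state ``"NA"`` with a warning.
    """
    seg = chromhmm_track.on_chrom(bin_.chrom)
    if not seg.empty:
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        overlap = np.minimum(ends, bin_.end) - np.maximum(starts, bin_.start)
        hit = overlap > 0
        if hit.any():
            idx = np.flatnonzero(hit)
            # max overlap, ties to the earlier segment (stable order by start)
            best = idx[np.argmax(overlap[idx])]
            contenders = idx[overlap[idx] == overlap[best]]
            best = contenders[np.argmin(starts[contenders])]
            return str(seg["state"].to_numpy()[best])
    warnings.warn(
        f"bin {bin_.bin_index} ({bin_.chrom}:{bin_.start}-{bin_.end}) has no "
        "chromHMM segment; state NA",
        stacklevel=2,
    )
    return "NA"


def classify_region(
    bin_: Bin,
    gene_track: FeatureTrack,
    island_track: FeatureTrack | None = None,
    transcripts: Sequence[Transcript] | None = None,
    tss_window: int = DEFAULT_TSS_WINDOW,
    island_slop: int = 0,
) -> dict:
    """Positional flags for one bin.

    ``near_tss`` is strict (< ``tss_window`` bp from a strand-aware TSS);
    ``in_cpg_island`` requires >= 1 bp overlap with an island (optionally
    expanded by ``island_slop``); ``intergenic`` means no gene-body overlap;
    ``first_exon_intron`` is true when the bin overlaps the 5'-most exon or
    first intron of any transcript of an overlapping gene (falling back to
    whole gene bodies when no transcript structure is supplied).
    """
    genes = gene_track.on_chrom(bin_.chrom)
    overlapping = genes[(genes["start"] < bin_.end) & (bin_.start < genes["end"])]
    intergenic = overlapping.empty

    near_tss = False
    if not genes.empty and "tss" in genes.columns:
        d = _tss_distance(bin_, genes["tss"].to_numpy(dtype=np.int64))
        near_tss = bool((d < tss_window).any())

    in_island = False
    if island_track is not None:
        isl = island_track.on_chrom(bin_.chrom)
        if not isl.empty:
            s = isl["start"].to_numpy() - island_slop
            e = isl["end"].to_numpy() + island_slop
            in_island = bool(((s < bin_.end) & (bin_.start < e)).any())

    first_ei = False
    if not intergenic:
        names = set(overlapping["name"])
        if transcripts:
            for t in transcripts:
                if t.gene in names and t.chrom == bin_.chrom:
                    s, e = t.first_exon_intron_span()
                    if s < bin_.end and bin_.start < e:
                        first_ei = True
                        break
        else:
            first_ei = True  # single-exon fallback: gene body is the first exon

    gene, signed = nearest_gene(bin_, gene_track) if not genes.empty else (None, None)
    return {
        "bin_index": bin_.bin_index,
        "nearest_gene": gene,
        "signed_distance": signed,
        "near_tss": near_tss,
        "in_cpg_island": in_island,
        "intergenic": intergenic,
        "first_exon_intron": first_ei,
    }


def annotate_bins(
    bins: Sequence[Bin],
    gene_track: FeatureTrack,
    island_track: FeatureTrack | None = None,
    chromhmm_tracks: Mapping[str, FeatureTrack] | None = None,
    transcripts: Sequence[Transcript] | None = None,
    tss_window: int = DEFAULT_TSS_WINDOW,
    island_slop: int = 0,
) -> pd.DataFrame:
    """Annotate every bin; one row per bin, keyed by ``bin_index``.

    ``chromhmm_tracks`` maps cell-type names to genome-tiling segmentations;
    each contributes a ``state_<celltype>`` column.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for b in bins:
            row = classify_region(
                b, gene_track, island_track, transcripts, tss_window, island_slop
            )
            if chromhmm_tracks:
                for ct, track in chromhmm_tracks.items():
                    row[f"state_{ct}"] = assign_chromhmm_state(b, track)
            rows.append(row)
    return pd.DataFrame(rows)


def select_pathway_input(
    labels: pd.DataFrame,
    annotations: pd.DataFrame,
    mode: str,
    target_label: str,
    results_by_group: Mapping[str, pd.DataFrame] | None = None,
    alpha_extended: float = 0.01,
    state_columns: tuple[str, str] | None = None,
) -> list[str]:
    """Gene list for pathway submission under the stated selection criteria.

    ``tissue_strict`` keeps bins of the target label that are both in a CpG
    island and TSS-proximal; ``or_relaxed`` requires either; ``extended``
    keeps bins whose Kendall p is below ``alpha_extended`` in every base
    group defining the label and whose chromatin state differs between the
    two cell types named by ``state_columns``.
    """
    if mode not in PATHWAY_MODES:
        raise ValueError(f"mode must be one of {PATHWAY_MODES}, got {mode!r}")
    if target_label not in LABEL_GROUPS:
        raise ValueError(f"target_label must be one of {sorted(LABEL_GROUPS)}")
    sel = labels[labels["label"] == target_label][["bin_index"]]
    ann = sel.merge(annotations, on="bin_index", how="inner")

    if mode == "tissue_strict":
        ann = ann[ann["in_cpg_island"] & ann["near_tss"]]
    elif mode == "or_relaxed":
        ann = ann[ann["in_cpg_island"] | ann["near_tss"]]
    else:
        if results_by_group is None:
            raise ValueError("extended mode needs per-group screening results")
        if state_columns is None:
            state_cols = [c for c in annotations.columns if c.startswith("state_")]
            if len(state_cols) != 2:
                raise ValueError("extended mode needs exactly two chromHMM state columns")
            state_columns = (state_cols[0], state_cols[1])
        keep = np.ones(len(ann), dtype=bool)
        for g in sorted(LABEL_GROUPS[target_label]):
            pg = results_by_group[g].set_index("bin_index")["p_value"]
            pvals = pg.reindex(ann["bin_index"]).to_numpy(dtype=float)
            keep &= pvals < alpha_extended
        a, b = state_columns
        sa = ann[a].astype(str).to_numpy()
        sb = ann[b].astype(str).to_numpy()
        keep &= (sa != "NA") & (sb != "NA") & (sa != sb)
        ann = ann[keep]

    genes = sorted(set(ann["nearest_gene"].dropna()))
    if not genes:
        warnings.warn(
            f"no qualifying bins for label {target_label!r} in mode {mode!r}", stacklevel=2
        )
    return genes


# ---------------------------------------------------------------------------
# transcript structure inputs


def read_transcripts_bed12(path: str | Path) -> list[Transcript]:
    """Read transcripts with exon blocks from a BED12 file (name = gene symbol)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: line {lineno}: BED12 needs 12 fields")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            out.append(Transcript(name, chrom, start, end, strand, exons))
    return out


def write_transcripts_bed12(transcripts: Sequence[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            exons = sorted(t.exons)
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - t.start) for s, _ in exons)
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t0\t{t.strand}\t"
                f"{t.start}\t{t.end}\t0,0,0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


def gtf_to_transcripts(path: str | Path) -> list[Transcript]:
    """Collect exon lines of a RefSeq-style GTF into Transcript objects."""
    by_tx: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            tx_id = attrs.get("transcript_id", "").strip('"')
            gene = attrs.get("gene_name", attrs.get("gene_id", "")).strip('"')
            rec = by_tx.setdefault(
                tx_id, {"gene": gene, "chrom": f[0], "strand": f[6], "exons": []}
            )
            rec["exons"].append((int(f[3]) - 1, int(f[4])))  # GTF is 1-based closed
    out = []
    for rec in by_tx.values():
        exons = tuple(sorted(rec["exons"]))
        out.append(
            Transcript(
                rec["gene"], rec["chrom"], exons[0][0], exons[-1][1], rec["strand"], exons
            )
        )
    return out


def transcripts_to_gene_track(transcripts: Sequence[Transcript]) -> pd.DataFrame:
    """Collapse transcripts to one interval per gene (for gene-track building)."""
    rows: dict[str, list] = {}
    for t in transcripts:
        cur = rows.get(t.gene)
        if cur is None:
            rows[t.gene] = [t.chrom, t.start, t.end, t.gene, t.strand]
        else:
            cur[1] = min(cur[1], t.start)
            cur[2] = max(cur[2], t.end)
    return pd.DataFrame(
        list(rows.values()), columns=["chrom", "start", "end", "name", "strand"]
    )
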