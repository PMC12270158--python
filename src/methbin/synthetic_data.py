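"""Self-contained synthetic cohorts, genomes, tracks and atlases.

Everything the pipeline consumes can be generated here with known planted
structure: fibrosis-correlated bins confined to chosen strata, island-dense
and open-sea CpG spacing, genome-tiling chromatin-state segmentations for
two cell types, and reference atlases with Dirichlet mixtures carrying an
optional fibrosis-linked hepatocyte shift. All draws are deterministic in
the config seed; the default cohort reproduces the real study's margins
(38 subjects, 30 paired, sex-specific fibrosis-stage counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from methbin import binning
from methbin.association import BASE_GROUPS
from methbin.binning import Bin, build_bins
from methbin.chromhmm_enrichment import CORE15_STATES
from methbin.deconvolution import ReferenceAtlas
from methbin.group_intersection import LABEL_GROUPS
from methbin.io_formats import FeatureTrack, make_feature_track, validate_metadata
from methbin.annotation import Transcript

log = logging.getLogger(__name__)

PLANT_LABELS = tuple(LABEL_GROUPS)  # Tissue, cfDNA, Male, Female, All


@dataclass(frozen=True)
class PlantedEffect:
    """One bin to plant with a per-stage beta shift in the groups of a label."""

    target_label: str
    delta: float  # per-stage shift in beta units
    direction: int = 1

    def __post_init__(self) -> None:
        if self.target_label not in PLANT_LABELS:
            raise ValueError(f"target_label must be one of {PLANT_LABELS}")
        if not -0.25 <= self.delta <= 0.25:
            raise ValueError("delta must lie in [-0.25, 0.25]")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class AtlasSpec:
    n_cell_types: int = 10
    n_markers: int = 500
    separation: float = 0.8
    low_max: float = 0.05
    noise_sd: float = 0.02
    dirichlet_alpha: float = 2.0
    hepatocyte_shift: float = 0.0  # mean proportion increase in high-fibrosis samples


@dataclass
class SimulationConfig:
    """Full description of one synthetic dataset (deterministic in ``seed``)."""

    seed: int = 0
    n_chromosomes: int = 2
    n_cpgs: int = 4000
    # cohort margins (defaults match the study's printed composition)
    male_tissue_only: int = 2
    male_cfdna_only: int = 2
    male_paired: int = 14
    female_tissue_only: int = 4
    female_cfdna_only: int = 0
    female_paired: int = 16
    fibrosis_male: tuple[int, ...] = (0, 7, 7, 3, 1)
    fibrosis_female: tuple[int, ...] = (2, 8, 4, 5, 1)
    # genome geometry
    island_weight: float = 0.25
    island_gap_mean: float = 12.0
    island_cluster_size: tuple[int, int] = (5, 30)
    opensea_gap_mean: float = 400.0
    promoter_prob: float = 0.6
    # coverage model
    coverage_tissue: float = 30.0
    coverage_cfdna: float = 10.0
    coverage_dispersion: float = 0.3
    # effect and noise model
    effects: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 0.12  # logit-scale per-sample noise
    subject_sd: float = 0.15  # logit-scale per-subject baseline (shared in pairs)
    max_gap: int = binning.DEFAULT_MAX_GAP
    chromhmm_cell_types: tuple[str, str] = ("GM12878", "HepG2")
    atlas: AtlasSpec = field(default_factory=AtlasSpec)

    def __post_init__(self) -> None:
        if isinstance(self.atlas, dict):
            self.atlas = AtlasSpec(**self.atlas)
        self.effects = tuple(
            e if isinstance(e, PlantedEffect) else PlantedEffect(**e) for e in self.effects
        )
        if sum(self.fibrosis_male) != self.n_males:
            raise ValueError("fibrosis_male counts must sum to the number of male subjects")
        if sum(self.fibrosis_female) != self.n_females:
            raise ValueError("fibrosis_female counts must sum to the number of female subjects")
        if self.n_cpgs < 0 or self.n_chromosomes < 1:
            raise ValueError("invalid genome size")
        if not 0.0 <= self.island_weight <= 1.0:
            raise ValueError("island_weight must be a probability")
        if self.island_gap_mean < 2 or self.opensea_gap_mean < 2:
            raise ValueError("gap means must be >= 2")

    @property
    def n_males(self) -> int:
        return self.male_tissue_only + self.male_cfdna_only + self.male_paired

    @property
    def n_females(self) -> int:
        return self.female_tissue_only + self.female_cfdna_only + self.female_paired

    @property
    def n_subjects(self) -> int:
        return self.n_males + self.n_females


@dataclass
class Genome:
    cpg_positions: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    gene_track: FeatureTrack
    island_track: FeatureTrack
    chromhmm_tracks: dict[str, FeatureTrack]
    transcripts: list[Transcript]


@dataclass
class GroundTruth:
    """What was planted, for end-to-end recovery checks."""

    planted: list[dict]  # bin_index, target_label, delta, direction
    true_weights: pd.DataFrame | None = None


@dataclass
class Cohort:
    metadata: pd.DataFrame
    records: dict[str, pd.DataFrame]  # sample_id -> record table
    bins: list[Bin]
    truth: GroundTruth


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# genome


def generate_genome(config: SimulationConfig) -> Genome:
    """CpG positions plus gene, island and chromatin-state tracks.

    Inter-CpG gaps follow a two-component mixture: dense island clusters
    (geometric gaps around ``island_gap_mean``) and open-sea gaps around
    ``opensea_gap_mean``, so the gap rule produces both multi-CpG bins and
    singletons. ChromHMM tracks tile each chromosome completely.
    """
    rng = _rng(config, 0)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    per_chrom = [config.n_cpgs // config.n_chromosomes] * config.n_chromosomes
    per_chrom[0] += config.n_cpgs - sum(per_chrom)

    positions: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    island_rows = []
    gene_rows = []
    transcripts: list[Transcript] = []
    gene_counter = 0
    lo, hi = config.island_cluster_size

    for chrom, n_sites in zip(chroms, per_chrom):
        pos_list: list[int] = []
        pos = 1000
        while len(pos_list) < n_sites:
            remaining = n_sites - len(pos_list)
            if remaining >= 2 and rng.random() < config.island_weight:
                size = min(int(rng.integers(lo, hi + 1)), remaining)
                cluster = [pos]
                for _ in range(size - 1):
                    cluster.append(cluster[-1] + 2 + int(rng.geometric(1.0 / config.island_gap_mean)))
                pos_list.extend(cluster)
                island_rows.append((chrom, max(cluster[0] - 20, 0), cluster[-1] + 22))
                # promoter gene anchored at the island for some clusters
                if rng.random() < config.promoter_prob:
                    length = int(rng.integers(2000, 8000))
                    strand = "+" if rng.random() < 0.5 else "-"
                    if strand == "+":
                        gs, ge = cluster[0], cluster[0] + length
                    else:
                        gs, ge = max(cluster[-1] + 2 - length, 0), cluster[-1] + 2
                    gene_counter += 1
                    name = f"GENE{gene_counter:04d}"
                    gene_rows.append((chrom, gs, ge, name, strand))
                    transcripts.append(_make_transcript(name, chrom, gs, ge, strand, rng))
                pos = cluster[-1] + 65 + int(rng.geometric(1.0 / config.opensea_gap_mean))
            else:
                pos_list.append(pos)
                pos += int(rng.geometric(1.0 / config.opensea_gap_mean))
        arr = np.asarray(pos_list[:n_sites], dtype=np.int64)
        positions[chrom] = arr
        lengths[chrom] = int(arr[-1]) + 2000 if arr.size else 2000
        # a few extra genes in open sea so intergenic bins have a nearest gene
        n_extra = max(1, n_sites // 200) if n_sites else 0
        for _ in range(n_extra):
            gs = int(rng.integers(0, max(lengths[chrom] - 3000, 1)))
            ge = gs + int(rng.integers(1500, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_counter += 1
            name = f"GENE{gene_counter:04d}"
            gene_rows.append((chrom, gs, ge, name, strand))
            transcripts.append(_make_transcript(name, chrom, gs, ge, strand, rng))

    from methbin.io_formats import chrom_sort_key

    gene_rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1]))
    gene_track = make_feature_track(
        pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "strand"]),
        "gene",
    ) if gene_rows else make_feature_track(
        pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"]), "gene"
    )
    island_track = make_feature_track(
        pd.DataFrame(island_rows, columns=["chrom", "start", "end"]),
        "cpg_island",
    ) if island_rows else make_feature_track(
        pd.DataFrame(columns=["chrom", "start", "end"]), "cpg_island"
    )

    state_weights = _default_state_weights()
    chromhmm_tracks = {}
    for ct in config.chromhmm_cell_types:
        rows = []
        for chrom in chroms:
            end_of_chrom = lengths[chrom]
            cursor = 0
            while cursor < end_of_chrom:
                seg_len = int(rng.integers(500, 5000))
                seg_end = min(cursor + seg_len, end_of_chrom)
                state = str(rng.choice(CORE15_STATES, p=state_weights))
                rows.append((chrom, cursor, seg_end, state))
                cursor = seg_end
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        df["state"] = df["name"]
        chromhmm_tracks[ct] = make_feature_track(df, "chromhmm") if rows else make_feature_track(
            pd.DataFrame(columns=["chrom", "start", "end", "name", "state"]), "chromhmm"
        )

    return Genome(
        cpg_positions=positions,
        chrom_lengths=lengths,
        gene_track=gene_track,
        island_track=island_track,
        chromhmm_tracks=chromhmm_tracks,
        transcripts=transcripts,
    )


def _make_transcript(
    name: str, chrom: str, start: int, end: int, strand: str, rng: np.random.Generator
) -> Transcript:
    """Three-exon transcript spanning the gene body."""
    length = end - start
    if length < 600:
        return Transcript(name, chrom, start, end, strand, ((start, end),))
    e1 = start + max(int(length * rng.uniform(0.05, 0.15)), 50)
    i1 = e1 + max(int(length * rng.uniform(0.1, 0.3)), 50)
    e2 = i1 + max(int(length * rng.uniform(0.05, 0.15)), 50)
    i2 = min(e2 + max(int(length * rng.uniform(0.1, 0.3)), 50), end - 50)
    exons = ((start, e1), (i1, min(e2, end - 1)), (i2, end))
    exons = tuple((s, e) for s, e in exons if s < e)
    return Transcript(name, chrom, start, end, strand, exons)


def _default_state_weights() -> np.ndarray:
    w = np.ones(len(CORE15_STATES))
    by_name = dict(zip(CORE15_STATES, range(len(CORE15_STATES))))
    w[by_name["15_Quies"]] = 8.0
    w[by_name["9_Het"]] = 3.0
    w[by_name["5_TxWk"]] = 3.0
    w[by_name["7_Enh"]] = 2.0
    return w / w.sum()


# ---------------------------------------------------------------------------
# cohort


def _build_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    spec = [
        ("male", config.male_paired, config.male_tissue_only, config.male_cfdna_only,
         config.fibrosis_male),
        ("female", config.female_paired, config.female_tissue_only, config.female_cfdna_only,
         config.fibrosis_female),
    ]
    subj_no = 0
    for sex, n_paired, n_tissue, n_cfdna, stage_counts in spec:
        avail = ["paired"] * n_paired + ["tissue"] * n_tissue + ["cfDNA"] * n_cfdna
        stages = [s for s, c in enumerate(stage_counts) for _ in range(c)]
        rng.shuffle(avail)
        rng.shuffle(stages)
        for availability, stage in zip(avail, stages):
            subj_no += 1
            subject = f"S{subj_no:02d}"
            diabetes = "yes" if rng.random() < 0.45 else "no"
            for st, tag in (("tissue", "T"), ("cfDNA", "C")):
                if availability != "paired" and availability != st:
                    continue
                rows.append(
                    (f"{subject}_{tag}", subject, sex, st, stage, diabetes)
                )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "subject_id", "sex", "sample_type", "fibrosis_stage", "diabetes"],
    )
    return validate_metadata(df)


def generate_cohort(config: SimulationConfig, genome: Genome) -> Cohort:
    """Per-sample methylation records with planted fibrosis effects.

    Bin baselines come from a bimodal beta mixture; planted bins shift mean
    beta by ``direction * delta * stage`` in exactly the base groups implied
    by the effect's target label. Paired samples share a subject-level
    logit-scale baseline; site counts are binomial given negative-binomial
    coverage (means differ between tissue and cfDNA).
    """
    rng = _rng(config, 1)
    metadata = _build_metadata(config, rng)
    bins = build_bins(genome.cpg_positions, config.max_gap)
    n_bins = len(bins)

    # flattened site arrays in bin order
    site_chrom = np.concatenate(
        [np.full(b.n_cpgs, b.chrom, dtype=object) for b in bins]
    ) if bins else np.array([], dtype=object)
    site_pos = np.concatenate(
        [np.asarray(b.cpg_positions, dtype=np.int64) for b in bins]
    ) if bins else np.array([], dtype=np.int64)
    site_bin = np.concatenate(
        [np.full(b.n_cpgs, i, dtype=np.int64) for i, b in enumerate(bins)]
    ) if bins else np.array([], dtype=np.int64)

    baseline = np.where(
        rng.random(n_bins) < 0.5, rng.beta(2.0, 8.0, n_bins), rng.beta(8.0, 2.0, n_bins)
    )
    baseline = np.clip(baseline, 0.03, 0.97)

    # planted bins: prefer multi-CpG bins so coverage filters never bind
    planted_rows: list[dict] = []
    plant_bin_rows = np.array([], dtype=np.int64)
    plant_delta = np.array([])
    plant_groups: list[frozenset] = []
    if config.effects:
        eligible = np.flatnonzero(np.array([b.n_cpgs >= 4 for b in bins]))
        if eligible.size < len(config.effects):
            raise ValueError("not enough multi-CpG bins to plant all effects")
        chosen = rng.choice(eligible, size=len(config.effects), replace=False)
        plant_bin_rows = np.sort(chosen)
        deltas = []
        for row, eff in zip(plant_bin_rows, config.effects):
            signed = eff.direction * eff.delta
            # mid-range baseline keeps beta + 4*delta inside (0, 1)
            baseline[row] = rng.uniform(0.15, 0.35) if signed > 0 else rng.uniform(0.65, 0.85)
            deltas.append(signed)
            plant_groups.append(LABEL_GROUPS[eff.target_label])
            planted_rows.append(
                {
                    "bin_index": int(bins[row].bin_index),
                    "target_label": eff.target_label,
                    "delta": eff.delta,
                    "direction": eff.direction,
                }
            )
        plant_delta = np.asarray(deltas)

    subjects = list(dict.fromkeys(metadata["subject_id"]))
    subj_idx = {s: i for i, s in enumerate(subjects)}
    subject_effect = rng.normal(0.0, config.subject_sd, size=(len(subjects), n_bins))
    plant_site_mask = np.isin(site_bin, plant_bin_rows)

    r_disp = 1.0 / config.coverage_dispersion
    records: dict[str, pd.DataFrame] = {}
    for row in metadata.itertuples(index=False):
        mu = baseline.copy()
        for prow, pdelta, pgroups in zip(plant_bin_rows, plant_delta, plant_groups):
            if row.base_group in pgroups:
                mu[prow] = mu[prow] + pdelta * row.fibrosis_stage
        mu = np.clip(mu, 0.01, 0.99)
        z = logit(mu) + subject_effect[subj_idx[row.subject_id]]
        z = z + rng.normal(0.0, config.noise_sd, n_bins)
        p_bin = expit(z)
        p_site = p_bin[site_bin]
        mean_cov = config.coverage_tissue if row.sample_type == "tissue" else config.coverage_cfdna
        p_nb = r_disp / (r_disp + mean_cov)
        cov = rng.negative_binomial(r_disp, p_nb, size=site_pos.size)
        if plant_site_mask.any():
            # planted bins are guaranteed observable in every subject so the
            # association filters never bind and read noise stays moderate
            cov[plant_site_mask] = np.maximum(cov[plant_site_mask], 15)
        n_meth = rng.binomial(cov, p_site)
        records[row.sample_id] = pd.DataFrame(
            {
                "chrom": site_chrom,
                "pos": site_pos,
                "n_meth": n_meth.astype(np.int64),
                "n_unmeth": (cov - n_meth).astype(np.int64),
                "sample_id": row.sample_id,
            }
        )

    truth = GroundTruth(planted=planted_rows)
    return Cohort(metadata=metadata, records=records, bins=bins, truth=truth)


# ---------------------------------------------------------------------------
# atlas and mixtures


@dataclass
class SimulatedMixtures:
    atlas: ReferenceAtlas
    beta: pd.DataFrame  # markers x samples
    true_weights: pd.DataFrame  # samples x cell types
    metadata: pd.DataFrame


def _default_mixture_metadata(n_low: int = 10, n_high: int = 10) -> pd.DataFrame:
    rows = []
    for i in range(n_low):
        rows.append((f"L{i + 1:02d}_C", f"L{i + 1:02d}", "female", "cfDNA", 1))
    for i in range(n_high):
        rows.append((f"H{i + 1:02d}_C", f"H{i + 1:02d}", "female", "cfDNA", 3))
    return validate_metadata(
        pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "sex", "sample_type", "fibrosis_stage"]
        )
    )


def generate_atlas_and_mixtures(
    config: SimulationConfig,
    metadata: pd.DataFrame | None = None,
) -> SimulatedMixtures:
    """Reference atlas plus noisy mixture samples with known weights.

    Marker betas sit near 0/1 with the configured separation between the
    owning cell type and the rest. Sample weights are Dirichlet draws; when
    ``atlas.hepatocyte_shift`` is non-zero, high-fibrosis samples get their
    hepatocyte weight raised so the group means differ by about the shift.
    """
    spec = config.atlas
    rng = _rng(config, 2)
    K, M = spec.n_cell_types, spec.n_markers
    if K < 2 or M < K:
        raise ValueError("atlas needs K >= 2 cell types and M >= K markers")
    if spec.low_max + spec.separation >= 1.0:
        raise ValueError(
            f"separation {spec.separation} infeasible with low_max {spec.low_max}"
        )
    cell_types = ["hepatocyte"] + [f"celltype_{i:02d}" for i in range(1, K)]
    owner = np.arange(M) % K
    A = rng.uniform(0.0, spec.low_max, size=(M, K))
    hi = rng.uniform(spec.low_max + spec.separation, 1.0, size=M)
    A[np.arange(M), owner] = hi
    marker_bins = tuple(f"m{i + 1:05d}" for i in range(M))
    atlas = ReferenceAtlas(cell_types=tuple(cell_types), marker_bins=marker_bins, A=A)

    if metadata is None:
        metadata = _default_mixture_metadata()
    samples = metadata["sample_id"].tolist()
    W = rng.dirichlet(np.full(K, spec.dirichlet_alpha), size=len(samples))
    if spec.hepatocyte_shift:
        delta_eff = spec.hepatocyte_shift / (1.0 - 1.0 / K)
        high = (metadata["fibrosis_stage"].to_numpy() >= 2)
        e_hep = np.zeros(K)
        e_hep[0] = 1.0
        W[high] = (1.0 - delta_eff) * W[high] + delta_eff * e_hep
    beta = A @ W.T + rng.normal(0.0, spec.noise_sd, size=(M, len(samples)))
    beta = np.clip(beta, 0.0, 1.0)
    return SimulatedMixtures(
        atlas=atlas,
        beta=pd.DataFrame(beta, index=list(marker_bins), columns=samples).rename_axis(
            "marker_bin"
        ),
        true_weights=pd.DataFrame(W, index=samples, columns=cell_types).rename_axis(
            "sample_id"
        ),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# transition-state fixtures for enrichment recovery


DEFAULT_TRANSITION_PROBS: dict[tuple[str, str], float] = {
    ("15_Quies", "15_Quies"): 0.28,
    ("9_Het", "9_Het"): 0.16,
    ("9_Het", "15_Quies"): 0.10,
    ("15_Quies", "9_Het"): 0.08,
    ("7_Enh", "15_Quies"): 0.08,
    ("15_Quies", "7_Enh"): 0.06,
    ("7_Enh", "7_Enh"): 0.08,
    ("5_TxWk", "5_TxWk"): 0.08,
    ("4_Tx", "4_Tx"): 0.05,
    ("1_TssA", "1_TssA"): 0.03,
}


def generate_transition_states(
    seed: int,
    n_assoc: int,
    n_background: int,
    base_probs: Mapping[tuple[str, str], float] | None = None,
    boost: Mapping[tuple[str, str], float] | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """State-pair draws for associated and background bins.

    Background pairs follow ``base_probs``; associated pairs follow the same
    distribution with the ``boost`` cells multiplied up and renormalized
    (e.g. ``{('7_Enh', '15_Quies'): 3.0}`` plants a 3x excess).
    """
    rng = np.random.default_rng(seed)
    probs = dict(base_probs or DEFAULT_TRANSITION_PROBS)
    cells = list(probs)
    p_bg = np.asarray([probs[c] for c in cells], dtype=float)
    p_bg = p_bg / p_bg.sum()
    p_as = p_bg.copy()
    for cell, factor in (boost or {}).items():
        if cell not in probs:
            raise ValueError(f"boosted cell {cell} not in base distribution")
        p_as[cells.index(cell)] *= factor
    p_as = p_as / p_as.sum()
    assoc_idx = rng.choice(len(cells), size=n_assoc, p=p_as)
    bg_idx = rng.choice(len(cells), size=n_background, p=p_bg)
    return [cells[i] for i in assoc_idx], [cells[i] for i in bg_idx]


# ---------------------------------------------------------------------------
# fixture emission


def _write_records_fast(df: pd.DataFrame, path: Path) -> None:
    """Cytosine-report writer operating on a record DataFrame."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,
            "strand": "+",
            "n_meth": df["n_meth"],
            "n_unmeth": df["n_unmeth"],
            "context": "CG",
            "tri": "CGN",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a complete fixture set and write it as plain-text files.

    Emits exactly the formats the readers consume: per-sample cytosine
    reports, a metadata TSV, gene/island/chromHMM BEDs, a BED12 transcript
    file, the atlas and marker beta matrices, and a ground-truth JSON.
    """
    from methbin.annotation import write_transcripts_bed12
    from methbin.deconvolution import write_atlas
    from methbin.io_formats import write_feature_bed, write_sample_metadata

    outdir = Path(outdir)
    (outdir / "reports").mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    cohort = generate_cohort(config, genome)
    mixtures = generate_atlas_and_mixtures(config, cohort.metadata)

    paths: dict[str, Path] = {}
    for sample_id, df in cohort.records.items():
        p = outdir / "reports" / f"{sample_id}.cov.txt"
        _write_records_fast(df, p)
        paths[f"report:{sample_id}"] = p
    paths["metadata"] = outdir / "metadata.tsv"
    write_sample_metadata(cohort.metadata, paths["metadata"])
    paths["genes"] = outdir / "genes.bed"
    write_feature_bed(genome.gene_track, paths["genes"])
    paths["transcripts"] = outdir / "transcripts.bed12"
    write_transcripts_bed12(genome.transcripts, paths["transcripts"])
    paths["islands"] = outdir / "islands.bed"
    write_feature_bed(genome.island_track, paths["islands"])
    for ct, track in genome.chromhmm_tracks.items():
        p = outdir / f"chromhmm_{ct}.bed"
        write_feature_bed(track, p)
        paths[f"chromhmm:{ct}"] = p
    paths["atlas"] = outdir / "atlas.tsv"
    write_atlas(mixtures.atlas, paths["atlas"])
    paths["marker_beta"] = outdir / "marker_beta.tsv"
    mixtures.beta.to_csv(paths["marker_beta"], sep="\t", float_format="%.8g")
    paths["true_weights"] = outdir / "true_weights.tsv"
    mixtures.true_weights.to_csv(paths["true_weights"], sep="\t", float_format="%.8g")
    paths["truth"] = outdir / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump({"planted": cohort.truth.planted}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
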