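from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methbin import association, binning
from methbin import group_intersection as gi
from methbin import io_formats as iof
from methbin import synthetic_data as sd


def label_planted(cohort):
    """Run beta -> screen -> label in memory; return labels keyed by bin_index."""
    matrix = binning.compute_bin_beta(cohort.records, cohort.bins)
    results = association.screen_all_groups(matrix, cohort.metadata)
    labels = gi.label_all_bins(results)
    return labels.set_index("bin_index")["label"]


class TestConfig:
    def test_default_margins_match_study(self, small_config):
        assert small_config.n_subjects == 38
        assert small_config.n_males == 18 and small_config.n_females == 20
        assert sum(small_config.fibrosis_male) == 18
        assert sum(small_config.fibrosis_female) == 20

    def test_bad_fibrosis_margins_rejected(self):
        with pytest.raises(ValueError, match="fibrosis_male"):
            sd.SimulationConfig(fibrosis_male=(1, 1, 1, 1, 1))

    def test_delta_bounds(self):
        with pytest.raises(ValueError, match="delta"):
            sd.PlantedEffect("Tissue", 0.3)

    def test_bad_label(self):
        with pytest.raises(ValueError, match="target_label"):
            sd.PlantedEffect("Plasma", 0.1)


class TestGenerateGenome:
    def test_deterministic(self, small_config):
        g1 = sd.generate_genome(small_config)
        g2 = sd.generate_genome(small_config)
        for chrom in g1.cpg_positions:
            np.testing.assert_array_equal(g1.cpg_positions[chrom], g2.cpg_positions[chrom])
        pd.testing.assert_frame_equal(g1.gene_track.df, g2.gene_track.df)
        pd.testing.assert_frame_equal(
            g1.chromhmm_tracks["GM12878"].df, g2.chromhmm_tracks["GM12878"].df
        )

    def test_distinct_seeds_distinct_data(self, small_config):
        other = sd.SimulationConfig(seed=small_config.seed + 1, n_cpgs=small_config.n_cpgs)
        g1 = sd.generate_genome(small_config)
        g2 = sd.generate_genome(other)
        assert not np.array_equal(g1.cpg_positions["chr1"], g2.cpg_positions["chr1"])

    def test_both_bin_categories_present(self, small_genome, small_config):
        bins = binning.build_bins(small_genome.cpg_positions, small_config.max_gap)
        sizes = [b.n_cpgs for b in bins]
        assert any(s >= 5 for s in sizes)
        assert any(s == 1 for s in sizes)

    def test_requested_site_count(self, small_genome, small_config):
        total = sum(len(p) for p in small_genome.cpg_positions.values())
        assert total == small_config.n_cpgs

    def test_chromhmm_tiles_genome(self, small_genome):
        for track in small_genome.chromhmm_tracks.values():
            for chrom, length in small_genome.chrom_lengths.items():
                seg = track.on_chrom(chrom)
                assert seg["start"].iloc[0] == 0
                assert seg["end"].iloc[-1] == length
                assert (seg["start"].to_numpy()[1:] == seg["end"].to_numpy()[:-1]).all()

    def test_empty_genome(self):
        cfg = sd.SimulationConfig(seed=1, n_cpgs=0)
        g = sd.generate_genome(cfg)
        assert sum(len(p) for p in g.cpg_positions.values()) == 0
        assert len(g.island_track) == 0

    def test_states_on_core15_grid(self, small_genome):
        from methbin.chromhmm_enrichment import CORE15_STATES

        for track in small_genome.chromhmm_tracks.values():
            assert set(track.df["state"]) <= set(CORE15_STATES)


class TestGenerateCohort:
    def test_metadata_margins(self, small_cohort):
        meta = small_cohort.metadata
        assert len(meta) == 32 + 36  # male, female samples
        male = meta[meta["sex"] == "male"]
        stages = male.drop_duplicates("subject_id")["fibrosis_stage"].value_counts()
        assert stages.to_dict() == {1: 7, 2: 7, 3: 3, 4: 1}
        paired = meta.groupby("subject_id")["sample_type"].nunique()
        assert (paired == 2).sum() == 30

    def test_deterministic(self, small_config, small_genome):
        c1 = sd.generate_cohort(small_config, small_genome)
        c2 = sd.generate_cohort(small_config, small_genome)
        pd.testing.assert_frame_equal(c1.metadata, c2.metadata)
        sid = c1.metadata["sample_id"].iloc[0]
        pd.testing.assert_frame_equal(c1.records[sid], c2.records[sid])

    def test_records_pass_io_validators(self, small_cohort, tmp_path):
        sid = small_cohort.metadata["sample_id"].iloc[0]
        df = small_cohort.records[sid]
        p = tmp_path / "r.txt"
        sd._write_records_fast(df, p)
        back = iof.records_to_frame(iof.read_cytosine_report(p, sid))
        pd.testing.assert_frame_equal(
            back, df.reset_index(drop=True), check_dtype=False
        )

    def test_null_cohort_calibrated(self):
        cfg = sd.SimulationConfig(seed=3, n_cpgs=6000)
        genome = sd.generate_genome(cfg)
        cohort = sd.generate_cohort(cfg, genome)
        matrix = binning.compute_bin_beta(cohort.records, cohort.bins)
        results = association.screen_all_groups(matrix, cohort.metadata)
        pooled = pd.concat(results.values())
        ok = pooled[~pooled["filtered"]]
        fpr = ok["significant"].mean()
        assert 0.02 <= fpr <= 0.08

    def test_planted_bin_recovered_with_label(self):
        effects = tuple(sd.PlantedEffect(lbl, 0.08) for lbl in ("Tissue", "Male", "All"))
        cfg = sd.SimulationConfig(seed=5, n_cpgs=2000, effects=effects)
        genome = sd.generate_genome(cfg)
        cohort = sd.generate_cohort(cfg, genome)
        labels = label_planted(cohort)
        got = {p["target_label"]: labels.loc[p["bin_index"]] for p in cohort.truth.planted}
        assert got["All"] == "All"
        assert got["Tissue"] in ("Tissue", "All")
        assert got["Male"] not in ("Female",)

    def test_planted_bins_pass_filters(self):
        effects = (sd.PlantedEffect("Female", 0.08, -1),)
        cfg = sd.SimulationConfig(seed=6, n_cpgs=2000, effects=effects)
        genome = sd.generate_genome(cfg)
        cohort = sd.generate_cohort(cfg, genome)
        matrix = binning.compute_bin_beta(cohort.records, cohort.bins)
        results = association.screen_all_groups(matrix, cohort.metadata)
        bin_index = cohort.truth.planted[0]["bin_index"]
        for g, res in results.items():
            row = res[res["bin_index"] == bin_index].iloc[0]
            assert not row["filtered"]

    def test_out_of_range_effect_count(self, small_genome):
        effects = tuple(sd.PlantedEffect("All", 0.05) for _ in range(10**4))
        cfg = sd.SimulationConfig(seed=5, n_cpgs=1500, effects=effects)
        with pytest.raises(ValueError, match="not enough"):
            sd.generate_cohort(cfg, small_genome)


class TestAtlasAndMixtures:
    def test_pure_weight_reproduces_column(self):
        cfg = sd.SimulationConfig(
            seed=9, atlas=sd.AtlasSpec(n_cell_types=2, n_markers=10, noise_sd=0.0)
        )
        mix = sd.generate_atlas_and_mixtures(cfg)
        w = mix.true_weights.to_numpy()
        beta = mix.beta.to_numpy()
        recon = mix.atlas.A @ w.T
        np.testing.assert_allclose(beta, np.clip(recon, 0, 1), atol=1e-12)

    def test_weights_sum_to_one(self):
        cfg = sd.SimulationConfig(seed=9)
        mix = sd.generate_atlas_and_mixtures(cfg)
        np.testing.assert_allclose(mix.true_weights.sum(axis=1), 1.0, atol=1e-12)

    def test_hepatocyte_shift_moves_group_means(self):
        cfg = sd.SimulationConfig(
            seed=10,
            atlas=sd.AtlasSpec(n_cell_types=10, n_markers=100, hepatocyte_shift=0.15),
        )
        mix = sd.generate_atlas_and_mixtures(cfg)
        high = mix.metadata["fibrosis_stage"] >= 2
        w = mix.true_weights["hepatocyte"]
        diff = w[high.to_numpy()].mean() - w[~high.to_numpy()].mean()
        assert diff == pytest.approx(0.15, abs=0.06)

    def test_separation_infeasible_rejected(self):
        cfg = sd.SimulationConfig(seed=9, atlas=sd.AtlasSpec(separation=0.99))
        with pytest.raises(ValueError, match="infeasible"):
            sd.generate_atlas_and_mixtures(cfg)

    def test_atlas_passes_separation_check(self):
        cfg = sd.SimulationConfig(seed=9)
        mix = sd.generate_atlas_and_mixtures(cfg)
        mix.atlas.check_separation(0.5)


class TestSimulateToDir:
    def test_fixture_set_complete_and_readable(self, tmp_path):
        cfg = sd.SimulationConfig(seed=2, n_cpgs=400)
        paths = sd.simulate_to_dir(cfg, tmp_path)
        meta = iof.read_sample_metadata(paths["metadata"])
        assert len(meta) == 68
        genes = iof.read_feature_bed(paths["genes"], "gene")
        assert len(genes) > 0
        track = iof.read_feature_bed(paths["chromhmm:GM12878"], "chromhmm")
        assert len(track) > 0
        from methbin.deconvolution import read_atlas

        atlas = read_atlas(paths["atlas"])
        assert atlas.n_cell_types == cfg.atlas.n_cell_types

    def test_byte_identical_on_rerun(self, tmp_path):
        cfg = sd.SimulationConfig(seed=2, n_cpgs=300)
        p1 = sd.simulate_to_dir(cfg, tmp_path / "a")
        p2 = sd.simulate_to_dir(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


class TestTransitionStates:
    def test_boost_shifts_distribution(self):
        a, b = sd.generate_transition_states(
            seed=1, n_assoc=5000, n_background=5000, boost={("7_Enh", "15_Quies"): 3.0}
        )
        f_assoc = sum(1 for c in a if c == ("7_Enh", "15_Quies")) / len(a)
        f_bg = sum(1 for c in b if c == ("7_Enh", "15_Quies")) / len(b)
        assert f_assoc > 2.0 * f_bg

    def test_unknown_boost_cell_rejected(self):
        with pytest.raises(ValueError, match="not in base distribution"):
            sd.generate_transition_states(1, 10, 10, boost={("1_TssA", "9_Het"): 2.0})
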