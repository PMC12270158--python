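from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import oracles
from methbin import annotation as ann
from methbin.binning import Bin
from methbin.io_formats import make_feature_track


def mkbin(start, end, chrom="chr1", idx=0):
    return Bin(bin_index=idx, chrom=chrom, start=start, end=end, cpg_positions=(start,))


def gene_track(rows):
    rows = sorted(rows, key=lambda r: (r[0], r[1]))
    return make_feature_track(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"]), "gene"
    )


def island_track(rows):
    return make_feature_track(pd.DataFrame(rows, columns=["chrom", "start", "end"]), "cpg_island")


def chromhmm_track(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    df["name"] = df["state"]
    return make_feature_track(df, "chromhmm")


class TestNearestGene:
    def test_downstream_gene(self):
        gt = gene_track([("chr1", 1000, 2000, "A", "+"), ("chr1", 5600, 6000, "B", "+")])
        gene, d = ann.nearest_gene(mkbin(5000, 5100), gt)
        assert (gene, d) == ("B", 500)

    def test_upstream_gene_negative(self):
        gt = gene_track([("chr1", 1000, 2000, "A", "+")])
        gene, d = ann.nearest_gene(mkbin(5000, 5100), gt)
        assert (gene, d) == ("A", -3000)

    def test_overlap_distance_zero(self):
        gt = gene_track([("chr1", 1000, 2000, "A", "+")])
        gene, d = ann.nearest_gene(mkbin(1500, 1600), gt)
        assert (gene, d) == ("A", 0)

    def test_alphabetical_tie_break(self):
        gt = gene_track([("chr1", 0, 100, "ZZZ", "+"), ("chr1", 500, 600, "AAA", "+")])
        # equidistant at 100 bp on both sides
        gene, d = ann.nearest_gene(mkbin(200, 400), gt)
        assert gene == "AAA" and abs(d) == 100

    def test_no_gene_on_chrom_warns(self):
        gt = gene_track([("chr2", 0, 100, "A", "+")])
        with pytest.warns(UserWarning, match="no gene"):
            gene, d = ann.nearest_gene(mkbin(0, 10), gt)
        assert gene is None and d is None

    def test_oracle_agreement_random(self, rng):
        for _ in range(200):
            genes = [
                (f"G{j:02d}", int(s), int(s) + int(rng.integers(50, 2000)))
                for j, s in enumerate(rng.integers(0, 50000, int(rng.integers(1, 20))))
            ]
            gt = gene_track([("chr1", s, e, n, "+") for n, s, e in genes])
            bs = int(rng.integers(0, 50000))
            be = bs + int(rng.integers(2, 300))
            got = ann.nearest_gene(mkbin(bs, be), gt)
            assert got == oracles.nearest_gene_oracle(bs, be, genes)


class TestClassifyRegion:
    def test_tss_window_strict(self):
        gt = gene_track([("chr1", 10000, 12000, "A", "+")])  # TSS at 10000
        near = ann.classify_region(mkbin(8500, 8600), gt)  # distance 10000-8599=1401
        assert near["near_tss"]
        exact_out = ann.classify_region(mkbin(8400, 8501), gt)  # distance 1500
        assert not exact_out["near_tss"]
        exact_in = ann.classify_region(mkbin(8400, 8502), gt)  # distance 1499
        assert exact_in["near_tss"]

    def test_tss_strand_aware(self):
        gt = gene_track([("chr1", 10000, 12000, "A", "-")])  # TSS at 11999
        res = ann.classify_region(mkbin(12100, 12200), gt)
        assert res["near_tss"]
        res_far = ann.classify_region(mkbin(13600, 13700), gt)  # 13699-11999 = 1700
        assert not res_far["near_tss"]

    def test_island_overlap(self):
        gt = gene_track([("chr1", 0, 10, "A", "+")])
        it = island_track([("chr1", 1000, 1200)])
        assert ann.classify_region(mkbin(1100, 1150), gt, it)["in_cpg_island"]
        assert not ann.classify_region(mkbin(1200, 1250), gt, it)["in_cpg_island"]

    def test_island_slop(self):
        gt = gene_track([("chr1", 0, 10, "A", "+")])
        it = island_track([("chr1", 1000, 1200)])
        res = ann.classify_region(mkbin(1250, 1300), gt, it, island_slop=100)
        assert res["in_cpg_island"]

    def test_intergenic_flag(self):
        gt = gene_track([("chr1", 1000, 2000, "A", "+")])
        assert ann.classify_region(mkbin(5000, 5100), gt)["intergenic"]
        assert not ann.classify_region(mkbin(1500, 1600), gt)["intergenic"]

    def test_first_intron_minus_strand(self):
        # minus-strand 2-exon gene: exons [1000,1500) and [3000,3500);
        # biological first exon is [3000,3500), first intron [1500,3000)
        gt = gene_track([("chr1", 1000, 3500, "A", "-")])
        tx = [ann.Transcript("A", "chr1", 1000, 3500, "-", ((1000, 1500), (3000, 3500)))]
        hit = ann.classify_region(mkbin(2000, 2100), gt, transcripts=tx)
        assert hit["first_exon_intron"]
        # the plus-strand reading of the same structure would call [1000,1500)
        # first; on minus strand a bin there is NOT in the first exon/intron
        miss = ann.classify_region(mkbin(1100, 1200), gt, transcripts=tx)
        assert not miss["first_exon_intron"]

    def test_first_exon_plus_strand(self):
        gt = gene_track([("chr1", 1000, 3500, "A", "+")])
        tx = [ann.Transcript("A", "chr1", 1000, 3500, "+", ((1000, 1500), (3000, 3500)))]
        assert ann.classify_region(mkbin(1100, 1200), gt, transcripts=tx)["first_exon_intron"]
        assert not ann.classify_region(mkbin(3100, 3200), gt, transcripts=tx)["first_exon_intron"]

    def test_track_order_independence(self):
        rows = [("chr1", 1000, 2000, "A", "+"), ("chr1", 3000, 4000, "B", "-")]
        res1 = ann.classify_region(mkbin(2400, 2500), gene_track(rows))
        res2 = ann.classify_region(mkbin(2400, 2500), gene_track(rows[::-1]))
        assert res1 == res2

    def test_intergenic_xor_overlapping(self, rng):
        gt = gene_track([("chr1", 1000, 2000, "A", "+"), ("chr1", 5000, 9000, "B", "-")])
        for _ in range(50):
            s = int(rng.integers(0, 10000))
            b = mkbin(s, s + int(rng.integers(1, 500)))
            res = ann.classify_region(b, gt)
            overlaps = (s < 2000 and b.end > 1000) or (s < 9000 and b.end > 5000)
            assert res["intergenic"] == (not overlaps)


class TestAssignChromhmmState:
    def test_fully_inside(self):
        track = chromhmm_track([("chr1", 0, 1000, "7_Enh"), ("chr1", 1000, 2000, "15_Quies")])
        assert ann.assign_chromhmm_state(mkbin(100, 200), track) == "7_Enh"

    def test_largest_overlap_wins(self):
        track = chromhmm_track([("chr1", 0, 1060, "7_Enh"), ("chr1", 1060, 2000, "15_Quies")])
        # bin [1000,1100): 60 bp Enh, 40 bp Quies
        assert ann.assign_chromhmm_state(mkbin(1000, 1100), track) == "7_Enh"

    def test_exact_tie_earlier_segment(self):
        track = chromhmm_track([("chr1", 0, 1050, "7_Enh"), ("chr1", 1050, 2000, "15_Quies")])
        assert ann.assign_chromhmm_state(mkbin(1000, 1100), track) == "7_Enh"

    def test_no_segment_is_na_with_warning(self):
        track = chromhmm_track([("chr2", 0, 1000, "7_Enh")])
        with pytest.warns(UserWarning, match="NA"):
            assert ann.assign_chromhmm_state(mkbin(0, 10), track) == "NA"


class TestAnnotateBins:
    def test_full_table(self):
        bins = [mkbin(1100, 1150, idx=0), mkbin(8000, 8100, idx=1)]
        gt = gene_track([("chr1", 1000, 2000, "A", "+")])
        it = island_track([("chr1", 1090, 1200)])
        tracks = {
            "GM12878": chromhmm_track([("chr1", 0, 9000, "9_Het")]),
            "HepG2": chromhmm_track([("chr1", 0, 9000, "15_Quies")]),
        }
        out = ann.annotate_bins(bins, gt, it, tracks)
        assert list(out["bin_index"]) == [0, 1]
        assert out.loc[0, "in_cpg_island"] and not out.loc[1, "in_cpg_island"]
        assert not out.loc[0, "intergenic"] and out.loc[1, "intergenic"]
        assert out.loc[1, "nearest_gene"] == "A"
        assert set(out["state_GM12878"]) == {"9_Het"}
        assert set(out["state_HepG2"]) == {"15_Quies"}

    def test_idempotent(self):
        bins = [mkbin(1100, 1150)]
        gt = gene_track([("chr1", 1000, 2000, "A", "+")])
        a = ann.annotate_bins(bins, gt)
        b = ann.annotate_bins(bins, gt)
        pd.testing.assert_frame_equal(a, b)


class TestSelectPathwayInput:
    def _fixture(self):
        labels = pd.DataFrame(
            {
                "bin_index": [0, 1, 2, 3, 4],
                "label": ["Tissue", "Tissue", "Tissue", "Tissue", "Tissue"],
            }
        )
        annotations = pd.DataFrame(
            {
                "bin_index": [0, 1, 2, 3, 4],
                "nearest_gene": ["G0", "G1", "G2", "G3", "G4"],
                "near_tss": [True, True, True, False, False],
                "in_cpg_island": [True, True, False, True, False],
                "intergenic": [False] * 5,
                "state_GM12878": ["1_TssA", "9_Het", "15_Quies", "9_Het", "9_Het"],
                "state_HepG2": ["15_Quies", "9_Het", "15_Quies", "9_Het", "9_Het"],
            }
        )
        return labels, annotations

    def test_tissue_strict_is_and(self):
        labels, annotations = self._fixture()
        genes = ann.select_pathway_input(labels, annotations, "tissue_strict", "Tissue")
        assert genes == ["G0", "G1"]

    def test_or_relaxed(self):
        labels, annotations = self._fixture()
        genes = ann.select_pathway_input(labels, annotations, "or_relaxed", "Tissue")
        assert genes == ["G0", "G1", "G2", "G3"]

    def test_extended_needs_small_p_and_state_difference(self):
        labels, annotations = self._fixture()
        results = {}
        pvals = {0: 0.005, 1: 0.005, 2: 0.5, 3: 0.005, 4: 0.005}
        for g in ("male_tissue", "male_cfDNA", "female_tissue", "female_cfDNA"):
            results[g] = pd.DataFrame(
                {"bin_index": list(pvals), "p_value": list(pvals.values())}
            )
        genes = ann.select_pathway_input(
            labels, annotations, "extended", "Tissue", results_by_group=results
        )
        # bin 0: p ok + states differ -> kept; bin 1: states equal; bin 2: p big;
        # bins 3, 4: states equal
        assert genes == ["G0"]

    def test_empty_selection_warns(self):
        labels, annotations = self._fixture()
        labels = labels.assign(label="cfDNA")
        with pytest.warns(UserWarning, match="no qualifying"):
            genes = ann.select_pathway_input(labels, annotations, "tissue_strict", "Tissue")
        assert genes == []

    def test_unknown_mode_rejected(self):
        labels, annotations = self._fixture()
        with pytest.raises(ValueError, match="mode"):
            ann.select_pathway_input(labels, annotations, "bogus", "Tissue")


class TestTranscriptIO:
    def test_bed12_round_trip(self, tmp_path):
        tx = [
            ann.Transcript("A", "chr1", 100, 1000, "+", ((100, 200), (400, 500), (900, 1000))),
            ann.Transcript("B", "chr2", 0, 300, "-", ((0, 100), (200, 300))),
        ]
        p = tmp_path / "tx.bed12"
        ann.write_transcripts_bed12(tx, p)
        back = ann.read_transcripts_bed12(p)
        assert back == tx

    def test_gtf_conversion(self, tmp_path):
        gtf = (
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "A"; transcript_id "A.1"; gene_name "A";\n'
            'chr1\tx\texon\t401\t500\t.\t+\t.\tgene_id "A"; transcript_id "A.1"; gene_name "A";\n'
        )
        p = tmp_path / "x.gtf"
        p.write_text(gtf)
        (tx,) = ann.gtf_to_transcripts(p)
        assert tx.gene == "A" and tx.exons == ((100, 200), (400, 500))

    def test_gene_track_collapse(self):
        tx = [
            ann.Transcript("A", "chr1", 100, 500, "+", ((100, 500),)),
            ann.Transcript("A", "chr1", 50, 400, "+", ((50, 400),)),
        ]
        df = ann.transcripts_to_gene_track(tx)
        assert df.loc[0, "start"] == 50 and df.loc[0, "end"] == 500
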