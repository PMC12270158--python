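"""Acceptance-criterion measurements shared by the test suite and report script.

Each function runs one criterion's experiment from scratch against the
package under test and returns a dict of measured quantities; the acceptance
tests assert the thresholds, and ``scripts/acceptance.py`` serialises the
numbers. All randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np
import pandas as pd

import oracles
from methbin import association, binning
from methbin import chromhmm_enrichment as ce
from methbin import deconvolution as dc
from methbin import group_intersection as gi
from methbin import synthetic_data as sd
from methbin.annotation import nearest_gene
from methbin.binning import Bin
from methbin.io_formats import make_feature_track


# 1 -------------------------------------------------------------------------


def binning_oracle(seed: int, n_sets: int = 1000, max_sites: int = 5000) -> dict:
    rng = np.random.default_rng(seed)
    n_agree = 0
    total_sites = 0
    for i in range(n_sets):
        if i < 3:
            n = max_sites  # a few sets at the size cap
        else:
            n = int(np.exp(rng.uniform(np.log(2), np.log(max_sites))))
        scale = int(rng.choice([20, 80, 300]))
        pos = np.unique(rng.integers(0, n * scale, n))
        total_sites += pos.size
        bins = binning.build_bins({"chr1": pos})
        expected = oracles.brute_force_bins(pos, 65)
        if [list(b.cpg_positions) for b in bins] == expected:
            n_agree += 1
    boundary_ok = (
        len(binning.build_bins({"chr1": [0, 64]})) == 1
        and len(binning.build_bins({"chr1": [0, 65]})) == 2
    )
    return {
        "n_sets": n_sets,
        "n_agree": n_agree,
        "total_sites": total_sites,
        "boundary_ok": boundary_ok,
    }


# 2 -------------------------------------------------------------------------


def kendall_oracle(seed: int, n_vectors: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    n_tau_ok = 0
    n_p_ok = 0
    max_tau_err = 0.0
    max_p_err = 0.0
    done = 0
    while done < n_vectors:
        n = int(rng.integers(3, 31))
        x = rng.integers(0, 8, n).astype(float)
        y = rng.integers(0, 8, n).astype(float)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            continue
        done += 1
        tau, p = association.kendall_tau_b(x, y)
        tau_err = abs(tau - oracles.kendall_tau_b_oracle(x, y))
        p_err = abs(p - oracles.kendall_p_oracle(x, y))
        max_tau_err = max(max_tau_err, tau_err)
        max_p_err = max(max_p_err, p_err)
        n_tau_ok += tau_err <= 1e-12
        n_p_ok += p_err <= 1e-9
    return {
        "n_vectors": n_vectors,
        "n_tau_ok": n_tau_ok,
        "n_p_ok": n_p_ok,
        "max_tau_err": max_tau_err,
        "max_p_err": max_p_err,
    }


# 3 -------------------------------------------------------------------------

MT, MC, FT, FC = gi.BASE_GROUPS

INTERSECTION_TRUTH = {
    frozenset(): "none",
    frozenset({MT}): "none",
    frozenset({MC}): "none",
    frozenset({FT}): "none",
    frozenset({FC}): "none",
    frozenset({MT, FT}): "Tissue",
    frozenset({MC, FC}): "cfDNA",
    frozenset({MT, MC}): "Male",
    frozenset({FT, FC}): "Female",
    frozenset({MT, FC}): "none",
    frozenset({MC, FT}): "none",
    frozenset({MT, MC, FT}): "Tissue",
    frozenset({MT, MC, FC}): "cfDNA",
    frozenset({MT, FT, FC}): "Tissue",
    frozenset({MC, FT, FC}): "cfDNA",
    frozenset({MT, MC, FT, FC}): "All",
}


def intersection_truth_table() -> dict:
    subsets = [
        frozenset(c)
        for c in chain.from_iterable(combinations(gi.BASE_GROUPS, k) for k in range(5))
    ]
    n_agree = sum(
        gi.assign_label(s).label == INTERSECTION_TRUTH[s] for s in subsets
    )
    return {"n_subsets": len(subsets), "n_agree": n_agree}


# 4 -------------------------------------------------------------------------


def null_calibration(seed: int, n_cpgs: int = 60000, min_bins: int = 10000) -> dict:
    cfg = sd.SimulationConfig(seed=seed, n_cpgs=n_cpgs, n_chromosomes=4)
    genome = sd.generate_genome(cfg)
    cohort = sd.generate_cohort(cfg, genome)
    matrix = binning.compute_bin_beta(cohort.records, cohort.bins)
    results = association.screen_all_groups(matrix, cohort.metadata)
    pooled = pd.concat(results.values())
    ok = pooled[~pooled["filtered"]]
    return {
        "n_bins": len(cohort.bins),
        "min_bins_required": min_bins,
        "n_tests": len(ok),
        "fpr": float(ok["significant"].mean()),
    }


# 5 -------------------------------------------------------------------------


def planted_label_recovery(
    seed: int, n_replicates: int = 50, bins_per_label: int = 2, delta: float = 0.08
) -> dict:
    labels = ("Tissue", "cfDNA", "Male", "Female", "All")
    n_correct = {l: 0 for l in labels}
    n_total = {l: 0 for l in labels}
    cross_sex = 0
    for rep in range(n_replicates):
        effects = tuple(
            sd.PlantedEffect(l, delta) for l in labels for _ in range(bins_per_label)
        )
        cfg = sd.SimulationConfig(seed=seed + rep, n_cpgs=2000, effects=effects)
        genome = sd.generate_genome(cfg)
        cohort = sd.generate_cohort(cfg, genome)
        matrix = binning.compute_bin_beta(cohort.records, cohort.bins)
        results = association.screen_all_groups(matrix, cohort.metadata)
        got = gi.label_all_bins(results).set_index("bin_index")["label"]
        for p in cohort.truth.planted:
            target = p["target_label"]
            found = got.loc[p["bin_index"]]
            n_total[target] += 1
            n_correct[target] += found == target
            if (target, found) in (("Male", "Female"), ("Female", "Male")):
                cross_sex += 1
    return {
        "n_replicates": n_replicates,
        "n_planted": sum(n_total.values()),
        "n_correct": sum(n_correct.values()),
        "recovery": sum(n_correct.values()) / sum(n_total.values()),
        "per_label": {l: n_correct[l] / n_total[l] for l in labels},
        "cross_sex_confusions": cross_sex,
    }


# 6 -------------------------------------------------------------------------


def annotation_oracle(seed: int, n_instances: int = 500) -> dict:
    from methbin.annotation import classify_region

    rng = np.random.default_rng(seed)
    n_agree = 0
    for _ in range(n_instances):
        n_genes = int(rng.integers(1, 25))
        genes = []
        for j, s in enumerate(np.sort(rng.integers(0, 100000, n_genes))):
            genes.append((f"G{j:03d}", int(s), int(s) + int(rng.integers(50, 3000))))
        track = make_feature_track(
            pd.DataFrame(
                [("chr1", s, e, n, "+") for n, s, e in genes],
                columns=["chrom", "start", "end", "name", "strand"],
            ),
            "gene",
        )
        bs = int(rng.integers(0, 100000))
        b = Bin(0, "chr1", bs, bs + int(rng.integers(2, 500)), (bs,))
        if nearest_gene(b, track) == oracles.nearest_gene_oracle(b.start, b.end, genes):
            n_agree += 1
    # TSS window strictness: TSS at 10000, bin end at 8501 -> distance 1500 (out),
    # bin end 8502 -> 1499 (in)
    track = make_feature_track(
        pd.DataFrame(
            [("chr1", 10000, 12000, "A", "+")],
            columns=["chrom", "start", "end", "name", "strand"],
        ),
        "gene",
    )
    tss_ok = (
        classify_region(Bin(0, "chr1", 8400, 8502, (8400,)), track)["near_tss"]
        and not classify_region(Bin(0, "chr1", 8400, 8501, (8400,)), track)["near_tss"]
    )
    return {"n_instances": n_instances, "n_agree": n_agree, "tss_strictness_ok": tss_ok}


# 7 -------------------------------------------------------------------------


def chromhmm_recovery(seed: int, n_replicates: int = 50) -> dict:
    boost_cell = ("7_Enh", "15_Quies")
    n_only = 0
    for rep in range(n_replicates):
        a_states, b_states = sd.generate_transition_states(
            seed=seed + rep, n_assoc=600, n_background=4000, boost={boost_cell: 3.0}
        )
        assoc = ce.build_transition_table(*zip(*a_states), group="associated")
        bg = ce.build_transition_table(*zip(*b_states), group="background")
        flagged = ce.compute_enrichment(assoc, bg).flagged()
        hit = bool(flagged.loc[boost_cell])
        only = int(flagged.to_numpy().sum()) == 1
        n_only += hit and only
    # constructed 29-bin low-support fixture
    assoc = ce.build_transition_table(
        ["7_Enh"] * 29 + ["9_Het"] * 971,
        ["15_Quies"] * 29 + ["9_Het"] * 971,
        "associated",
    )
    bg = ce.build_transition_table(
        ["7_Enh"] * 10 + ["9_Het"] * 990,
        ["15_Quies"] * 10 + ["9_Het"] * 990,
        "background",
    )
    res = ce.compute_enrichment(assoc, bg)
    low_support_ok = (
        bool(res.enriched.loc["7_Enh", "15_Quies"])
        and bool(res.low_support.loc["7_Enh", "15_Quies"])
        and not bool(res.flagged().loc["7_Enh", "15_Quies"])
    )
    return {
        "n_replicates": n_replicates,
        "n_only_planted_flagged": n_only,
        "recovery": n_only / n_replicates,
        "low_support_fixture_ok": low_support_ok,
    }


# 8 -------------------------------------------------------------------------


def deconvolution_recovery(seed: int, n_mixtures: int = 100, n_shift_reps: int = 100) -> dict:
    # weight recovery on noisy mixtures
    meta = sd._default_mixture_metadata(n_mixtures // 2, n_mixtures - n_mixtures // 2)
    cfg = sd.SimulationConfig(
        seed=seed, atlas=sd.AtlasSpec(n_cell_types=10, n_markers=500, noise_sd=0.02)
    )
    mix = sd.generate_atlas_and_mixtures(cfg, meta)
    props = dc.estimate_proportions_matrix(mix.atlas, mix.beta)
    w_hat = props[list(mix.atlas.cell_types)].to_numpy()
    mae = float(np.abs(w_hat - mix.true_weights.to_numpy()).mean())

    # closed-form cases
    atlas_A = np.zeros((10, 2))
    atlas_A[::2, 0] = 1.0
    atlas_A[1::2, 1] = 1.0
    atlas = dc.ReferenceAtlas(("a", "b"), tuple(f"m{i}" for i in range(10)), atlas_A)
    pure = dc.estimate_proportions(atlas, atlas_A[:, 0]).w
    sym = dc.estimate_proportions(atlas, np.full(10, 0.5)).w
    exact_ok = bool(
        np.allclose(pure, [1.0, 0.0], atol=1e-6) and np.allclose(sym, [0.5, 0.5], atol=1e-6)
    )

    # fibrosis-linked hepatocyte shift detected end to end
    n_sig = 0
    for rep in range(n_shift_reps):
        cfg = sd.SimulationConfig(
            seed=seed + 1 + rep,
            atlas=sd.AtlasSpec(
                n_cell_types=10, n_markers=200, noise_sd=0.02, hepatocyte_shift=0.15
            ),
        )
        m = sd.generate_atlas_and_mixtures(cfg)  # 10 low / 10 high samples
        p_hat = dc.estimate_proportions_matrix(m.atlas, m.beta)
        p = dc.compare_proportions_by_fibrosis(p_hat, m.metadata, "hepatocyte")
        n_sig += p < 0.05
    return {
        "n_mixtures": n_mixtures,
        "mae": mae,
        "exact_cases_ok": exact_ok,
        "n_shift_reps": n_shift_reps,
        "shift_power": n_sig / n_shift_reps,
    }


# 9 -------------------------------------------------------------------------


def wilcoxon_oracle(seed: int, reps_per_split: int = 5) -> dict:
    rng = np.random.default_rng(seed)
    n_ok = 0
    n_total = 0
    max_err = 0.0
    for n in range(2, 9):
        for n1 in range(1, n):
            for _ in range(reps_per_split):
                vals = rng.permutation(100)[:n].astype(float)
                a, b = vals[:n1], vals[n1:]
                p = association.wilcoxon_rank_sum(a, b)
                p_exp = oracles.wilcoxon_exact_oracle(a, b)
                err = abs(p - p_exp)
                max_err = max(max_err, err)
                n_total += 1
                n_ok += err <= 1e-12
    return {"n_cases": n_total, "n_agree": n_ok, "max_err": max_err}
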