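"""Generator behaviour: allele presets, population truth, read counts,
cytology tables — determinism, calibration and the documented invariants."""

import numpy as np
import pandas as pd
import pytest

from meiostab import simulate as sim
from meiostab.alleles import read_fasta
from meiostab.cytology import chiasma_summary
from meiostab.simulate import (
    CytoModelParams,
    GeneSpec,
    SizingError,
    build_allele_set,
    expected_derived_fraction,
    simulate_cytology,
    simulate_population,
    simulate_read_counts,
    structural_pair,
)

COUNT_COLS = ["count_A", "count_C", "count_G", "count_T"]


class TestGeneSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            GeneSpec("g", 100)  # not divisible by 3
        with pytest.raises(ValueError):
            GeneSpec("g", 300, n_diagnostic_sites=0)
        with pytest.raises(ValueError):
            GeneSpec("g", 300, divergence_lyr_are=1.5)
        with pytest.raises(SizingError):
            GeneSpec("g", 300, sv_preset="ZYP1b_GC")  # too short for the tract


class TestAlleleSets:
    def test_plain_preset_differs_only_at_snps(self):
        spec = GeneSpec("REC8", 900, n_diagnostic_sites=5)
        aset = build_allele_set(spec, seed=7)
        ly = aset.by_id("REC8_ly2").sequence
        derived = aset.by_id("REC8_4n").sequence
        diffs = [i + 1 for i, (a, b) in enumerate(zip(ly, derived)) if a != b]
        assert diffs == [s.position for s in aset.diag_sites]
        assert len(diffs) == 5
        for s in aset.diag_sites:
            assert derived[s.position - 1] == s.derived_base
            assert ly[s.position - 1] == s.ancestral_base

    def test_td_allele_longer_by_78(self, asy3_td_set):
        ref, alt = asy3_td_set.event["ref"], asy3_td_set.event["alt"]
        assert len(alt) - len(ref) == 78

    def test_del_preset_removes_unit(self):
        spec = GeneSpec("ASY3", 2382, sv_preset="ASY3_DEL")
        ref, alt = structural_pair(spec, seed=1)
        assert len(ref) - len(alt) == 78
        ev = build_allele_set(spec, seed=1).event
        u0 = ev["unit_start"] - 1
        assert alt.sequence == ref.sequence[:u0] + ref.sequence[u0 + 78 :]

    def test_prd3_segment_ancestry_by_direct_column_scan(self, prd3_set):
        """First-segment diagnostic columns match arenosa, later ones lyrata."""
        ev = prd3_set.event
        q, ar, ly = ev["query"].sequence, ev["parent_a"].sequence, ev["parent_b"].sequence
        j = ev["breakpoint"]
        left = [i for i in range(j) if ar[i] != ly[i]]
        right = [i for i in range(j, len(q)) if ar[i] != ly[i]]
        left_ar = sum(q[i] == ar[i] for i in left)
        right_ly = sum(q[i] == ly[i] for i in right)
        assert (len(left) - left_ar, len(right) - right_ly) == (7, 5)
        assert left_ar == 21 and right_ly == 24

    def test_determinism_and_seed_sensitivity(self):
        spec = sim.DEFAULT_GENES["ASY3"]
        a = build_allele_set(spec, seed=5)
        b = build_allele_set(spec, seed=5)
        assert [x.sequence for x in a.alleles] == [x.sequence for x in b.alleles]
        assert a.diag_sites == b.diag_sites
        c = build_allele_set(spec, seed=6)
        assert [x.sequence for x in a.alleles] != [x.sequence for x in c.alleles]


class TestPopulation:
    def test_degenerate_frequencies_all_hom(self):
        truth = simulate_population(10, {"ASY3": (1.0, 0.0, 0.0)}, seed=0)
        assert (truth.genotypes["dosage"] == 4).all()
        assert (truth.genotypes["genotype_class"] == "HOM_DERIVED").all()

    def test_default_asy3_split_near_41_11(self):
        sizes = []
        for s in range(20):
            truth = simulate_population(52, seed=s)
            counts = truth.genotypes.query("gene=='ASY3'")["genotype_class"].value_counts()
            sizes.append(counts.get("HOM_DERIVED", 0))
        assert abs(np.mean(sizes) - 41) < 2.5

    def test_truth_invariants(self):
        truth = simulate_population(40, seed=3)
        assert truth.plants["stability_pi"].between(0, 1).all()
        g = truth.genotypes
        assert g["dosage"].between(0, 4).all()
        assert (g.loc[g["dosage"] == 4, "genotype_class"] == "HOM_DERIVED").all()
        assert (g.loc[g["dosage"] == 0, "genotype_class"] == "HOM_ANCESTRAL").all()
        assert (g.loc[g["dosage"].isin([1, 2, 3]), "genotype_class"] == "HET").all()

    def test_seed_determinism(self):
        a = simulate_population(20, seed=9)
        b = simulate_population(20, seed=9)
        pd.testing.assert_frame_equal(a.plants, b.plants)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_population(0)
        with pytest.raises(ValueError):
            simulate_population(5, {"ASY3": (0.5, 0.2, 0.2)})


def _one_gene_truth(dosage, n_sites, gene="G"):
    plants = pd.DataFrame(
        {"plant_id": ["P1"], "population": ["LIC"], "causal_class": ["HET"],
         "stability_pi": [0.8]}
    )
    genos = pd.DataFrame(
        {"plant_id": ["P1"], "gene": [gene], "dosage": [dosage],
         "genotype_class": ["HET" if dosage in (1, 2, 3) else "HOM_DERIVED"]}
    )
    sites = [sim.DiagnosticSiteTruth(i + 1, "G", "A") for i in range(n_sites)]
    return sim.TruthTable(plants, genos, gene), {gene: sites}


class TestReadCounts:
    def test_counts_sum_to_depth(self, small_population):
        _, _, counts = small_population
        assert (counts[COUNT_COLS].sum(axis=1) == counts["depth"]).all()
        assert (counts["depth"] == 500).all()

    def test_error_free_saturated_dosage(self):
        truth, sites = _one_gene_truth(4, 5)
        counts = simulate_read_counts(truth, sites, depth=300, error_rate=0.0, seed=0)
        assert (counts["count_G"] == 300).all()

    def test_zero_depth_zero_counts(self):
        truth, sites = _one_gene_truth(2, 3)
        counts = simulate_read_counts(truth, sites, depth=0, error_rate=0.01, seed=0)
        assert (counts[COUNT_COLS + ["depth"]] == 0).all().all()

    def test_dosage2_mean_fraction_near_half(self):
        truth, sites = _one_gene_truth(2, 200)
        counts = simulate_read_counts(truth, sites, depth=2000, error_rate=0.0, seed=12)
        frac = counts["count_G"] / counts["depth"]
        se = np.sqrt(0.25 / 2000 / 200)
        assert abs(frac.mean() - 0.5) < 3 * se

    def test_high_depth_fraction_converges_to_p_d(self):
        for d in range(5):
            truth, sites = _one_gene_truth(d, 20)
            counts = simulate_read_counts(truth, sites, depth=100_000,
                                          error_rate=0.01, seed=d)
            p = expected_derived_fraction(d, 0.01)
            frac = (counts["count_G"] / counts["depth"]).mean()
            se = np.sqrt(max(p * (1 - p), 1e-6) / 100_000 / 20)
            assert abs(frac - p) < 3 * se

    def test_determinism(self):
        truth, sites = _one_gene_truth(3, 10)
        a = simulate_read_counts(truth, sites, 100, 0.01, seed=4)
        b = simulate_read_counts(truth, sites, 100, 0.01, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_bad_error_rate(self):
        truth, sites = _one_gene_truth(1, 3)
        with pytest.raises(ValueError):
            simulate_read_counts(truth, sites, 100, 0.3, seed=0)


class TestCytology:
    def test_pi_one_gives_full_stability(self):
        truth = simulate_population(5, {"ASY3": (1.0, 0.0, 0.0)}, seed=1)
        truth.plants["stability_pi"] = 1.0
        cyto = simulate_cytology(truth, n_cells_per_plant=20, seed=1)
        assert (cyto.cells["n_bivalents_scored"] == 16).all()
        assert (~cyto.cells["multivalent_present"]).all()

    @pytest.mark.parametrize(
        "group,n,target", [("diploid", 312, 1.52), ("stable_4n", 960, 1.12),
                           ("unstable_4n", 590, 1.26)]
    )
    def test_group_chiasma_means_match_calibration(self, group, n, target):
        biv = sim.simulate_group_bivalents(group, n, seed=5)
        s = chiasma_summary(biv)
        se = float(s["sd_chiasmata"][0]) / np.sqrt(n)
        assert abs(float(s["mean_chiasmata"][0]) - target) < 3 * se

    def test_hei10_mean_near_20_4_for_stable_plants(self):
        truth = simulate_population(30, {"ASY3": (1.0, 0.0, 0.0)}, seed=2)
        truth.plants["stability_pi"] = 0.95
        cyto = simulate_cytology(truth, n_cells_per_plant=30, seed=2)
        mean = cyto.hei10["foci"].mean()
        # E = 16 * (1 + 0.275) = 20.4; var per cell = 16 * 0.275
        se = np.sqrt(16 * 0.275 / len(cyto.hei10))
        assert abs(mean - 20.4) < 3 * se

    def test_45s_classes_underrepresented_in_unstable_cells(self):
        truth = simulate_population(40, {"ASY3": (0.0, 1.0, 0.0)}, seed=3)
        truth.plants["stability_pi"] = 0.05
        cyto = simulate_cytology(truth, n_cells_per_plant=25, seed=3)
        unstable_cells = cyto.cells.loc[cyto.cells["multivalent_present"],
                                        ["plant_id", "cell_id"]]
        biv = cyto.bivalents.merge(unstable_cells, on=["plant_id", "cell_id"])
        frac_45s = biv["rdna_class"].isin(["fortyfiveS", "both"]).mean()
        assert frac_45s < 4 / 16  # karyotype proportion of 45S-bearing pairs

    def test_determinism(self):
        truth = simulate_population(4, seed=8)
        a = simulate_cytology(truth, n_cells_per_plant=10, seed=8)
        b = simulate_cytology(truth, n_cells_per_plant=10, seed=8)
        pd.testing.assert_frame_equal(a.bivalents, b.bivalents)
        pd.testing.assert_frame_equal(a.hei10, b.hei10)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            CytoModelParams(karyotype=(7, 5, 2, 3))
        with pytest.raises(ValueError):
            CytoModelParams(extra_rates={"diploid": (-0.1, 0, 0),
                                         "stable_4n": (0, 0, 0),
                                         "unstable_4n": (0, 0, 0)})


def test_write_run_produces_expected_files(tmp_path, small_population):
    truth, sites, counts = small_population
    sets = [sim.build_allele_set(sim.DEFAULT_GENES[g], 42) for g in sites]
    cyto = simulate_cytology(truth, n_cells_per_plant=5, seed=42)
    sim.write_run(tmp_path, sets, truth, counts, cyto)
    for name in ["alleles.fasta", "snp_counts.tsv", "truth.tsv", "cells.tsv",
                 "bivalents.tsv", "hei10.tsv"]:
        assert (tmp_path / name).exists()
    alleles = read_fasta(tmp_path / "alleles.fasta")
    assert {a.gene for a in alleles} == set(sites)
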