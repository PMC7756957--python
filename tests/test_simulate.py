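"""Generator truth: determinism, planted geometry, and sampling oracles."""

import numpy as np
import pandas as pd
import pytest

from epiphase.simulate import (
    ChipSimSpec,
    GenomeSpec,
    GenotypeProfile,
    InsertionSimSpec,
    build_genome,
    reference_cytosines,
    simulate_chip_experiment,
    simulate_insertions_and_reads,
    simulate_methylome,
)


class TestBuildGenome:
    def test_seeded_determinism(self):
        spec = GenomeSpec(chromosome_length=100_000, te_count=8, gene_count=8)
        g1, g2 = build_genome(spec, seed=4), build_genome(spec, seed=4)
        assert g1.sequences == g2.sequences
        assert g1.linker_patches.equals(g2.linker_patches)
        assert g1.nucleosomes == g2.nucleosomes

    def test_pericentromere_fraction_of_tes(self, small_genome):
        tes = list(small_genome.features.tes())
        frac = sum(f.compartment == "pericentromeric" for f in tes) / len(tes)
        # TEs place uniformly, so the pericentromeric share tracks the
        # declared 0.4 span fraction up to packing granularity (n=20)
        assert 0.4 - 3 * np.sqrt(0.4 * 0.6 / len(tes)) <= frac <= 0.4 + 3 * np.sqrt(0.4 * 0.6 / len(tes))

    def test_nucleosome_count_and_spacing_on_10kb_te(self):
        spec = GenomeSpec(
            chromosome_length=40_000,
            te_count=1,
            te_length_range=(10_000, 10_000),
            gene_count=0,
            pericentromere_fraction=0.0,
            centromere_fraction=0.0,
            families={"LTR/Gypsy": 10_000},
        )
        g = build_genome(spec, seed=2)
        centers = g.nucleosomes.centers["chr1"]
        assert len(centers) in (66, 67)
        assert set(np.diff(centers)) == {150}

    def test_patches_never_intersect_cores_default_geometry(self, small_genome):
        half_core = small_genome.spec.core_width // 2
        core = np.zeros(len(small_genome.sequences["chr1"]), dtype=bool)
        for c in small_genome.nucleosomes.centers["chr1"]:
            core[c - half_core : c + half_core] = True
        for rec in small_genome.linker_patches.itertuples(index=False):
            assert not core[rec.start : rec.end].any()

    def test_infeasible_packing_raises(self):
        spec = GenomeSpec(chromosome_length=20_000, te_count=10, te_length_range=(5000, 6000))
        with pytest.raises(ValueError, match="packing"):
            build_genome(spec, seed=0)

    def test_core_width_must_fit_repeat_length(self):
        with pytest.raises(ValueError):
            GenomeSpec(nrl=140, core_width=150)


class TestReferenceCytosines:
    def test_contexts_on_both_strands(self):
        #        0123456789
        seq = "ACGTACCGTT"
        cyt = reference_cytosines(seq, "chr1")
        plus = cyt[cyt["strand"] == "+"].set_index("pos")["context"]
        assert plus.loc[1] == "CG"  # C at 1 followed by G
        assert plus.loc[5] == "CHG"  # C-C-G
        assert plus.loc[6] == "CG"
        minus = cyt[cyt["strand"] == "-"].set_index("pos")["context"]
        assert minus.loc[2] == "CG"  # G at 2 pairs with the CG at 1/2
        assert minus.loc[7] == "CG"


class TestSimulateMethylome:
    def test_degenerate_zero_baselines(self, small_genome):
        zero = {c: {r: 0.0 for r in ("intergenic", "gene", "te_arm", "te_peri")} for c in ("CG", "CHG", "CHH")}
        m = simulate_methylome(small_genome, GenotypeProfile("null", zero, coverage=5), seed=9)
        assert int(m.frame["n_meth"].sum()) == 0

    def test_wt_peri_cg_matches_binomial_oracle(self, small_genome, wt_methylome):
        peri = [
            f for f in small_genome.features.tes() if f.compartment == "pericentromeric"
        ]
        mask = np.zeros(len(small_genome.sequences["chr1"]), dtype=bool)
        for f in peri:
            mask[f.interval.start : f.interval.end] = True
        cg = wt_methylome.subset_context("CG").frame
        sel = cg[mask[cg["pos"].to_numpy()]]
        n_meth, n_total = sel["n_meth"].sum(), sel["n_total"].sum()
        assert n_total > 20_000 * 5  # plenty of sites at 30x
        p_hat = n_meth / n_total
        sd = np.sqrt(0.85 * 0.15 / n_total)
        assert abs(p_hat - 0.85) <= 3 * sd + 1e-3

    def test_linker_gain_matches_planted_truth(self, small_genome, ddm1clf_methylome, ddm1_methylome):
        in_patch = np.zeros(len(small_genome.sequences["chr1"]), dtype=bool)
        for rec in small_genome.linker_patches.itertuples(index=False):
            in_patch[rec.start : rec.end] = True
        gain = GenotypeProfile.ddm1_clf().linker_gain["CG"]
        cg = ddm1clf_methylome.subset_context("CG").frame
        pm = in_patch[cg["pos"].to_numpy()]
        p_in = cg[pm]["n_meth"].sum() / cg[pm]["n_total"].sum()
        ref = ddm1_methylome.subset_context("CG").frame
        pm_ref = in_patch[ref["pos"].to_numpy()]
        p_ref = ref[pm_ref]["n_meth"].sum() / ref[pm_ref]["n_total"].sum()
        assert abs((p_in - p_ref) - gain) < 0.02


class TestSimulateChip:
    def test_equal_multipliers_equal_libraries_ratio_one(self, small_genome):
        ids = small_genome.features.tes().ids()
        spec = ChipSimSpec({i: 2.0 for i in ids})
        c1, _ = simulate_chip_experiment(small_genome, spec, seed=5, library_id="x")
        c2, _ = simulate_chip_experiment(small_genome, spec, seed=6, library_id="y")
        ratio = (c1["count"] + 1) / (c2["count"] + 1)
        assert abs(np.median(ratio) - 1.0) < 0.15

    def test_spikein_tally_binomial_oracle(self, small_genome):
        ids = small_genome.features.tes().ids()
        lengths = sum(len(small_genome.features[i].interval) for i in ids)
        # spike mass chosen so the expected spike-in read share is 5%
        spec = ChipSimSpec(
            {i: 1.0 for i in ids},
            library_size=1_000_000,
            spikein_mass=lengths * 0.05 / 0.95,
        )
        _, st = simulate_chip_experiment(small_genome, spec, seed=8)
        sd = np.sqrt(1_000_000 * 0.05 * 0.95)
        assert abs(st.nd_ip - 50_000) <= 3 * sd

    def test_zero_multiplier_gives_zero_counts(self, small_genome):
        ids = small_genome.features.tes().ids()
        mult = {i: 1.0 for i in ids}
        mult[ids[0]] = 0.0
        for seed in (1, 2, 3):
            c, _ = simulate_chip_experiment(small_genome, ChipSimSpec(mult), seed=seed)
            assert int(c.set_index("feature_id").loc[ids[0], "count"]) == 0

    def test_zero_library_size_rejected(self, small_genome):
        ids = small_genome.features.tes().ids()
        with pytest.raises(ValueError, match="library size"):
            simulate_chip_experiment(
                small_genome, ChipSimSpec({i: 1.0 for i in ids}, library_size=0), seed=1
            )


class TestSimulateInsertions:
    def test_zero_insertions_empty_truth(self, small_genome):
        donor = small_genome.features.tes().ids()[0]
        r1, r2, truth = simulate_insertions_and_reads(
            small_genome, InsertionSimSpec(donor, n_insertions=0), seed=3
        )
        assert truth.empty and len(r1) == len(r2) > 0

    def test_seeded_determinism(self, small_genome):
        donor = small_genome.features.tes().ids()[0]
        spec = InsertionSimSpec(donor, n_insertions=3)
        out1 = simulate_insertions_and_reads(small_genome, spec, seed=4)
        out2 = simulate_insertions_and_reads(small_genome, spec, seed=4)
        assert out1[0] == out2[0] and out1[1] == out2[1]

    def test_sites_respect_masks(self, small_genome):
        donor_f = small_genome.features.tes().ids()[0]
        _, _, truth = simulate_insertions_and_reads(
            small_genome, InsertionSimSpec(donor_f, n_insertions=6), seed=5
        )
        donor = small_genome.features[donor_f].interval
        cen = small_genome.centromere_mask[0]
        for x in truth["position"]:
            assert not (donor.start <= x < donor.end)
            assert not (cen.start <= x < cen.end)

    def test_junction_reads_exist_each_side(self, small_genome):
        donor_id = small_genome.features.tes().ids()[0]
        donor = small_genome.features[donor_id].interval
        ref = small_genome.sequences["chr1"]
        donor_seq = ref[donor.start : donor.end]
        r1, r2, truth = simulate_insertions_and_reads(
            small_genome, InsertionSimSpec(donor_id, n_insertions=3, coverage=30), seed=6
        )
        seqs = [s for _, s in r1] + [s for _, s in r2]
        from epiphase.simulate import revcomp

        seqs += [revcomp(s) for s in seqs]
        for x in truth["position"]:
            left_junction = ref[x - 30 : x] + donor_seq[:30]
            right_junction = donor_seq[-30:] + ref[x : x + 30]
            assert any(left_junction in s for s in seqs), "left junction uncovered"
            assert any(right_junction in s for s in seqs), "right junction uncovered"
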