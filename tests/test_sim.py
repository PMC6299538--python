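"""Synthetic-data generator: founder spectra, gene drop, read model,
array assignment, and sequencing-budget arithmetic."""

import numpy as np
import pytest

import pedpeel as pp
from pedpeel import sim
from pedpeel.io import MISSING
from pedpeel.pedigree import Pedigree
from pedpeel.transmission import T_SEG


class TestFounders:
    def test_fixed_frequency_mean(self):
        founders = pp.simulate_founders(50, 10_000, seed=1, low=0.5, high=0.5)
        mean = founders.haplotypes.mean()
        assert abs(mean - 0.5) < 0.01

    def test_degenerate_frequency_raises(self):
        with pytest.raises(RuntimeError):
            pp.simulate_founders(3, 10, seed=1, low=0.0, high=0.0)

    def test_seed_determinism(self):
        a = pp.simulate_founders(5, 100, seed=9)
        b = pp.simulate_founders(5, 100, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_all_loci_segregate(self):
        founders = pp.simulate_founders(4, 2_000, seed=2)
        totals = founders.haplotypes.sum(axis=(0, 1))
        assert np.all((totals > 0) & (totals < 8))

    def test_beta_spectrum_supported(self):
        founders = pp.simulate_founders(10, 500, seed=3, spectrum="beta")
        assert founders.haplotypes.shape == (10, 2, 500)


class TestGeneDrop:
    def _trio(self):
        return Pedigree.from_records([("F", "0", "0"), ("M", "0", "0"),
                                      ("C", "F", "M")])

    def test_zero_recombination_passes_whole_haplotypes(self):
        ped = self._trio()
        mmap = pp.MarkerMap.uniform(50, 1_000_000)
        founders = pp.simulate_founders(2, 50, seed=4)
        truth = pp.gene_drop(ped, founders, mmap, seed=5, rate_per_bp=0.0)
        c, f = ped.index_of("C"), ped.index_of("F")
        pat = truth.haplotypes[c, 0]
        assert (np.array_equal(pat, truth.haplotypes[f, 0])
                or np.array_equal(pat, truth.haplotypes[f, 1]))

    def test_mendelian_consistency(self):
        ped = pp.random_pedigree(6, 3, 10, 7)
        mmap = pp.MarkerMap.uniform(100, 100_000_000)
        founders = pp.simulate_founders(len(ped.founders), 100, seed=8)
        truth = pp.gene_drop(ped, founders, mmap, seed=9)
        for i in range(len(ped)):
            if ped.is_founder(i):
                continue
            for which, parent in ((0, ped.sire[i]), (1, ped.dam[i])):
                allele = truth.haplotypes[i, which]
                assert np.all((allele == truth.haplotypes[parent, 0])
                              | (allele == truth.haplotypes[parent, 1]))

    def test_segregation_states_predict_transmission(self):
        """Feeding the recorded true segregation into the conditional
        transmission makes every child's genotype deterministic."""
        ped = pp.random_pedigree(4, 2, 8, 10)
        mmap = pp.MarkerMap.uniform(60, 100_000_000)
        founders = pp.simulate_founders(len(ped.founders), 60, seed=11)
        truth = pp.gene_drop(ped, founders, mmap, seed=12)
        geno = 2 * truth.haplotypes[:, 0] + truth.haplotypes[:, 1]
        for i in range(len(ped)):
            if ped.is_founder(i):
                continue
            s, d = ped.sire[i], ped.dam[i]
            probs = T_SEG[truth.segregation[i], geno[s], geno[d], geno[i]]
            assert np.all(probs == 1.0)

    def test_crossover_rate_matches_map_length(self):
        """1e8 bp at 1e-8 per bp: one crossover per meiosis on average."""
        records = [("S", "0", "0"), ("D", "0", "0")]
        records += [(f"c{k}", "S", "D") for k in range(500)]
        ped = Pedigree.from_records(records)
        L = 400
        mmap = pp.MarkerMap.uniform(L, 100_000_000)
        founders = pp.simulate_founders(2, L, seed=13)
        truth = pp.gene_drop(ped, founders, mmap, seed=14)
        seg = truth.segregation[2:]
        pat = seg >> 1
        mat = seg & 1
        changes = (np.abs(np.diff(pat, axis=1)).sum()
                   + np.abs(np.diff(mat, axis=1)).sum())
        per_meiosis = changes / (2 * 500)
        assert abs(per_meiosis - 1.0) < 0.1


class TestReads:
    def test_zero_coverage_zero_reads(self):
        founders = pp.simulate_founders(3, 50, seed=15)
        plan = pp.SequencingPlan(coverage=[0, 0, 0],
                                 array_status=["none"] * 3)
        obs = pp.simulate_reads(founders, plan, seed=16)
        assert obs.ref_reads.sum() == 0 and obs.alt_reads.sum() == 0

    def test_mean_depth_matches_target(self):
        founders = pp.simulate_founders(2, 10_000, seed=17)
        plan = pp.SequencingPlan(coverage=[30, 30],
                                 array_status=["none"] * 2)
        obs = pp.simulate_reads(founders, plan, seed=18)
        depth = (obs.ref_reads + obs.alt_reads).mean()
        assert abs(depth - 30) < 1

    def test_no_errors_on_homozygous_reference(self):
        haps = pp.HaplotypeSet(
            haplotypes=np.zeros((1, 2, 200), dtype=np.int8),
            segregation=np.full((1, 200), -1, dtype=np.int8),
        )
        plan = pp.SequencingPlan(coverage=[10], array_status=["none"])
        obs = pp.simulate_reads(haps, plan, seed=19, error_rate=0.0)
        assert obs.alt_reads.sum() == 0

    def test_error_rate_produces_flips(self):
        haps = pp.HaplotypeSet(
            haplotypes=np.zeros((1, 2, 20_000), dtype=np.int8),
            segregation=np.full((1, 20_000), -1, dtype=np.int8),
        )
        plan = pp.SequencingPlan(coverage=[10], array_status=["none"])
        obs = pp.simulate_reads(haps, plan, seed=20, error_rate=0.001)
        total = obs.ref_reads.sum() + obs.alt_reads.sum()
        frac = obs.alt_reads.sum() / total
        assert 0.0005 < frac < 0.002


class TestArrayData:
    def _setup(self):
        founders = pp.simulate_founders(3, 40, seed=21)
        hd = np.arange(0, 40, 2)
        ld = hd[::4]
        return founders, hd, ld

    def test_error_free_matches_truth(self):
        founders, hd, ld = self._setup()
        plan = pp.SequencingPlan(coverage=[0, 0, 0],
                                 array_status=["HD", "LD", "none"])
        obs = pp.make_array_data(founders, plan, hd, ld)
        assert np.array_equal(obs.genotypes[0, hd],
                              founders.genotypes[0, hd])
        # LD individual observed only at the LD subset
        not_ld = np.setdiff1d(np.arange(40), ld)
        assert np.all(obs.genotypes[1, not_ld] == MISSING)
        assert np.array_equal(obs.genotypes[1, ld], founders.genotypes[1, ld])
        assert np.all(obs.genotypes[2] == MISSING)

    def test_ld_must_be_subset_of_hd(self):
        founders, hd, _ = self._setup()
        plan = pp.SequencingPlan(coverage=[0, 0, 0], array_status=["HD"] * 3)
        with pytest.raises(ValueError, match="subset"):
            pp.make_array_data(founders, plan, hd, np.array([1]))


class TestSequencingCost:
    def test_focal_column(self):
        total, breakdown = pp.sequencing_cost({1: 33, 2: 78, 15: 64, 30: 36})
        assert total == 76_569
        assert breakdown == {1: 3_531, 2: 13_650, 15: 28_608, 30: 30_780}

    def test_low_coverage_rows(self):
        assert pp.sequencing_cost({1: 1282})[0] == 137_174
        assert pp.sequencing_cost({2: 530})[0] == 92_750

    def test_all_sequenced_total(self):
        total, _ = pp.sequencing_cost({1: 1282, 2: 530, 15: 64, 30: 36})
        assert total == 289_312

    def test_empty_plan_costs_nothing(self):
        assert pp.sequencing_cost({})[0] == 0

    def test_unknown_tier_raises(self):
        with pytest.raises(ValueError, match="coverage"):
            pp.sequencing_cost({7: 3})


class TestDisconnectedFamily:
    def test_only_focal_sequenced(self):
        b = pp.make_disconnected_family(30, 0, 0, 100, 10, seed=22)
        reads = b.obs.ref_reads + b.obs.alt_reads
        assert reads[b.focal].sum() > 0
        others = np.delete(np.arange(7), b.focal)
        assert reads[others].sum() == 0

    def test_everyone_has_hd_array(self):
        b = pp.make_disconnected_family(1, 0, 0, 100, 10, seed=23)
        a_idx = b.mmap.set_a_indices
        assert np.all(b.obs.genotypes[:, a_idx] != MISSING)

    def test_seed_determinism(self):
        a = pp.make_disconnected_family(5, 30, 0, 60, 6, seed=24)
        b = pp.make_disconnected_family(5, 30, 0, 60, 6, seed=24)
        assert np.array_equal(a.obs.ref_reads, b.obs.ref_reads)
        assert np.array_equal(a.obs.genotypes, b.obs.genotypes)
        assert np.array_equal(a.truth.haplotypes, b.truth.haplotypes)

    def test_parent_mean_depth(self):
        b = pp.make_disconnected_family(0, 30, 0, 5_000, 10, seed=25)
        parents = [b.ped.index_of("sire"), b.ped.index_of("dam")]
        depth = (b.obs.ref_reads + b.obs.alt_reads)[parents].mean()
        assert abs(depth - 30) < 1.5
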