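"""Hybrid peeling: interpolation, chunk invariance, streaming, and the
accuracy gain over plain single-locus peeling."""

import warnings

import numpy as np
import pytest

import pedpeel as pp
from pedpeel import calling
from pedpeel.hybrid import HybridPlan, iter_b_chunks, run_hybrid
from pedpeel.model import ModelParams
from pedpeel.multilocus import run_multi_locus
from pedpeel.pedigree import Pedigree


class TestInterpolation:
    @pytest.mark.parametrize("pos_k,expect", [(25, 0.25), (0, 0.0), (100, 1.0)])
    def test_weight_is_proportional_distance(self, pos_k, expect):
        assert pp.interpolation_weight(pos_k, 0, 100) == expect

    def test_degenerate_interval(self):
        assert pp.interpolation_weight(5, 5, 5) == 0.0

    def test_endpoints(self):
        left = np.array([1.0, 0, 0, 0])
        right = np.array([0.0, 1, 0, 0])
        # a is the distance fraction FROM the left flank
        assert np.allclose(pp.interpolate_segregation(left, right, 0.0), left)
        assert np.allclose(pp.interpolate_segregation(left, right, 1.0), right)

    def test_midpoint_is_convex_mix(self):
        left = np.array([1.0, 0, 0, 0])
        right = np.array([0.0, 1, 0, 0])
        got = pp.interpolate_segregation(left, right, 0.5)
        assert np.allclose(got, [0.5, 0.5, 0, 0])

    def test_plan_clamps_outside_span(self):
        mmap = pp.MarkerMap(
            ["l1", "l2", "l3", "l4"], ["1"] * 4,
            np.array([10, 50, 100, 150]),
            np.array([False, True, True, False]),
        )
        plan = HybridPlan.from_map(mmap)
        assert np.all((plan.weight >= 0) & (plan.weight <= 1))
        # locus before the A span interpolates to the first A locus only
        seg_a = np.zeros((1, 2, 4))
        seg_a[0, 0] = [1, 0, 0, 0]
        seg_a[0, 1] = [0, 0, 0, 1]
        interp = plan.interpolated_seg(seg_a)
        assert np.allclose(interp[0, 0], [1, 0, 0, 0])   # left of span
        assert np.allclose(interp[0, 1], [0, 0, 0, 1])   # right of span


def _bundle(seed=0, **kw):
    kw.setdefault("n_loci", 120)
    kw.setdefault("n_set_a", 12)
    return pp.make_disconnected_family(2, 30, 0, seed=seed, **kw)


def _fixed(bundle):
    return ModelParams.initial(bundle.obs, positions_bp=bundle.mmap.position,
                               delta=0.001)


class TestHybridStructure:
    def test_empty_b_equals_multi_locus(self):
        b = _bundle()
        all_a = pp.MarkerMap(b.mmap.locus_ids, b.mmap.chromosome,
                             b.mmap.position, np.ones(len(b.mmap), dtype=bool))
        hyb = run_hybrid(b.ped, b.obs, all_a, _fixed(b), est_maf=False,
                         est_errors=False, est_recomb=False)
        multi = run_multi_locus(b.ped, b.obs, _fixed(b), est_maf=False,
                                est_errors=False, est_recomb=False,
                                positions_bp=all_a.position)
        assert np.abs(hyb.probs - multi.probs).max() < 1e-12

    def test_empty_a_warns_and_falls_back(self):
        b = _bundle()
        no_a = pp.MarkerMap(b.mmap.locus_ids, b.mmap.chromosome,
                            b.mmap.position, np.zeros(len(b.mmap), dtype=bool))
        with pytest.warns(UserWarning, match="set A is empty"):
            hyb = run_hybrid(b.ped, b.obs, no_a, _fixed(b), est_maf=False,
                             est_errors=False)
        single = pp.run_single_locus(b.ped, b.obs, _fixed(b), est_maf=False,
                                     est_errors=False)
        assert np.abs(hyb.probs - single.probs).max() < 1e-12

    def test_founders_only_pedigree_reduces_to_single_locus(self):
        """With no parent-offspring pairs every segregation distribution is
        uniform and the hybrid output equals plain single-locus peeling."""
        ped = Pedigree.from_records([("a", "0", "0"), ("b", "0", "0"),
                                     ("c", "0", "0")])
        rng = np.random.default_rng(1)
        obs = pp.ObservedData.empty(3, 30)
        obs.ref_reads[:] = rng.poisson(1.0, size=obs.ref_reads.shape)
        obs.alt_reads[:] = rng.poisson(0.5, size=obs.alt_reads.shape)
        mmap = pp.MarkerMap.uniform(30, 3_000_000, 5)
        params = ModelParams.initial(obs, positions_bp=mmap.position)
        hyb = run_hybrid(ped, obs, mmap,
                         ModelParams.initial(obs, positions_bp=mmap.position),
                         est_maf=False, est_errors=False, est_recomb=False)
        single = pp.run_single_locus(
            ped, obs, ModelParams.initial(obs, positions_bp=mmap.position),
            est_maf=False, est_errors=False)
        assert np.abs(hyb.probs - single.probs).max() < 1e-9

    @pytest.mark.parametrize("n_chunks", [1, 4, 17])
    def test_chunk_invariance(self, n_chunks):
        b = _bundle(seed=3)
        ref = run_hybrid(b.ped, b.obs, b.mmap, _fixed(b), est_maf=False,
                         est_errors=False, est_recomb=False, n_chunks=1)
        got = run_hybrid(b.ped, b.obs, b.mmap, _fixed(b), est_maf=False,
                         est_errors=False, est_recomb=False,
                         n_chunks=n_chunks)
        assert np.array_equal(ref.probs, got.probs)

    def test_b_loci_stream_without_random_access(self):
        """The B phase touches one chunk of interpolated segregation at a
        time: consuming the generator chunk-by-chunk reproduces run_hybrid."""
        b = _bundle(seed=4)
        params = _fixed(b)
        full = run_hybrid(b.ped, b.obs, b.mmap, params, est_maf=False,
                          est_errors=False, est_recomb=False)
        plan = HybridPlan.from_map(b.mmap)
        a_idx, b_idx = plan.set_a, plan.set_b
        a_params = ModelParams(p=params.p[a_idx], eps=params.eps[a_idx],
                               delta=params.delta[a_idx],
                               gamma=np.diff(b.mmap.position[a_idx].astype(float)) * 1e-8)
        a_res = run_multi_locus(b.ped, b.obs.subset_loci(a_idx), a_params,
                                est_maf=False, est_errors=False,
                                est_recomb=False)
        obs_b = b.obs.subset_loci(b_idx)
        streamed = np.empty((len(b.ped), len(b_idx), 4))
        for sub, frozen in iter_b_chunks(plan, a_res.seg, chunk_size=7):
            res = pp.run_single_locus(
                b.ped, obs_b.subset_loci(sub),
                ModelParams(p=params.p[b_idx[sub]], eps=params.eps[b_idx[sub]],
                            delta=params.delta[b_idx[sub]],
                            gamma=np.full(max(len(sub) - 1, 1), 0.01)),
                est_maf=False, est_errors=False, frozen_seg=frozen,
                chunk_size=len(sub))
            streamed[:, sub] = res.probs
        assert np.array_equal(full.probs[:, b_idx], streamed)


class TestHybridAccuracy:
    def test_hybrid_beats_single_locus_at_b_loci(self):
        """Three-generation family with sibs, focal sequenced thin, parents
        deep: interpolated segregation must not hurt, and should help,
        genotype accuracy at the dense loci."""
        records = [("gp1", "0", "0"), ("gp2", "0", "0"), ("gp3", "0", "0"),
                   ("gp4", "0", "0"), ("sire", "gp1", "gp2"),
                   ("dam", "gp3", "gp4"), ("focal", "sire", "dam")]
        records += [(f"sib{k}", "sire", "dam") for k in range(4)]
        ped = Pedigree.from_records(records)
        rng = np.random.default_rng(11)
        mmap = pp.MarkerMap.uniform(220, 100_000_000, 20)
        founders = pp.simulate_founders(4, 220, seed=12)
        truth = pp.gene_drop(ped, founders, mmap, seed=13)
        cov = np.zeros(len(ped))
        cov[ped.index_of("focal")] = 1
        cov[ped.index_of("sire")] = 30
        cov[ped.index_of("dam")] = 30
        plan = pp.SequencingPlan(coverage=cov, array_status=["HD"] * len(ped))
        reads = pp.simulate_reads(truth, plan, seed=14)
        arrays = pp.make_array_data(truth, plan, mmap.set_a_indices,
                                    mmap.set_a_indices[:0])
        from pedpeel.sim import merge_observations
        obs = merge_observations(arrays, reads)
        params = ModelParams.initial(obs, positions_bp=mmap.position,
                                     delta=0.001)
        hyb = run_hybrid(ped, obs, mmap, params, est_maf=False,
                         est_errors=False, est_recomb=False)
        single = pp.run_single_locus(
            ped, obs, ModelParams.initial(obs, positions_bp=mmap.position,
                                          delta=0.001),
            est_maf=False, est_errors=False)
        f = ped.index_of("focal")
        b_idx = mmap.set_b_indices
        true_d = truth.genotypes[f, b_idx].astype(float)
        hyb_err = np.abs(hyb.dosages[f, b_idx] - true_d).mean()
        single_err = np.abs(single.dosages[f, b_idx] - true_d).mean()
        assert hyb_err <= single_err

    def test_parent_reads_never_reduce_focal_certainty(self):
        """Mean per-locus maximum genotype probability of the focal is
        monotone in parent coverage on fixed seeded fixtures."""
        b = pp.make_disconnected_family(2, 30, 0, 200, 20, seed=21)
        parents = [b.ped.index_of("sire"), b.ped.index_of("dam")]
        certainties = []
        for keep in (0, 100, 200):  # progressively reveal parent reads
            obs = pp.ObservedData(genotypes=b.obs.genotypes.copy(),
                                  ref_reads=b.obs.ref_reads.copy(),
                                  alt_reads=b.obs.alt_reads.copy())
            obs.ref_reads[parents, keep:] = 0
            obs.alt_reads[parents, keep:] = 0
            res = run_hybrid(b.ped, obs, b.mmap, _fixed(b), est_maf=False,
                             est_errors=False, est_recomb=False)
            certainties.append(res.probs[b.focal].max(axis=1).mean())
        assert certainties[0] <= certainties[1] + 1e-3
        assert certainties[1] <= certainties[2] + 1e-3
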