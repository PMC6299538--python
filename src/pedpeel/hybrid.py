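"""Hybrid peeling: multi-locus on a sparse locus set A, then independent
single-locus peeling at the dense remainder B with interpolated segregation.

The A phase estimates per-individual segregation distributions with the
full segregation HMM. Those distributions are then frozen and linearly
interpolated (by physical distance) to every B locus, where a
segregation-aware single-locus peel is run for each locus independently.
Given the frozen segregation, B loci are pure per-locus work units: any
chunking or parallel schedule yields identical results, and memory scales
with the number of individuals, not with the number of loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .io import MarkerMap, ObservedData
from .model import ModelParams, normalize
from .multilocus import run_multi_locus
from .pedigree import Pedigree
from .peeling import (DEFAULT_CYCLES, DEFAULT_TOL, PeelingResult,
                      run_single_locus)


def interpolation_weight(pos_k, pos_j, pos_j1) -> float:
    """Proportional distance of locus k from the left flanking locus j:
    ``d(k, j) / d(j, j+1)`` in base pairs, clamped to [0, 1]."""
    if pos_j1 == pos_j:
        return 0.0
    a = (pos_k - pos_j) / (pos_j1 - pos_j)
    return float(min(max(a, 0.0), 1.0))


def interpolate_segregation(seg_left: np.ndarray, seg_right: np.ndarray,
                            a) -> np.ndarray:
    """Convex combination of the flanking segregation distributions.

    ``a`` is the proportional distance from the *left* flank, so the weight
    on the left flank is ``1 - a`` (a = 0 returns the left flank, a = 1 the
    right). Renormalised for safety.
    """
    a = np.asarray(a, dtype=float)[..., None]
    return normalize((1.0 - a) * seg_left + a * seg_right)


@dataclass
class HybridPlan:
    """Index bookkeeping for one hybrid run.

    For each B locus: the positions of its flanking A loci inside the A
    block (``left`` / ``right``) and its interpolation weight ``a`` (the
    proportional distance from the left flank). B loci outside the span of
    A clamp to the nearest A locus.
    """

    set_a: np.ndarray  # indices of A loci in map order
    set_b: np.ndarray  # indices of B loci in map order
    left: np.ndarray  # (|B|,) index into set_a
    right: np.ndarray  # (|B|,) index into set_a
    weight: np.ndarray  # (|B|,) in [0, 1]

    @classmethod
    def from_map(cls, mmap: MarkerMap) -> "HybridPlan":
        a_idx = mmap.set_a_indices
        b_idx = mmap.set_b_indices
        if len(a_idx) == 0:
            raise ValueError("set A is empty")
        a_pos = mmap.position[a_idx].astype(float)
        b_pos = mmap.position[b_idx].astype(float)
        right = np.searchsorted(a_pos, b_pos)
        left = right - 1
        left = np.clip(left, 0, len(a_idx) - 1)
        right = np.clip(right, 0, len(a_idx) - 1)
        weight = np.array(
            [
                interpolation_weight(bp, a_pos[l], a_pos[r])
                for bp, l, r in zip(b_pos, left, right)
            ]
        )
        return cls(set_a=a_idx, set_b=b_idx, left=left, right=right,
                   weight=weight)

    def interpolated_seg(self, seg_a: np.ndarray,
                         b_subset: np.ndarray | None = None) -> np.ndarray:
        """(N, |B subset|, 4) interpolated segregation at B loci, from the
        (N, |A|, 4) A-phase posteriors."""
        sel = slice(None) if b_subset is None else b_subset
        lf = self.left[sel]
        rt = self.right[sel]
        w = self.weight[sel]
        return interpolate_segregation(seg_a[:, lf], seg_a[:, rt], w)


def iter_b_chunks(plan: HybridPlan, seg_a: np.ndarray, chunk_size: int
                  ) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Stream (B-locus indices within the B block, frozen segregation) pairs.

    Only one chunk's segregation is materialised at a time — the B phase
    needs state for the current chunk plus the frozen A-phase segregation.
    """
    n_b = len(plan.set_b)
    for start in range(0, n_b, chunk_size):
        sub = np.arange(start, min(start + chunk_size, n_b))
        yield sub, plan.interpolated_seg(seg_a, sub)


def run_hybrid(ped: Pedigree, obs: ObservedData, mmap: MarkerMap,
               params: ModelParams | None = None,
               n_cycles_a: int = DEFAULT_CYCLES,
               n_cycles_b: int = DEFAULT_CYCLES,
               tol: float = DEFAULT_TOL,
               est_maf: bool = True, est_errors: bool = True,
               est_recomb: bool = True,
               n_chunks: int | None = None,
               seg_a: np.ndarray | None = None) -> PeelingResult:
    """Hybrid peeling over all loci of ``mmap``.

    Runs multi-locus peeling on set A (unless a frozen ``seg_a`` checkpoint
    is supplied), freezes the segregation posteriors, and then peels every
    B locus independently with segregation-aware single-locus transmission.
    A-locus outputs come from the A phase. With an empty set A the function
    warns and falls back to plain single-locus peeling.
    """
    L = len(mmap)
    if obs.n_loci != L:
        raise ValueError("observations and marker map disagree on locus count")
    if params is None:
        params = ModelParams.initial(obs, positions_bp=mmap.position)

    if len(mmap.set_a_indices) == 0:
        warnings.warn("set A is empty; falling back to single-locus peeling")
        return run_single_locus(ped, obs, params, n_cycles=n_cycles_a, tol=tol,
                                est_maf=est_maf, est_errors=est_errors)

    plan = HybridPlan.from_map(mmap)
    a_idx, b_idx = plan.set_a, plan.set_b

    a_positions = mmap.position[a_idx]
    a_params = ModelParams(
        p=params.p[a_idx], eps=params.eps[a_idx], delta=params.delta[a_idx],
        gamma=np.diff(a_positions.astype(float)) * 1e-8 if len(a_idx) > 1
        else params.gamma[:1],
    )
    if seg_a is None:
        a_res = run_multi_locus(ped, obs.subset_loci(a_idx), a_params,
                                n_cycles=n_cycles_a, tol=tol, est_maf=est_maf,
                                est_errors=est_errors, est_recomb=est_recomb)
        seg_a = a_res.seg
    else:
        # frozen checkpoint: skip the HMM phase entirely (this is what lets
        # the B phase be distributed across jobs); A loci are peeled
        # single-locus style with the checkpointed segregation
        seg_a = np.asarray(seg_a, dtype=float)
        a_res = run_single_locus(ped, obs.subset_loci(a_idx), a_params,
                                 n_cycles=n_cycles_b, tol=tol, est_maf=est_maf,
                                 est_errors=est_errors, frozen_seg=seg_a)

    probs = np.empty((len(ped), L, 4))
    p_out = np.empty(L)
    eps_out = np.empty(L)
    delta_out = np.empty(L)
    probs[:, a_idx] = a_res.probs
    p_out[a_idx] = a_res.params.p
    eps_out[a_idx] = a_res.params.eps
    delta_out[a_idx] = a_res.params.delta

    if len(b_idx) > 0:
        if n_chunks:
            chunk = max(1, int(np.ceil(len(b_idx) / n_chunks)))
        else:
            chunk = max(16, min(len(b_idx), int(2_000_000 / max(len(ped), 1))))
        obs_b = obs.subset_loci(b_idx)
        for sub, frozen in iter_b_chunks(plan, seg_a, chunk):
            res = run_single_locus(
                ped, obs_b.subset_loci(sub),
                ModelParams(p=params.p[b_idx[sub]], eps=params.eps[b_idx[sub]],
                            delta=params.delta[b_idx[sub]],
                            gamma=np.full(max(len(sub) - 1, 1), 0.01)),
                n_cycles=n_cycles_b, tol=tol, est_maf=est_maf,
                est_errors=est_errors, frozen_seg=frozen,
                chunk_size=len(sub),
            )
            probs[:, b_idx[sub]] = res.probs
            p_out[b_idx[sub]] = res.params.p
            eps_out[b_idx[sub]] = res.params.eps
            delta_out[b_idx[sub]] = res.params.delta

    out_params = ModelParams(p=p_out, eps=eps_out, delta=delta_out,
                             gamma=a_res.params.gamma)
    return PeelingResult(ids=list(ped.ids), probs=probs, params=out_params,
                         seg=seg_a, seg_loci=a_idx,
                         n_cycles_run=a_res.n_cycles_run,
                         max_delta=a_res.max_delta)
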