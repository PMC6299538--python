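"""Iterative peeling engine.

Genotype probabilities are estimated per individual and locus as the
normalised product of three terms: the *anterior* (information flowing down
from parents), the *posterior* (information flowing up from offspring and
mates) and the *penetrance* (the individual's own array/read data). The
engine sweeps the pedigree family-by-family: a peel-down pass updates the
anterior terms in generation order, a peel-up pass updates the per-family
joint posterior tables in reverse order. On loop-free pedigrees the
converged probabilities equal the exact posterior marginals; pedigrees with
loops are handled by the same iteration, approximately.

The transmission function is either the single-locus table (each parental
haplotype passed with probability one half) or, when per-individual
segregation distributions are supplied or estimated, the segregation-aware
transmission marginalised over those distributions.

Exclusivity contract: an individual's anterior never incorporates its own
penetrance or posterior; a parent's contribution to a family excludes that
family's own posterior table; the family table used for a child's anterior
excludes that child's factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model
from .io import ObservedData
from .model import DOSAGE, ModelParams, normalize
from .pedigree import Pedigree
from .transmission import T_SEG, T_SINGLE

DEFAULT_CYCLES = 20
DEFAULT_TOL = 1e-4


@dataclass
class PeelingResult:
    """Genotype probabilities and fitted parameters for one peeling run."""

    ids: list[str]
    probs: np.ndarray  # (N, L, 4)
    params: ModelParams
    seg: np.ndarray | None = None  # (N, L_A, 4) segregation posteriors
    seg_loci: np.ndarray | None = None  # indices of the loci seg refers to
    n_cycles_run: int = 0
    max_delta: float = field(default=np.inf)

    @property
    def dosages(self) -> np.ndarray:
        return self.probs @ DOSAGE


class _FamilyView:
    """Index structure for one mate pair inside the engine."""

    __slots__ = ("sire", "dam", "children")

    def __init__(self, sire: int, dam: int, children: tuple[int, ...]):
        self.sire = sire
        self.dam = dam
        self.children = children


def _canonical_families(ped: Pedigree) -> list[_FamilyView]:
    """Families in a processing order independent of input record order:
    by child generation, then parents' ids."""
    fams = ped.families()
    fams = sorted(
        fams,
        key=lambda f: (ped.generation[f.children[0]], ped.ids[f.sire], ped.ids[f.dam]),
    )
    return [
        _FamilyView(f.sire, f.dam, tuple(sorted(f.children, key=lambda c: ped.ids[c])))
        for f in fams
    ]


class PeelEngine:
    """One peeling run over a block of loci.

    Parameters
    ----------
    ped, obs
        Pedigree and observations (loci of ``obs`` define the block).
    params
        Per-locus model parameters (lengths matching the block).
    seg
        ``None`` for plain single-locus transmission; an (N, L, 4) array of
        frozen per-individual segregation distributions; or ``"estimate"``
        to run the per-individual forward-backward over loci each cycle
        (multi-locus peeling).
    """

    def __init__(self, ped: Pedigree, obs: ObservedData, params: ModelParams,
                 seg=None, est_maf: bool = True, est_errors: bool = True,
                 est_recomb: bool = True):
        self.ped = ped
        self.obs = obs
        self.params = params
        self.est_maf = est_maf
        self.est_errors = est_errors
        self.est_recomb = est_recomb
        self.N = len(ped)
        self.L = obs.n_loci

        self.multilocus = isinstance(seg, str) and seg == "estimate"
        if self.multilocus:
            self.seg_tr = None  # filled after the first forward-backward
            self.seg_post = np.full((len(ped), obs.n_loci, 4), 0.25)
        else:
            self.seg_tr = None if seg is None else np.asarray(seg, dtype=float)
            self.seg_post = self.seg_tr

        self.families = _canonical_families(ped)
        self.child_family = np.full(self.N, -1, dtype=int)
        self.parent_families: list[list[tuple[int, int]]] = [[] for _ in range(self.N)]
        for fi, fam in enumerate(self.families):
            for c in fam.children:
                self.child_family[c] = fi
            self.parent_families[fam.sire].append((fi, 0))
            self.parent_families[fam.dam].append((fi, 1))
        self.founders = [i for i in range(self.N) if ped.is_founder(i)]
        self.nonfounders = np.array(
            [i for i in range(self.N) if not ped.is_founder(i)], dtype=int
        )

        N, L = self.N, self.L
        self.penetrance = model.combined_penetrance(obs, params)
        self.anterior = np.full((N, L, 4), 0.25)
        self._set_founder_anteriors()
        # child-to-family message tables M_c(g_f, g_m) and per-family products
        self.msg = np.full((N, L, 4, 4), 1.0 / 16.0)
        self.fam_post = [np.full((L, 4, 4), 1.0 / 16.0) for _ in self.families]
        # family contribution to each parent, (L, 4), index [fi][role 0=sire,1=dam]
        self.contrib = [
            [np.full((L, 4), 0.25), np.full((L, 4), 0.25)] for _ in self.families
        ]

    # ------------------------------------------------------------------
    def _set_founder_anteriors(self) -> None:
        prior = model.founder_anterior(self.params.p)  # (L, 4)
        for i in self.founders:
            self.anterior[i] = prior

    def _posterior_as_parent(self, i: int) -> np.ndarray:
        """Product of this individual's family contributions (Eq-6b style)."""
        out = np.full((self.L, 4), 0.25)
        for fi, role in self.parent_families[i]:
            out = out * self.contrib[fi][role]
        return normalize(out)

    def _parent_q(self, i: int, exclude_family: int) -> np.ndarray:
        """anterior * penetrance * posterior excluding one family's table."""
        q = self.anterior[i] * self.penetrance[i]
        for fi, role in self.parent_families[i]:
            if fi != exclude_family:
                q = q * self.contrib[fi][role]
        return normalize(q)

    def _excl_products(self, tables: np.ndarray) -> np.ndarray:
        """Leave-one-out products along axis 0 via prefix/suffix products."""
        n = tables.shape[0]
        if n == 1:
            return np.ones_like(tables)
        pref = np.ones_like(tables)
        suff = np.ones_like(tables)
        for k in range(1, n):
            pref[k] = pref[k - 1] * tables[k - 1]
        for k in range(n - 2, -1, -1):
            suff[k] = suff[k + 1] * tables[k + 1]
        return pref * suff

    # ------------------------------------------------------------------
    def _peel_down(self) -> None:
        """Update anterior terms, oldest families first."""
        self._set_founder_anteriors()
        for fi, fam in enumerate(self.families):
            q_s = self._parent_q(fam.sire, fi)
            q_d = self._parent_q(fam.dam, fi)
            stacked = np.stack([self.msg[c] for c in fam.children])
            excl = self._excl_products(stacked)
            joint = q_s[:, :, None] * q_d[:, None, :]  # (L, g_f, g_m)
            for k, c in enumerate(fam.children):
                table = joint * excl[k]
                if self.seg_tr is None:
                    ant = np.einsum("lfm,fmc->lc", table, T_SINGLE)
                else:
                    ant = np.einsum("lfm,ls,sfmc->lc", table, self.seg_tr[c], T_SEG)
                self.anterior[c] = normalize(ant)

    def _peel_up(self) -> None:
        """Update family posterior tables and parent contributions,
        youngest families first."""
        for fi in range(len(self.families) - 1, -1, -1):
            fam = self.families[fi]
            prod = np.ones((self.L, 4, 4))
            for c in fam.children:
                lam = normalize(self.penetrance[c] * self._posterior_as_parent(c))
                if self.seg_tr is None:
                    m = np.einsum("lc,fmc->lfm", lam, T_SINGLE)
                else:
                    m = np.einsum("lc,ls,sfmc->lfm", lam, self.seg_tr[c], T_SEG)
                m = normalize(m, axes=(-2, -1))
                self.msg[c] = m
                prod = prod * m
            self.fam_post[fi] = normalize(prod, axes=(-2, -1))
            q_s = self._parent_q(fam.sire, fi)
            q_d = self._parent_q(fam.dam, fi)
            self.contrib[fi][0] = normalize(
                np.einsum("lfm,lm->lf", self.fam_post[fi], q_d)
            )
            self.contrib[fi][1] = normalize(
                np.einsum("lfm,lf->lm", self.fam_post[fi], q_s)
            )

    # ------------------------------------------------------------------
    def genotype_probabilities(self) -> np.ndarray:
        probs = np.empty((self.N, self.L, 4))
        for i in range(self.N):
            probs[i] = normalize(
                self.anterior[i] * self.penetrance[i] * self._posterior_as_parent(i)
            )
        return probs

    # ------------------------------------------------------------------
    def _seg_evidence(self) -> np.ndarray:
        """Per-locus segregation evidence for every non-founder (Nn, L, 4).

        The individual's own anterior is excluded; the family table excludes
        the individual's own factor.
        """
        e = np.full((self.N, self.L, 4), 0.25)
        for fi, fam in enumerate(self.families):
            q_s = self._parent_q(fam.sire, fi)
            q_d = self._parent_q(fam.dam, fi)
            stacked = np.stack([self.msg[c] for c in fam.children])
            excl = self._excl_products(stacked)
            joint = q_s[:, :, None] * q_d[:, None, :]
            for k, c in enumerate(fam.children):
                lam = normalize(self.penetrance[c] * self._posterior_as_parent(c))
                ev = np.einsum("lfm,lc,sfmc->ls", joint * excl[k], lam, T_SEG)
                e[c] = normalize(ev)
        return e[self.nonfounders]

    def _forward_backward(self) -> None:
        """Batched forward-backward over loci for all non-founders.

        Updates ``seg_tr`` (prediction product, local evidence excluded —
        used inside same-locus transmission) and ``seg_post`` (full posterior
        — reported, interpolated, and used for recombination estimation),
        and re-estimates per-interval recombination rates when enabled.
        """
        from .transmission import SEG_HAMMING, seg_transition

        Nn, L = len(self.nonfounders), self.L
        if Nn == 0:
            return
        e = self._seg_evidence()  # (Nn, L, 4)
        G = seg_transition(self.params.gamma)  # (L-1, 4, 4)
        fwd = np.full((Nn, L, 4), 0.25)
        bwd = np.full((Nn, L, 4), 0.25)
        for j in range(1, L):
            fwd[:, j] = normalize((fwd[:, j - 1] * e[:, j - 1]) @ G[j - 1])
        for j in range(L - 2, -1, -1):
            bwd[:, j] = normalize((bwd[:, j + 1] * e[:, j + 1]) @ G[j].T)

        seg_tr = np.full((self.N, L, 4), 0.25)
        seg_post = np.full((self.N, L, 4), 0.25)
        seg_tr[self.nonfounders] = normalize(fwd * bwd)
        seg_post[self.nonfounders] = normalize(fwd * e * bwd)
        self.seg_tr = seg_tr
        self.seg_post = seg_post

        if self.est_recomb and L > 1:
            left = fwd * e  # (Nn, L, 4)
            right = e * bwd
            pair = left[:, :-1, :, None] * G[None, :, :, :] * right[:, 1:, None, :]
            pair = pair / pair.sum(axis=(-2, -1), keepdims=True)
            changes = (pair * SEG_HAMMING).sum(axis=(-2, -1)).mean(axis=0)
            self.params.gamma = np.clip(
                changes / 2.0, model.GAMMA_MIN, model.GAMMA_MAX
            )

    # ------------------------------------------------------------------
    def _update_params(self, probs: np.ndarray) -> None:
        if self.est_maf and self.founders:
            self.params.p = model.estimate_maf(probs[self.founders])
        if self.est_errors:
            self.params.eps = model.estimate_array_error(
                self.obs.genotypes, probs, self.params.eps
            )
            self.params.delta = model.estimate_seq_error(
                self.obs.ref_reads, self.obs.alt_reads, probs, self.params.delta
            )
            self.penetrance = model.combined_penetrance(self.obs, self.params)

    # ------------------------------------------------------------------
    def run(self, n_cycles: int = DEFAULT_CYCLES, tol: float = DEFAULT_TOL,
            estimate_params: bool = True) -> PeelingResult:
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        prev = None
        delta = np.inf
        cycles = 0
        for cycle in range(n_cycles):
            self._peel_down()
            self._peel_up()
            if self.multilocus:
                self._forward_backward()
            probs = self.genotype_probabilities()
            if estimate_params:
                self._update_params(probs)
            cycles = cycle + 1
            if prev is not None:
                delta = float(np.abs(probs - prev).max())
                if tol > 0 and delta < tol:
                    prev = probs
                    break
            prev = probs
        return PeelingResult(
            ids=list(self.ped.ids),
            probs=prev,
            params=self.params,
            seg=self.seg_post.copy() if self.seg_post is not None else None,
            n_cycles_run=cycles,
            max_delta=delta,
        )


# ----------------------------------------------------------------------
def _auto_chunk(n_individuals: int, n_loci: int) -> int:
    # keep the (N, chunk, 4, 4) message array around 100-200 MB at most
    return max(16, min(n_loci, int(2_000_000 / max(n_individuals, 1))))


def run_single_locus(ped: Pedigree, obs: ObservedData,
                     params: ModelParams | None = None,
                     n_cycles: int = DEFAULT_CYCLES, tol: float = DEFAULT_TOL,
                     est_maf: bool = True, est_errors: bool = True,
                     frozen_seg: np.ndarray | None = None,
                     chunk_size: int | None = None) -> PeelingResult:
    """Single-locus iterative peeling over all loci of ``obs``.

    Loci are independent, so the computation is streamed in locus chunks;
    chunk boundaries cannot affect the result. ``frozen_seg`` (N, L, 4)
    switches the transmission to the segregation-aware form with fixed
    per-individual segregation distributions (the hybrid B phase).
    """
    if params is None:
        params = ModelParams.initial(obs)
    L = obs.n_loci
    chunk = chunk_size or _auto_chunk(len(ped), L)
    probs = np.empty((len(ped), L, 4))
    p_out = np.empty(L)
    eps_out = np.empty(L)
    delta_out = np.empty(L)
    cycles = 0
    delta_max = 0.0
    for start in range(0, L, chunk):
        idx = np.arange(start, min(start + chunk, L))
        sub_params = ModelParams(
            p=params.p[idx], eps=params.eps[idx], delta=params.delta[idx],
            gamma=np.full(max(len(idx) - 1, 1), 0.01),
        )
        engine = PeelEngine(
            ped, obs.subset_loci(idx), sub_params,
            seg=None if frozen_seg is None else frozen_seg[:, idx],
            est_maf=est_maf, est_errors=est_errors, est_recomb=False,
        )
        res = engine.run(n_cycles=n_cycles, tol=tol)
        probs[:, idx] = res.probs
        p_out[idx] = res.params.p
        eps_out[idx] = res.params.eps
        delta_out[idx] = res.params.delta
        cycles = max(cycles, res.n_cycles_run)
        delta_max = max(delta_max, res.max_delta)
    out_params = ModelParams(p=p_out, eps=eps_out, delta=delta_out,
                             gamma=params.gamma)
    return PeelingResult(ids=list(ped.ids), probs=probs, params=out_params,
                         n_cycles_run=cycles, max_delta=delta_max)
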