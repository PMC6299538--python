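"""Multi-locus peeling: segregation HMM over loci plus up/down peeling.

Each non-founder carries, at every locus, a distribution over the four
segregation states (which grandparental haplotype each parent transmitted).
Along a chromosome these states follow a Markov chain whose transitions are
governed by the inter-locus recombination rate, and the per-locus evidence
comes from the peeling tables; the forward-backward algorithm combines the
two. Founders have no parents and keep a uniform segregation distribution.
"""

from __future__ import annotations

import numpy as np

from .io import ObservedData
from .model import ModelParams, normalize
from .model import GAMMA_MIN, GAMMA_MAX
from .pedigree import Pedigree
from .peeling import DEFAULT_CYCLES, DEFAULT_TOL, PeelEngine, PeelingResult
from .transmission import SEG_HAMMING, seg_transition


def forward_backward(evidence: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Segregation posteriors from per-locus evidence and per-interval
    recombination rates.

    Parameters
    ----------
    evidence
        (L, 4) non-negative local evidence vectors.
    gamma
        (L-1,) recombination rates between adjacent loci.

    Returns
    -------
    (L, 4) posterior distribution at each locus (uniform boundary messages).
    """
    def _norm(v):  # exact normalisation (no probability floor): this is a
        return v / v.sum(axis=-1, keepdims=True)  # standalone op, not a product chain

    e = np.asarray(evidence, dtype=float)
    L = e.shape[0]
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (max(L - 1, 0),))
    G = seg_transition(gamma) if L > 1 else None
    fwd = np.full((L, 4), 0.25)
    bwd = np.full((L, 4), 0.25)
    for j in range(1, L):
        fwd[j] = _norm((fwd[j - 1] * e[j - 1]) @ G[j - 1])
    for j in range(L - 2, -1, -1):
        bwd[j] = _norm((bwd[j + 1] * e[j + 1]) @ G[j].T)
    return _norm(fwd * e * bwd)


def estimate_recombination(evidence: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Expected per-interval recombination rate from the pairwise posterior
    over adjacent segregation states.

    ``evidence`` is (n_individuals, L, 4); the pairwise table for each
    individual and interval is assembled from the forward message and
    evidence at locus j, the transition, and the evidence and backward
    message at locus j+1, normalised per individual per interval. The rate
    is the mean expected number of segregation changes divided by two (one
    meiosis per parent), clamped to [1e-6, 0.49].
    """
    e = np.asarray(evidence, dtype=float)
    if e.ndim == 2:
        e = e[None]
    n, L = e.shape[0], e.shape[1]
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (L - 1,))
    G = seg_transition(gamma)
    fwd = np.full((n, L, 4), 0.25)
    bwd = np.full((n, L, 4), 0.25)
    for j in range(1, L):
        fwd[:, j] = normalize((fwd[:, j - 1] * e[:, j - 1]) @ G[j - 1])
    for j in range(L - 2, -1, -1):
        bwd[:, j] = normalize((bwd[:, j + 1] * e[:, j + 1]) @ G[j].T)
    left = fwd * e
    right = e * bwd
    pair = left[:, :-1, :, None] * G[None] * right[:, 1:, None, :]
    pair = pair / pair.sum(axis=(-2, -1), keepdims=True)
    changes = (pair * SEG_HAMMING).sum(axis=(-2, -1)).mean(axis=0)
    return np.clip(changes / 2.0, GAMMA_MIN, GAMMA_MAX)


def run_multi_locus(ped: Pedigree, obs: ObservedData,
                    params: ModelParams | None = None,
                    n_cycles: int = DEFAULT_CYCLES, tol: float = DEFAULT_TOL,
                    est_maf: bool = True, est_errors: bool = True,
                    est_recomb: bool = True,
                    positions_bp: np.ndarray | None = None) -> PeelingResult:
    """Multi-locus iterative peeling over all loci of ``obs``.

    Each cycle peels down, peels up, refreshes every non-founder's
    segregation distribution by forward-backward, and (optionally)
    re-estimates allele frequencies, error rates and recombination rates.
    The returned result carries the segregation posteriors for all loci.
    """
    if params is None:
        params = ModelParams.initial(obs, positions_bp=positions_bp)
    engine = PeelEngine(ped, obs, params, seg="estimate",
                        est_maf=est_maf, est_errors=est_errors,
                        est_recomb=est_recomb)
    res = engine.run(n_cycles=n_cycles, tol=tol)
    res.seg_loci = np.arange(obs.n_loci)
    return res
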