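"""Genotype penetrance functions, founder priors and parameter estimation.

Phased genotypes are ordered ``(aa, aA, Aa, AA)``; the first allele of each
pair is the paternally inherited one. With allele codes a=0 (reference) and
A=1 (alternative), genotype index ``g`` encodes ``paternal = g >> 1`` and
``maternal = g & 1``, so the alternative-allele dosage is ``(g>>1)+(g&1)``.

All probability tables are kept in linear space, normalised to sum to 1,
and floored at ``PROB_FLOOR`` after every normalisation so that products of
many tables never collapse to exact zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MISSING, ObservedData

PROB_FLOOR = 1e-10

#: dosage (alternative-allele count) of each phased genotype
DOSAGE = np.array([0.0, 1.0, 1.0, 2.0])

# clamping bounds for estimated parameters
P_MIN, P_MAX = 1e-4, 1 - 1e-4
ERR_MIN, ERR_MAX = 1e-4, 0.1
GAMMA_MIN, GAMMA_MAX = 1e-6, 0.49


def normalize(table: np.ndarray, axes=-1) -> np.ndarray:
    """Normalise over ``axes``, apply the probability floor, renormalise."""
    s = table.sum(axis=axes, keepdims=True)
    s = np.where(s > 0, s, 1.0)
    out = table / s
    np.maximum(out, PROB_FLOOR, out=out)
    out /= out.sum(axis=axes, keepdims=True)
    return out


@dataclass
class ModelParams:
    """Per-locus model parameters.

    p
        Alternative-allele frequency in [0,1] (L,).
    eps
        SNP-array genotyping error rate (L,).
    delta
        Per-read sequencing error rate (L,).
    gamma
        Recombination rate between adjacent loci (L-1,), only meaningful for
        the sparse multi-locus set.
    """

    p: np.ndarray
    eps: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.clip(np.atleast_1d(np.asarray(self.p, dtype=float)), P_MIN, P_MAX)
        self.eps = np.clip(np.atleast_1d(np.asarray(self.eps, dtype=float)), ERR_MIN, ERR_MAX)
        self.delta = np.clip(np.atleast_1d(np.asarray(self.delta, dtype=float)), ERR_MIN, ERR_MAX)
        self.gamma = np.clip(np.atleast_1d(np.asarray(self.gamma, dtype=float)), 0.0, 0.5)

    @classmethod
    def initial(cls, obs: ObservedData, positions_bp: np.ndarray | None = None,
                eps: float = 0.01, delta: float = 0.01,
                recomb_per_bp: float = 1e-8) -> "ModelParams":
        """Starting values: p from the pooled data mean (with a +1/+1
        pseudocount so single-read loci do not start at a clamp boundary),
        eps = delta = 0.01, gamma from physical distance at 1 cM/Mb."""
        L = obs.n_loci
        observed = obs.genotypes != MISSING
        alt = np.where(observed, obs.genotypes, 0).sum(axis=0).astype(float)
        tot = 2.0 * observed.sum(axis=0)
        alt += obs.alt_reads.sum(axis=0)
        tot += (obs.ref_reads + obs.alt_reads).sum(axis=0)
        p = (alt + 1.0) / (tot + 2.0)
        if positions_bp is not None and L > 1:
            gamma = np.diff(np.asarray(positions_bp, dtype=float)) * recomb_per_bp
        else:
            gamma = np.full(max(L - 1, 1), 0.01)
        return cls(p=p, eps=np.full(L, eps), delta=np.full(L, delta),
                   gamma=np.clip(gamma, GAMMA_MIN, GAMMA_MAX))

    def subset(self, idx: np.ndarray) -> "ModelParams":
        """Parameters restricted to a locus subset (gamma left per-pair of
        the subset via midpoint distances is not meaningful; recomputed by
        callers that need it)."""
        idx = np.asarray(idx)
        g = self.gamma[idx[:-1]] if len(idx) > 1 else self.gamma[:1]
        return ModelParams(p=self.p[idx], eps=self.eps[idx],
                           delta=self.delta[idx], gamma=g)


# ----------------------------------------------------------------------
# penetrance
# ----------------------------------------------------------------------
def penetrance_from_reads(n_ref, n_alt, delta) -> np.ndarray:
    """Read-count genotype likelihoods, normalised over the four phased states.

    Proportional to ``((1-d)^nr d^na, .5^(nr+na), .5^(nr+na), d^nr (1-d)^na)``;
    evaluated in log space so hundreds of reads stay finite.
    Zero reads give the uniform distribution.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0) or np.any(delta >= 0.5):
        raise ValueError("sequencing error rate must lie in (0, 0.5)")
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    if np.any(n_ref < 0) or np.any(n_alt < 0):
        raise ValueError("read counts must be non-negative")
    log_half = np.log(0.5)
    het = (n_ref + n_alt) * log_half
    logs = np.stack(
        [
            n_ref * np.log1p(-delta) + n_alt * np.log(delta),
            het,
            het,
            n_ref * np.log(delta) + n_alt * np.log1p(-delta),
        ],
        axis=-1,
    )
    logs -= logs.max(axis=-1, keepdims=True)
    return normalize(np.exp(logs))


#: disagreement indicator [observed genotype 0/1/2][phased genotype]
_ARRAY_DISAGREE = np.array(
    [
        [0, 1, 1, 1],  # observed 0: only aa agrees
        [1, 0, 0, 1],  # observed 1: aA and Aa agree
        [1, 1, 1, 0],  # observed 2: only AA agrees
    ],
    dtype=float,
)


def penetrance_from_array(observed, eps) -> np.ndarray:
    """SNP-array genotype likelihoods: ``1 - eps`` for phased genotypes
    consistent with the unphased call, ``eps`` otherwise; uniform for MISSING."""
    observed = np.asarray(observed)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0) or np.any(eps >= 0.5):
        raise ValueError("array error rate must lie in (0, 0.5)")
    if not np.all(np.isin(observed, (0, 1, 2, MISSING))):
        raise ValueError("array genotype codes must be 0, 1, 2 or 9 (missing)")
    obs_safe = np.where(observed == MISSING, 0, observed).astype(int)
    disagree = _ARRAY_DISAGREE[obs_safe]
    eps_b = np.broadcast_to(eps, observed.shape)[..., None]
    table = np.where(disagree == 1, eps_b, 1.0 - eps_b)
    table = np.where((observed == MISSING)[..., None], 0.25, table)
    return normalize(table)


def combined_penetrance(obs: ObservedData, params: ModelParams) -> np.ndarray:
    """(N, L, 4) product of array and read penetrances, normalised."""
    arr = penetrance_from_array(obs.genotypes, params.eps[None, :])
    reads = penetrance_from_reads(obs.ref_reads, obs.alt_reads, params.delta[None, :])
    return normalize(arr * reads)


# ----------------------------------------------------------------------
# priors
# ----------------------------------------------------------------------
def founder_anterior(p) -> np.ndarray:
    """Hardy-Weinberg prior over phased genotypes for parent-less individuals:
    ``((1-p)^2, p(1-p), p(1-p), p^2)``."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return np.stack([q * q, p * q, p * q, p * p], axis=-1)


# ----------------------------------------------------------------------
# parameter estimation (per locus, from current genotype probabilities)
# ----------------------------------------------------------------------
def estimate_maf(founder_probs: np.ndarray) -> np.ndarray:
    """Allele frequency from mean founder dosage, divided by 2 so the result
    is a frequency in [0,1]; clamped away from the boundaries.

    ``founder_probs`` is (n_founders, ..., 4) over phased genotypes.
    """
    if founder_probs.shape[0] == 0:
        raise ValueError("allele frequency estimation needs at least one founder")
    dosage = founder_probs @ DOSAGE
    return np.clip(dosage.mean(axis=0) / 2.0, P_MIN, P_MAX)


def estimate_array_error(observed: np.ndarray, probs: np.ndarray,
                         current: np.ndarray) -> np.ndarray:
    """Mean posterior disagreement between array calls and genotypes.

    ``observed`` (N, L), ``probs`` (N, L, 4). Loci with no array data keep
    their current value. Result clamped to [1e-4, 0.1].
    """
    has = observed != MISSING
    obs_safe = np.where(has, observed, 0).astype(int)
    mism = (_ARRAY_DISAGREE[obs_safe] * probs).sum(axis=-1)
    num = np.where(has, mism, 0.0).sum(axis=0)
    den = has.sum(axis=0)
    out = np.array(current, dtype=float, copy=True)
    ok = den > 0
    out[ok] = np.clip(num[ok] / den[ok], ERR_MIN, ERR_MAX)
    return out


def estimate_seq_error(ref: np.ndarray, alt: np.ndarray, probs: np.ndarray,
                       current: np.ndarray) -> np.ndarray:
    """Sequencing error from reads that contradict a homozygous genotype,
    ignoring heterozygotes; loci with no informative reads keep their
    current value. Result clamped to [1e-4, 0.1]."""
    p_aa = probs[..., 0]
    p_AA = probs[..., 3]
    num = (alt * p_aa + ref * p_AA).sum(axis=0)
    den = ((ref + alt) * (p_aa + p_AA)).sum(axis=0)
    out = np.array(current, dtype=float, copy=True)
    ok = den > 0
    out[ok] = np.clip(num[ok] / den[ok], ERR_MIN, ERR_MAX)
    return out
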