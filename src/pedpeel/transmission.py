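"""Parent-to-offspring transmission tensors and segregation transitions.

Genotype index ``g`` encodes (paternal, maternal) alleles as
``(g >> 1, g & 1)``. Segregation states over ``s in (pp, pm, mp, mm)`` encode
which grandparental haplotype each parent transmitted: the first letter is
the father's choice, the second the mother's; ``s >> 1`` is the father's
(0 = his paternal, 1 = his maternal haplotype) and ``s & 1`` the mother's.
"""

from __future__ import annotations

import numpy as np


def _allele(genotype: int, which: int) -> int:
    """Allele of a phased genotype: which=0 paternal, which=1 maternal."""
    return (genotype >> 1) if which == 0 else (genotype & 1)


def _build_single() -> np.ndarray:
    """T[g_f, g_m, g_c]: each parent transmits either haplotype with
    probability one half (independent meioses)."""
    T = np.zeros((4, 4, 4))
    for gf in range(4):
        for gm in range(4):
            for gc in range(4):
                pat = 0.5 * ((_allele(gf, 0) == _allele(gc, 0))
                             + (_allele(gf, 1) == _allele(gc, 0)))
                mat = 0.5 * ((_allele(gm, 0) == _allele(gc, 1))
                             + (_allele(gm, 1) == _allele(gc, 1)))
                T[gf, gm, gc] = pat * mat
    return T


def _build_seg() -> np.ndarray:
    """T[s, g_f, g_m, g_c]: deterministic transmission given the segregation
    state (each parent's transmitted haplotype is fixed by ``s``)."""
    T = np.zeros((4, 4, 4, 4))
    for s in range(4):
        sf, sm = s >> 1, s & 1
        for gf in range(4):
            for gm in range(4):
                for gc in range(4):
                    T[s, gf, gm, gc] = float(
                        _allele(gf, sf) == _allele(gc, 0)
                        and _allele(gm, sm) == _allele(gc, 1)
                    )
    return T


#: single-locus transmission, (g_f, g_m, g_c)
T_SINGLE = _build_single()
#: segregation-conditional transmission, (s, g_f, g_m, g_c)
T_SEG = _build_seg()

#: Hamming distance between segregation-state labels
SEG_HAMMING = np.array(
    [[bin(a ^ b).count("1") for b in range(4)] for a in range(4)], dtype=float
)


def single_parent_transmission(parent_genotype: int, allele: int) -> float:
    """P(transmitted allele | parent's phased genotype), averaging the two
    haplotypes — the single-locus per-parent table (entries 0, 0.5 or 1)."""
    return 0.5 * ((_allele(parent_genotype, 0) == allele)
                  + (_allele(parent_genotype, 1) == allele))


def single_parent_transmission_seg(parent_genotype: int, allele: int,
                                   transmitted_haplotype: int) -> float:
    """P(transmitted allele | parent genotype, which haplotype was passed):
    deterministic 0/1 (0 = parent's paternal haplotype, 1 = maternal)."""
    return float(_allele(parent_genotype, transmitted_haplotype) == allele)


def transmission(g_child: int, g_mother: int, g_father: int) -> float:
    """Single-locus transmission probability tr(g_child | g_mother, g_father)."""
    return float(T_SINGLE[g_father, g_mother, g_child])


def transmission_with_seg(g_child: int, g_mother: int, g_father: int,
                          seg: np.ndarray) -> float:
    """Transmission marginalised over a segregation distribution ``seg`` (4,)."""
    seg = np.asarray(seg, dtype=float)
    return float(np.einsum("s,s->", seg, T_SEG[:, g_father, g_mother, g_child]))


def seg_transition(gamma) -> np.ndarray:
    """Locus-to-locus segregation transition matrix
    ``(1-gamma)^(2-n) gamma^n`` with n the Hamming distance (rows sum to 1)."""
    gamma = np.asarray(gamma, dtype=float)
    g = gamma[..., None, None]
    return (1.0 - g) ** (2.0 - SEG_HAMMING) * g**SEG_HAMMING


def seg_weighted_transmission(seg: np.ndarray) -> np.ndarray:
    """(..., 4, 4, 4) transmission tensors for per-locus segregation
    distributions ``seg`` (..., 4): sum_s seg[s] * T_SEG[s]."""
    return np.einsum("...s,sfmc->...fmc", seg, T_SEG)
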