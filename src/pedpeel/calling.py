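"""Threshold-based genotype calling, allele phasing, and yield/accuracy
metrics.

A genotype is called when the pooled unphased probability (the two
heterozygous phased states are pooled) of the best genotype reaches the
threshold; each parental allele is called independently from its marginal.
The comparison is inclusive (``>=``): the boundary case has measure zero
and inclusiveness keeps a probability of exactly ``threshold`` callable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NO_CALL
from .model import DOSAGE

DEFAULT_THRESHOLD = 0.98


def _check_threshold(threshold: float) -> None:
    if not 0.5 < threshold <= 1.0:
        raise ValueError("calling threshold must lie in (0.5, 1]")


@dataclass
class CallSet:
    """Called genotypes (0/1/2, 9 = no call), called parental alleles
    (0/1, 9 = no call) and genotype dosages for a block of individuals."""

    genotype: np.ndarray  # (..., ) int8
    paternal: np.ndarray
    maternal: np.ndarray
    dosage: np.ndarray  # float, in [0, 2]


def call_genotypes(probs: np.ndarray, threshold: float = DEFAULT_THRESHOLD
                   ) -> np.ndarray:
    """Unphased genotype calls from phased 4-state probabilities (..., 4)."""
    _check_threshold(threshold)
    unphased = np.stack(
        [probs[..., 0], probs[..., 1] + probs[..., 2], probs[..., 3]], axis=-1
    )
    best = unphased.argmax(axis=-1)
    best_p = np.take_along_axis(unphased, best[..., None], axis=-1)[..., 0]
    return np.where(best_p >= threshold, best, NO_CALL).astype(np.int8)


def call_phase(probs: np.ndarray, threshold: float = DEFAULT_THRESHOLD
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-parental-allele calls from the marginal allele probabilities.

    Calling each allele from its own marginal lets homozygous loci phase
    trivially and makes the phase yield count allele slots.
    """
    _check_threshold(threshold)
    p_pat1 = probs[..., 2] + probs[..., 3]  # paternal allele is A
    p_mat1 = probs[..., 1] + probs[..., 3]  # maternal allele is A
    out = []
    for p1 in (p_pat1, p_mat1):
        allele = np.full(p1.shape, NO_CALL, dtype=np.int8)
        allele[p1 >= threshold] = 1
        allele[(1.0 - p1) >= threshold] = 0
        out.append(allele)
    return out[0], out[1]


def make_callset(probs: np.ndarray, threshold: float = DEFAULT_THRESHOLD
                 ) -> CallSet:
    pat, mat = call_phase(probs, threshold)
    return CallSet(
        genotype=call_genotypes(probs, threshold),
        paternal=pat,
        maternal=mat,
        dosage=probs @ DOSAGE,
    )


# ----------------------------------------------------------------------
def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN when either vector has zero variance."""
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def yields_and_accuracy(calls: CallSet, true_paternal: np.ndarray,
                        true_maternal: np.ndarray,
                        probs: np.ndarray | None = None) -> pd.DataFrame:
    """Per-individual yield and accuracy metrics against simulated truth.

    Columns: ``geno_yield`` (fraction of loci with a genotype call),
    ``phase_yield`` (fraction of parental-allele slots called),
    ``call_acc`` / ``phase_call_acc`` (fraction of calls matching truth),
    ``geno_acc`` (Pearson r of dosage vs true 0/1/2) and ``phase_acc``
    (Pearson r of per-haplotype allele dosage vs true 0/1, both haplotypes
    concatenated). Correlations on zero-variance truth are NaN.
    """
    true_geno = true_paternal.astype(int) + true_maternal.astype(int)
    n_ind, n_loci = calls.genotype.shape
    rows = []
    for i in range(n_ind):
        g_called = calls.genotype[i] != NO_CALL
        p_called = calls.paternal[i] != NO_CALL
        m_called = calls.maternal[i] != NO_CALL
        n_allele_calls = int(p_called.sum() + m_called.sum())
        n_allele_ok = int(
            (calls.paternal[i][p_called] == true_paternal[i][p_called]).sum()
            + (calls.maternal[i][m_called] == true_maternal[i][m_called]).sum()
        )
        row = {
            "geno_yield": g_called.mean(),
            "phase_yield": n_allele_calls / (2 * n_loci),
            "call_acc": (
                (calls.genotype[i][g_called] == true_geno[i][g_called]).mean()
                if g_called.any() else float("nan")
            ),
            "phase_call_acc": (
                n_allele_ok / n_allele_calls if n_allele_calls else float("nan")
            ),
            "geno_acc": _safe_corr(calls.dosage[i], true_geno[i]),
        }
        if probs is not None:
            hap_dos = np.concatenate(
                [probs[i, :, 2] + probs[i, :, 3], probs[i, :, 1] + probs[i, :, 3]]
            )
            hap_true = np.concatenate([true_paternal[i], true_maternal[i]])
            row["phase_acc"] = _safe_corr(hap_dos, hap_true.astype(float))
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_metrics(per_individual: pd.DataFrame) -> pd.Series:
    """Median over individuals (the usual population summary)."""
    return per_individual.median(numeric_only=True)
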