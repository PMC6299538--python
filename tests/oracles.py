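"""Independent brute-force oracles used by the test suite.

These enumerate the full joint distribution directly and share no code
path with the iterative engines they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from pedpeel.model import founder_anterior
from pedpeel.pedigree import Pedigree
from pedpeel.transmission import T_SINGLE, seg_transition


def exact_marginals(ped: Pedigree, penetrance: np.ndarray,
                    p: float) -> np.ndarray:
    """Exact per-individual genotype marginals by summing the joint over
    all 4^N genotype configurations.

    ``penetrance`` is (N, 4) per-genotype likelihoods; founders carry a
    Hardy-Weinberg prior at allele frequency ``p``.
    """
    n = len(ped)
    prior = founder_anterior(p)
    configs = np.stack(
        np.meshgrid(*([np.arange(4)] * n), indexing="ij"), axis=-1
    ).reshape(-1, n)  # (4^n, n)
    w = np.ones(len(configs))
    for i in range(n):
        if ped.is_founder(i):
            w *= prior[configs[:, i]]
        else:
            w *= T_SINGLE[configs[:, ped.sire[i]], configs[:, ped.dam[i]],
                          configs[:, i]]
        w *= penetrance[i, configs[:, i]]
    marg = np.zeros((n, 4))
    for i in range(n):
        for g in range(4):
            marg[i, g] = w[configs[:, i] == g].sum()
    return marg / marg.sum(axis=1, keepdims=True)


def exact_segregation_posterior(evidence: np.ndarray,
                                gamma: np.ndarray) -> np.ndarray:
    """Exact HMM posteriors by enumerating all 4^L segregation paths."""
    e = np.asarray(evidence, dtype=float)
    L = e.shape[0]
    gamma = np.broadcast_to(np.asarray(gamma, dtype=float), (max(L - 1, 0),))
    G = seg_transition(gamma)
    post = np.zeros((L, 4))
    total = 0.0
    for path in itertools.product(range(4), repeat=L):
        w = 0.25 * e[0, path[0]]
        for j in range(1, L):
            w *= G[j - 1, path[j - 1], path[j]] * e[j, path[j]]
        total += w
        for j in range(L):
            post[j, path[j]] += w
    return post / total


def random_tree_pedigree(rng, n_max: int = 8) -> Pedigree:
    """A random loop-free pedigree with at most ``n_max`` individuals.

    Built by repeatedly either adding a founder pair with a child, or
    attaching a new child to an existing individual and a fresh founder
    mate — every mating introduces a new individual, so the marriage graph
    stays a tree.
    """
    records = [("i0", "0", "0"), ("i1", "0", "0"), ("i2", "i0", "i1")]
    k = 3
    size = rng.integers(3, n_max + 1)
    while k + 1 < size:
        parent = f"i{rng.integers(0, k)}"
        mate, child = f"i{k}", f"i{k + 1}"
        records.append((mate, "0", "0"))
        records.append((child, parent, mate))
        k += 2
    return Pedigree.from_records(records)
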