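"""Synthetic data: founder haplotypes, gene drop, array and read simulation,
and sequencing-budget accounting.

The generator emulates the study conditions the peelers are validated
against: biallelic founder haplotypes drawn i.i.d. per locus from a
minor-allele-frequency spectrum, Mendelian gene drop with Poisson crossover
counts along a physical map (default 1e-8 recombinations per base pair on a
1e8 bp chromosome), high/low-density SNP-array subsets, and read counts from
a Poisson-Gamma depth model (per-locus sequenceability ~ Gamma(4, 0.25),
mean 1) with a per-read error rate of 0.001. True haplotypes and true
segregation states are retained for oracle tests and accuracy metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, MarkerMap, ObservedData
from .pedigree import Pedigree

CHROMOSOME_BP = 100_000_000
RECOMB_PER_BP = 1e-8
READ_ERROR = 0.001
GAMMA_SHAPE = 4.0

#: default sequencing price list: library preparation per individual, and
#: per-coverage lane costs (non-linear, matching current industry pricing)
LIBRARY_COST = 39
COVERAGE_COST = {1: 68, 2: 136, 15: 408, 30: 816}


@dataclass
class HaplotypeSet:
    """True haplotypes (N, 2, L): axis 1 is (paternal, maternal). For
    non-founders, ``segregation`` (N, L) records which grandparental
    haplotype each parent transmitted (state index 2*father + mother,
    0 = paternal); founders carry -1."""

    haplotypes: np.ndarray
    segregation: np.ndarray
    frequencies: np.ndarray | None = None

    @property
    def genotypes(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1)


@dataclass
class SequencingPlan:
    """Per-individual targeted coverage and array status ('HD', 'LD', 'none')."""

    coverage: np.ndarray
    array_status: list[str]

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if np.any(self.coverage < 0):
            raise ValueError("coverages must be non-negative")


# ----------------------------------------------------------------------
def simulate_founders(n_founders: int, n_loci: int, seed,
                      spectrum: str = "uniform", low: float = 0.05,
                      high: float = 0.5, theta: float = 0.2,
                      max_retries: int = 100) -> HaplotypeSet:
    """Founder haplotypes i.i.d. per locus given a drawn allele frequency.

    ``spectrum`` is ``"uniform"`` (frequency ~ U(low, high)) or ``"beta"``
    (a neutral-like Beta(theta, theta) shape). Monomorphic loci are
    resampled so every locus segregates among the founders.
    """
    rng = np.random.default_rng(seed)
    if spectrum == "uniform":
        freqs = rng.uniform(low, high, size=n_loci)
    elif spectrum == "beta":
        freqs = np.clip(rng.beta(theta, theta, size=n_loci), 0.01, 0.99)
    else:
        raise ValueError(f"unknown frequency spectrum {spectrum!r}")
    haps = (rng.random((n_founders, 2, n_loci)) < freqs).astype(np.int8)
    for _ in range(max_retries):
        mono = haps.sum(axis=(0, 1)) % (2 * n_founders) == 0
        if not mono.any():
            break
        k = int(mono.sum())
        haps[:, :, mono] = (rng.random((n_founders, 2, k)) < freqs[mono]).astype(np.int8)
    else:
        raise RuntimeError("could not obtain segregating loci; frequencies degenerate?")
    seg = np.full((n_founders, n_loci), -1, dtype=np.int8)
    return HaplotypeSet(haplotypes=haps, segregation=seg, frequencies=freqs)


def _gamete(parent_haps: np.ndarray, positions: np.ndarray, length_bp: float,
            rate_per_bp: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis: returns (allele vector, per-locus source haplotype)."""
    n_x = rng.poisson(length_bp * rate_per_bp)
    start = rng.integers(0, 2)
    if n_x == 0:
        src = np.full(len(positions), start, dtype=np.int8)
    else:
        breakpoints = np.sort(rng.uniform(0, length_bp, size=n_x))
        src = ((start + np.searchsorted(breakpoints, positions)) % 2).astype(np.int8)
    return parent_haps[src, np.arange(len(positions))], src


def gene_drop(ped: Pedigree, founders: HaplotypeSet, mmap: MarkerMap,
              seed, rate_per_bp: float = RECOMB_PER_BP) -> HaplotypeSet:
    """Drop founder haplotypes through the pedigree with recombination.

    Founder rows of ``founders`` are assigned to pedigree founders in
    pedigree order. Every child's paternal haplotype is a crossover mosaic
    of its sire's two haplotypes (likewise maternal/dam), and the source
    haplotype at every locus is recorded as the true segregation state.
    """
    rng = np.random.default_rng(seed)
    n, L = len(ped), len(mmap)
    positions = mmap.position.astype(float)
    length_bp = max(float(positions[-1]), 1.0)
    founder_ids = ped.founders
    if founders.haplotypes.shape[0] < len(founder_ids):
        raise ValueError("not enough founder haplotype pairs for the pedigree")
    haps = np.zeros((n, 2, L), dtype=np.int8)
    seg = np.full((n, L), -1, dtype=np.int8)
    for k, i in enumerate(founder_ids):
        haps[i] = founders.haplotypes[k]
    for i in ped.peeling_order():
        if ped.is_founder(i):
            continue
        pat_allele, pat_src = _gamete(haps[ped.sire[i]], positions, length_bp,
                                      rate_per_bp, rng)
        mat_allele, mat_src = _gamete(haps[ped.dam[i]], positions, length_bp,
                                      rate_per_bp, rng)
        haps[i, 0] = pat_allele
        haps[i, 1] = mat_allele
        seg[i] = 2 * pat_src + mat_src
    return HaplotypeSet(haplotypes=haps, segregation=seg,
                        frequencies=founders.frequencies)


def simulate_reads(haps: HaplotypeSet, plan: SequencingPlan, seed,
                   alpha: float = GAMMA_SHAPE,
                   error_rate: float = READ_ERROR) -> ObservedData:
    """Poisson-Gamma read counts.

    Per-locus sequenceability ``y_j ~ Gamma(alpha, 1/alpha)`` (mean 1,
    shared across individuals); read depth per individual and locus
    ``~ Poisson(x_i * y_j)``; each read samples one of the two true alleles
    uniformly and is flipped with probability ``error_rate``.
    """
    rng = np.random.default_rng(seed)
    n, _, L = haps.haplotypes.shape
    y = rng.gamma(alpha, 1.0 / alpha, size=L)
    depth = rng.poisson(plan.coverage[:, None] * y[None, :])
    p_alt_true = haps.haplotypes.sum(axis=1) / 2.0  # 0, .5 or 1
    alt_true = rng.binomial(depth, p_alt_true)
    ref_true = depth - alt_true
    # errors flip reads in both directions
    alt_obs = (rng.binomial(alt_true, 1.0 - error_rate)
               + rng.binomial(ref_true, error_rate)) if error_rate > 0 else alt_true
    obs = ObservedData.empty(n, L)
    obs.ref_reads = (depth - alt_obs).astype(np.int32)
    obs.alt_reads = alt_obs.astype(np.int32)
    return obs


def make_array_data(haps: HaplotypeSet, plan: SequencingPlan,
                    hd_loci: np.ndarray, ld_loci: np.ndarray,
                    seed=0, eps: float = 0.0) -> ObservedData:
    """Unphased array genotypes at the HD or LD marker subset.

    With probability ``eps`` an observed genotype is flipped to one of the
    other two values uniformly (default 0: error-free fixtures).
    """
    if not np.all(np.isin(ld_loci, hd_loci)):
        raise ValueError("LD loci must be a subset of HD loci")
    rng = np.random.default_rng(seed)
    n, _, L = haps.haplotypes.shape
    geno = haps.genotypes
    obs = ObservedData.empty(n, L)
    for i, status in enumerate(plan.array_status):
        if status == "HD":
            loci = hd_loci
        elif status == "LD":
            loci = ld_loci
        elif status == "none":
            continue
        else:
            raise ValueError(f"unknown array status {status!r}")
        g = geno[i, loci].astype(np.int8)
        if eps > 0:
            flip = rng.random(len(loci)) < eps
            shift = rng.integers(1, 3, size=len(loci))
            g = np.where(flip, (g + shift) % 3, g).astype(np.int8)
        obs.genotypes[i, loci] = g
    return obs


def merge_observations(*parts: ObservedData) -> ObservedData:
    """Combine array and read observations for the same individuals/loci."""
    out = ObservedData.empty(parts[0].n_individuals, parts[0].n_loci)
    for part in parts:
        got = part.genotypes != MISSING
        out.genotypes[got] = part.genotypes[got]
        out.ref_reads += part.ref_reads
        out.alt_reads += part.alt_reads
    return out


# ----------------------------------------------------------------------
def sequencing_cost(counts: dict[int, int],
                    library_cost: float = LIBRARY_COST,
                    coverage_cost: dict[int, float] | None = None
                    ) -> tuple[float, dict[int, float]]:
    """Total sequencing budget and per-coverage breakdown.

    ``counts`` maps coverage tier (x) to the number of individuals; each
    individual costs one library preparation plus the tier's lane cost.
    """
    table = COVERAGE_COST if coverage_cost is None else coverage_cost
    breakdown = {}
    for cov, n in counts.items():
        if cov not in table:
            raise ValueError(f"no cost entry for coverage {cov}x")
        breakdown[cov] = n * (library_cost + table[cov])
    return float(sum(breakdown.values())), breakdown


# ----------------------------------------------------------------------
@dataclass
class SimBundle:
    """A simulated dataset plus the generating truth."""

    ped: Pedigree
    mmap: MarkerMap
    obs: ObservedData
    truth: HaplotypeSet
    plan: SequencingPlan
    focal: int | None = None


def make_disconnected_family(coverage_focal: float, coverage_parents: float,
                             coverage_grandparents: float, n_loci: int,
                             n_set_a: int, seed,
                             spectrum: str = "uniform") -> SimBundle:
    """A three-generation, seven-member family: a focal individual, its two
    parents and four grandparents, analysed in isolation.

    All members carry high-density array data (the set-A markers); sequence
    coverage is as requested per generation. Truth is retained.
    """
    ped = Pedigree.from_records([
        ("gp1", "0", "0"), ("gp2", "0", "0"), ("gp3", "0", "0"), ("gp4", "0", "0"),
        ("sire", "gp1", "gp2"), ("dam", "gp3", "gp4"),
        ("focal", "sire", "dam"),
    ])
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31, size=3)
    mmap = MarkerMap.uniform(n_loci, CHROMOSOME_BP, n_set_a)
    founders = simulate_founders(4, n_loci, seeds[0], spectrum=spectrum)
    truth = gene_drop(ped, founders, mmap, seeds[1])
    cov = np.array([coverage_grandparents] * 4
                   + [coverage_parents] * 2 + [coverage_focal])
    plan = SequencingPlan(coverage=cov, array_status=["HD"] * 7)
    reads = simulate_reads(truth, plan, seeds[2])
    arrays = make_array_data(truth, plan, mmap.set_a_indices,
                             mmap.set_a_indices[:0])
    obs = merge_observations(arrays, reads)
    return SimBundle(ped=ped, mmap=mmap, obs=obs, truth=truth, plan=plan,
                     focal=ped.index_of("focal"))


def random_pedigree(n_founders: int, n_generations: int, n_per_generation: int,
                    seed) -> Pedigree:
    """A random multi-generation pedigree: each offspring draws a sire and a
    dam (distinct) uniformly from the previous generation."""
    rng = np.random.default_rng(seed)
    records = [(f"g0_{k}", "0", "0") for k in range(n_founders)]
    prev = [r[0] for r in records]
    for g in range(1, n_generations + 1):
        cur = []
        for k in range(n_per_generation):
            s, d = rng.choice(len(prev), size=2, replace=False)
            name = f"g{g}_{k}"
            records.append((name, prev[s], prev[d]))
            cur.append(name)
        prev = cur
    return Pedigree.from_records(records)


def simulate_population(ped: Pedigree, n_loci: int, n_set_a: int, seed,
                        coverage: np.ndarray | None = None,
                        array_status: list[str] | None = None,
                        n_ld: int | None = None,
                        spectrum: str = "uniform") -> SimBundle:
    """Simulate genomes and data for an arbitrary pedigree.

    ``coverage`` defaults to 0x everywhere; ``array_status`` defaults to HD
    for everyone. The LD array is the first ``n_ld`` set-A markers spread
    evenly (default one quarter of set A).
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31, size=3)
    mmap = MarkerMap.uniform(n_loci, CHROMOSOME_BP, n_set_a)
    founders = simulate_founders(len(ped.founders), n_loci, seeds[0],
                                 spectrum=spectrum)
    truth = gene_drop(ped, founders, mmap, seeds[1])
    if coverage is None:
        coverage = np.zeros(len(ped))
    if array_status is None:
        array_status = ["HD"] * len(ped)
    plan = SequencingPlan(coverage=coverage, array_status=array_status)
    reads = simulate_reads(truth, plan, seeds[2])
    hd = mmap.set_a_indices
    if n_ld is None:
        n_ld = max(1, len(hd) // 4)
    ld = hd[np.linspace(0, len(hd) - 1, n_ld).round().astype(int)]
    arrays = make_array_data(truth, plan, hd, ld)
    obs = merge_observations(arrays, reads)
    return SimBundle(ped=ped, mmap=mmap, obs=obs, truth=truth, plan=plan)
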