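"""Scaled-down experiment runner: disconnected families, family-vs-full
pedigree calling, and whole-pedigree imputation.

Each scenario generates data with the synthetic-data module, runs the
appropriate peeler, and returns tidy tables of yield/accuracy metrics.
Every run is fully reproducible from (scenario, scale parameters, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calling, sim
from .hybrid import run_hybrid
from .pedigree import Pedigree

FOCAL_GRID = (1, 2, 5, 15, 30)
RELATIVE_CONFIGS = ((0, 0), (30, 0), (30, 30))  # (parents, grandparents)

#: the platform's per-read error rate — treated as known in family analyses
PLATFORM_SEQ_ERROR = sim.READ_ERROR


def _fixed_param_run(ped, obs, mmap):
    """Hybrid peeling with parameters fixed at their platform values.

    Per-locus estimation of allele frequency and error rates needs many
    informative individuals per locus; inside a seven-member family with a
    single sequenced member the mismatch-based estimators are degenerate
    (a heterozygote's minority reads get reclassified as sequencing errors
    exactly when its genotype drifts homozygous, a positive feedback), so
    family-scale analyses run with parameters fixed.
    """
    from .model import ModelParams

    params = ModelParams.initial(obs, positions_bp=mmap.position,
                                 delta=PLATFORM_SEQ_ERROR)
    return run_hybrid(ped, obs, mmap, params,
                      est_maf=False, est_errors=False, est_recomb=False)


def _focal_metrics(bundle: sim.SimBundle, threshold: float) -> dict:
    res = _fixed_param_run(bundle.ped, bundle.obs, bundle.mmap)
    calls = calling.make_callset(res.probs, threshold)
    metrics = calling.yields_and_accuracy(
        calls, bundle.truth.haplotypes[:, 0], bundle.truth.haplotypes[:, 1],
        probs=res.probs,
    )
    return metrics.iloc[bundle.focal].to_dict()


def disconnected_families(n_reps: int = 5, n_loci: int = 2000,
                          n_set_a: int = 200, seed: int = 0,
                          focal_grid=FOCAL_GRID,
                          relative_configs=RELATIVE_CONFIGS,
                          threshold: float = calling.DEFAULT_THRESHOLD
                          ) -> pd.DataFrame:
    """Coverage-grid sweep over isolated seven-member families.

    Returns one row per (focal coverage, parent coverage, grandparent
    coverage, replicate) with the focal individual's yields and accuracies.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for focal_cov in focal_grid:
        for par_cov, gp_cov in relative_configs:
            for rep in range(n_reps):
                bundle = sim.make_disconnected_family(
                    focal_cov, par_cov, gp_cov, n_loci, n_set_a,
                    seed=int(rng.integers(0, 2**31)),
                )
                row = {"focal_cov": focal_cov, "parent_cov": par_cov,
                       "gp_cov": gp_cov, "rep": rep}
                row.update(_focal_metrics(bundle, threshold))
                rows.append(row)
    return pd.DataFrame(rows)


def pooled_call_fractions(grid: pd.DataFrame) -> tuple[float, float]:
    """Pooled fractions of correct genotype calls and correct phased alleles
    across a disconnected-family grid table (weighting each row's accuracy
    by its number of calls)."""
    g_w = grid.geno_yield.to_numpy()
    p_w = grid.phase_yield.to_numpy()
    g_acc = grid.call_acc.to_numpy()
    p_acc = grid.phase_call_acc.to_numpy()
    g_ok = np.isfinite(g_acc) & (g_w > 0)
    p_ok = np.isfinite(p_acc) & (p_w > 0)
    geno = float((g_acc[g_ok] * g_w[g_ok]).sum() / g_w[g_ok].sum())
    phase = float((p_acc[p_ok] * p_w[p_ok]).sum() / p_w[p_ok].sum())
    return geno, phase


def headline_yields(seed: int = 0, n_reps: int = 10, n_loci: int = 2000,
                    n_set_a: int = 200,
                    threshold: float = calling.DEFAULT_THRESHOLD) -> dict:
    """Mean focal yields (%) for the two headline coverage configurations:
    a 30x focal with array-only relatives, and a 30x focal with 30x parents."""
    rng = np.random.default_rng(seed)
    out = {"geno_yield_30x_alone": [], "geno_yield_30x_parents30x": [],
           "phase_yield_30x_parents30x": []}
    for rep in range(n_reps):
        seeds = rng.integers(0, 2**31, size=2)
        alone = sim.make_disconnected_family(30, 0, 0, n_loci, n_set_a,
                                             seed=int(seeds[0]))
        m = _focal_metrics(alone, threshold)
        out["geno_yield_30x_alone"].append(m["geno_yield"])
        both = sim.make_disconnected_family(30, 30, 0, n_loci, n_set_a,
                                            seed=int(seeds[1]))
        m = _focal_metrics(both, threshold)
        out["geno_yield_30x_parents30x"].append(m["geno_yield"])
        out["phase_yield_30x_parents30x"].append(m["phase_yield"])
    return {k: 100.0 * float(np.mean(v)) for k, v in out.items()}


def _family_subpedigree(ped: Pedigree, focal: int) -> tuple[Pedigree, list[int]]:
    """The focal individual plus its parents and grandparents, isolated."""
    members = [focal]
    parents = [p for p in (ped.sire[focal], ped.dam[focal]) if p >= 0]
    members.extend(parents)
    for p in parents:
        members.extend(q for q in (ped.sire[p], ped.dam[p]) if q >= 0)
    members = list(dict.fromkeys(members))
    member_set = set(members)
    records = []
    for i in members:
        s = ped.ids[ped.sire[i]] if ped.sire[i] in member_set else "0"
        d = ped.ids[ped.dam[i]] if ped.dam[i] in member_set else "0"
        records.append((ped.ids[i], s, d))
    sub = Pedigree.from_records(records)
    return sub, members


def full_pedigree_calling(n_founders: int = 12, n_generations: int = 3,
                          n_per_generation: int = 24, n_loci: int = 500,
                          n_set_a: int = 50, n_sequenced: int = 24,
                          seed: int = 0,
                          threshold: float = calling.DEFAULT_THRESHOLD
                          ) -> pd.DataFrame:
    """Paired comparison: peel each sequenced individual inside its
    disconnected family versus inside the full pedigree.

    Returns one row per sequenced individual with ``family_`` and ``full_``
    prefixed yield/accuracy columns.
    """
    rng = np.random.default_rng(seed)
    ped = sim.random_pedigree(n_founders, n_generations, n_per_generation,
                              int(rng.integers(0, 2**31)))
    coverage = np.zeros(len(ped))
    candidates = [i for i in range(len(ped)) if ped.generation[i] >= 1]
    chosen = rng.choice(candidates, size=min(n_sequenced, len(candidates)),
                        replace=False)
    tiers = np.array([1, 2, 15, 30])
    coverage[chosen] = rng.choice(tiers, size=len(chosen))
    bundle = sim.simulate_population(
        ped, n_loci, n_set_a, int(rng.integers(0, 2**31)), coverage=coverage
    )

    full_res = _fixed_param_run(ped, bundle.obs, bundle.mmap)  # fixed params on both arms
    full_calls = calling.make_callset(full_res.probs, threshold)
    full_metrics = calling.yields_and_accuracy(
        full_calls, bundle.truth.haplotypes[:, 0], bundle.truth.haplotypes[:, 1],
        probs=full_res.probs,
    )

    rows = []
    for i in sorted(chosen):
        sub, members = _family_subpedigree(ped, int(i))
        order = [sub.index_of(ped.ids[m]) for m in members]
        sub_obs = type(bundle.obs)(
            genotypes=bundle.obs.genotypes[members][np.argsort(order)],
            ref_reads=bundle.obs.ref_reads[members][np.argsort(order)],
            alt_reads=bundle.obs.alt_reads[members][np.argsort(order)],
        )
        # re-align rows to the sub-pedigree's own individual order
        sel = np.array(members)[np.argsort(order)]
        sub_res = _fixed_param_run(sub, sub_obs, bundle.mmap)
        sub_calls = calling.make_callset(sub_res.probs, threshold)
        sub_metrics = calling.yields_and_accuracy(
            sub_calls,
            bundle.truth.haplotypes[sel, 0], bundle.truth.haplotypes[sel, 1],
            probs=sub_res.probs,
        )
        focal_row = sub_metrics.iloc[int(np.flatnonzero(sel == i)[0])]
        row = {"id": ped.ids[int(i)], "coverage": coverage[int(i)]}
        row.update({f"family_{k}": v for k, v in focal_row.items()})
        row.update({f"full_{k}": v for k, v in full_metrics.iloc[int(i)].items()})
        rows.append(row)
    return pd.DataFrame(rows)


def imputation(n_founders: int = 30, n_generations: int = 4,
               n_per_generation: int = 90, n_loci: int = 1000,
               n_set_a: int = 60, seed: int = 0,
               frac_hd: float = 0.7, frac_ld: float = 0.15,
               n_sequenced: int = 40) -> pd.DataFrame:
    """Whole-pedigree imputation of non-sequenced individuals.

    A multi-generation pedigree in which a subset of individuals carries
    mixed-coverage sequence and individuals are HD-arrayed, LD-arrayed or
    non-genotyped at random. Returns the median genotype-dosage accuracy of
    non-sequenced individuals stratified by array status.
    """
    rng = np.random.default_rng(seed)
    ped = sim.random_pedigree(n_founders, n_generations, n_per_generation,
                              int(rng.integers(0, 2**31)))
    n = len(ped)
    statuses = rng.choice(
        ["HD", "LD", "none"], size=n,
        p=[frac_hd, frac_ld, 1.0 - frac_hd - frac_ld],
    ).tolist()
    coverage = np.zeros(n)
    chosen = rng.choice(n, size=min(n_sequenced, n), replace=False)
    tiers = np.array([1, 2, 15, 30])
    coverage[chosen] = rng.choice(tiers, size=len(chosen))
    bundle = sim.simulate_population(
        ped, n_loci, n_set_a, int(rng.integers(0, 2**31)),
        coverage=coverage, array_status=statuses,
    )
    res = run_hybrid(ped, bundle.obs, bundle.mmap)
    true_geno = bundle.truth.genotypes
    rows = []
    for i in range(n):
        if coverage[i] > 0:
            continue
        x = res.probs[i] @ np.array([0.0, 1.0, 1.0, 2.0])
        t = true_geno[i].astype(float)
        acc = (np.corrcoef(x, t)[0, 1]
               if np.std(t) > 0 and np.std(x) > 0 else np.nan)
        rows.append({"id": ped.ids[i], "array": statuses[i], "accuracy": acc})
    per_ind = pd.DataFrame(rows)
    return per_ind


def run_experiment(scenario: str, seed: int = 0, **scale) -> pd.DataFrame:
    """Dispatch by scenario name (``disconnected_families``,
    ``full_pedigree_calling`` or ``imputation``)."""
    scenarios = {
        "disconnected_families": disconnected_families,
        "full_pedigree_calling": full_pedigree_calling,
        "imputation": imputation,
    }
    if scenario not in scenarios:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {sorted(scenarios)}")
    return scenarios[scenario](seed=seed, **scale)
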