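# Methods

This note documents the model implemented in `pedpeel`, the numerical and
design choices that were genuinely open, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Model

### Phased genotypes and the three peeling terms

Every individual × locus carries a distribution over the four ordered
genotypes (aa, aA, Aa, AA); the first allele is the paternally inherited
one, so aA and Aa are distinct states and phase falls out of the genotype
distribution for free. The genotype probability is the normalised product
of an anterior term (from parents), a posterior term (from offspring and
mates) and a penetrance term (the individual's own data).

Penetrance: with array data, consistent phased genotypes get 1−ε and the
rest ε (an unphased het call is consistent with both aA and Aa); with read
counts the four likelihoods are ((1−δ)^nref δ^nalt, ½^(nref+nalt),
½^(nref+nalt), δ^nref (1−δ)^nalt), evaluated in log space so depths in the
hundreds stay finite. When both data types are present at a locus their
penetrances multiply. Individuals without data carry a uniform penetrance.

Anterior: founders (and each anonymous parent standing in for an unknown
parent slot) use the Hardy–Weinberg prior ((1−p)², p(1−p), p(1−p), p²).
Non-founders sum the transmission function over the parents' joint
distribution, which is assembled from each parent's anterior × penetrance ×
posterior-excluding-this-family, times the family's joint posterior table
excluding the focal child. This exclusion structure guarantees that no
individual's information flows back into itself within one update — the
engine's central invariant, and the reason converged results on loop-free
pedigrees equal exact sum-product marginals (verified against brute-force
enumeration in the tests).

Posterior: per mate pair, a 4×4 table over the parents' joint genotypes,
the product over shared children of the child's transmission-weighted
penetrance × posterior; per parent, the product over that parent's mate
pairs of the table collapsed against the mate's own term. The paper-level
definition of the mate's term in this collapse is under-determined; we use
mate-anterior × mate-penetrance × mate-posterior-excluding-this-pair,
mirroring the anterior's exclusion logic, to avoid double-counting the
shared family.

Updates sweep family-by-family: peel-down in increasing generation order,
peel-up in reverse, for up to 20 cycles (early stop when no genotype
probability moves by more than 1e-4; the tolerance and cycle count are
arguments). Families are processed in a canonical order (generation, then
parent ids) so results do not depend on input record order. Pedigrees with
loops reuse the same iteration and are therefore approximate — no
junction-tree exact inference is attempted.

### Segregation states and the multi-locus HMM

Multi-locus peeling refines the transmission function with a per-individual
distribution over segregation states s ∈ {pp, pm, mp, mm} (father's ×
mother's transmitted haplotype; given s, transmission is deterministic).
Both parents' segregations are tracked jointly — the state space is exactly
4 per individual, not 2 independent pairs. Along the chromosome the states
follow a Markov chain with transition (1−γ)^(2−n) γ^n for n state changes;
per-locus evidence combines the individual's penetrance × posterior with
both parents' terms and the child-excluded family table (the individual's
own anterior is deliberately excluded — it is itself built from the
segregation being estimated). The forward–backward algorithm yields the
segregation posterior at every locus.

One choice here deviates from the obvious reading of the source recursions:
the segregation distribution used inside *same-locus* transmission updates
is the prediction product forward × backward, *excluding* the local
evidence at that locus, while the full forward × evidence × backward
posterior is what gets reported, interpolated to dense loci, and used for
recombination estimation. Including the local evidence would feed an
individual's locus-j data into its own locus-j anterior (a double count);
excluding it preserves the information-exclusivity invariant and makes two
reductions exact, both tested: a single-locus chromosome reproduces plain
single-locus peeling, and γ = 0.5 (no linkage information) reproduces it at
every locus. When set A is dense the two variants are nearly identical
anyway, since the neighbouring loci dominate the posterior.

Recombination rates are re-estimated per interval from the pairwise
posterior over adjacent segregation states (forward × evidence at j,
transition, evidence × backward at j+1, normalised per individual per
interval): γ̂ = mean expected number of segregation changes / 2 (one
meiosis per parent), clamped to [1e-6, 0.49]. The initial γ comes from
physical distance at 1 cM/Mb.

### Hybrid peeling

Multi-locus peeling runs on the sparse set A only; the segregation
posteriors are then frozen and linearly interpolated by physical distance
to every dense (set B) locus: seg(k) = (1−a)·seg(j) + a·seg(j+1) with a =
d(k,j)/d(j,j+1), the proportional distance from the left flank (loci
outside the A span clamp to the nearest A locus). As printed, the source
recursion places the weight a on the *left* flank even though a is defined
as the distance *from* the left flank, which would make a B locus lean on
its *far* neighbour; we implement the evidently intended orientation
(weight 1−a on the left flank). The choice is immaterial when A is dense —
flanking segregations are then nearly equal — but the intended orientation
is the defensible one at any density, and is pinned by a regression test.

Each B locus is then peeled single-locus style with the segregation-aware
transmission and its frozen, interpolated segregation. Given that frozen
segregation, B loci are pure, independent work units: the engine streams
them in chunks, any chunking yields bit-identical results (tested for 1, 4
and 17 chunks), memory scales with individuals only, and a segregation
checkpoint file lets the B phase be distributed across processes. A-locus
results are taken from the multi-locus phase; the B phase feeds nothing
back into segregation.

## Parameters

| parameter | meaning | default | bounds |
|---|---|---|---|
| p | alternative-allele frequency, per locus | pooled data mean (+1/+1 pseudocount) | [1e-4, 1−1e-4] |
| ε | array genotype error, per locus | 0.01 | [1e-4, 0.1] |
| δ | per-read sequencing error, per locus | 0.01 (0.001 when the platform rate is known) | [1e-4, 0.1] |
| γ | recombination per adjacent set-A interval | physical distance × 1 cM/Mb | [1e-6, 0.49] |
| threshold | calling threshold on pooled/allele probabilities | 0.98, inclusive (≥) | (0.5, 1] |
| cycles | peel-down/up sweeps per phase | 20, early stop at max Δp < 1e-4 | ≥ 1 |

All probability tables are floored at 1e-10 after each normalisation and
renormalised, so long products never collapse to hard zeros; products are
accumulated in linear space, which is safe because every factor is a
normalised 4- or 16-entry table.

When enabled, p, ε, δ (and γ in the multi-locus phase) are re-estimated
once per cycle from the current genotype probabilities: p as half the mean
founder dosage (the raw founder-dosage average lies in [0,2]; the factor ½
makes it a frequency, which the Hardy–Weinberg prior requires), ε as the
mean posterior disagreement with the array calls, δ from reads that
contradict a confidently homozygous genotype (heterozygotes are ignored).

**When estimation is appropriate.** These estimators average over the
individuals informative at a locus. At population scale (hundreds of
individuals, relatives corroborating each genotype) they are stable and
recover simulated truth (δ within ±20%, γ within ±30% in the tests). In a
seven-member family with a single sequenced member they are degenerate:
a true heterozygote with a skewed read split drifts toward homozygous,
its minority reads are then counted as errors, δ inflates to its clamp,
and the family-internal allele frequency follows the focal genotype — a
positive feedback that produces confident wrong calls. The family-scale
analyses (and the disconnected-family experiment runner) therefore fix the
parameters at their platform values: δ = 0.001 (the known per-read error),
ε = 0.01, p at its pooled-data initial estimate, γ from the map. Estimation
remains the default for population-scale runs.

The estimators use the *current* genotype probabilities, which include each
individual's own penetrance; with few informative individuals this makes
even the ε estimator self-reinforcing (estimated mismatch ≈ 3ε under a flat
prior). This is inherent to the published update and only safe when many
corroborated genotypes dominate the average — hence the rule above.

## Synthetic data

The generator emulates the study conditions end to end: founder haplotypes
i.i.d. per locus given a frequency drawn from a uniform(0.05, 0.5) or
Beta-shaped spectrum (monomorphic loci are resampled); Mendelian gene drop
with Poisson(L·r) crossovers per meiosis placed uniformly (default r =
1e-8/bp on a 1e8 bp chromosome) and the true segregation state recorded at
every locus; HD and LD array subsets with optional genotyping errors;
Poisson-Gamma read counts (per-locus sequenceability Gamma(shape 4, scale
0.25), mean 1, shared across individuals; per-read error 0.001); and the
non-linear sequencing price list ($39 library; $68/1x, $136/2x, $408/15x,
$816/30x).

What it does **not** emulate: linkage disequilibrium among *founder*
haplotypes (founder loci are independent given their frequencies — pedigree
linkage, which is what peeling exploits, is created by the gene drop), a
coalescent frequency spectrum, demographic structure, mutation,
base-quality variation, or reference-alignment artefacts. Consequently the
tests demonstrate correctness of the inference machinery and
reproduce yield/accuracy levels under matched model assumptions; absolute
yields on real data additionally depend on the founder-haplotype structure
the generator does not model.

Scales used in the shipped studies (chosen so everything runs in minutes on
one CPU): disconnected families at 2,000 loci with 200 sparse markers and
5–10 replicates per coverage configuration; family-vs-full-pedigree
comparison at ~100 individuals × 500 loci; whole-pedigree imputation at
~390 individuals × 1,000 loci with 60 sparse markers. The sparse:dense
ratio (1:10) is far higher than a real HD-array:sequence ratio (~1:350), so
array-only yield contributions are proportionally inflated at low coverage;
the high-coverage headline numbers are dominated by sequence and transfer
as shown by the acceptance script.

## Degenerate inputs and edge cases

Unknown single parents become private anonymous founders (half-sibs are not
promoted to full sibs); childless individuals carry a uniform posterior; a
chromosome with a single locus, an empty set B, or a founders-only pedigree
all reduce to the simpler peeler exactly; an empty set A falls back to
single-locus peeling with a warning; zero-variance truth vectors yield NaN
correlations rather than a value; ties in the calling argmax resolve to the
lower genotype code (measure-zero in practice).

## Limitations

Loops are handled by iteration, not exact inference; phasing of a parent
from its children needs several offspring and stays uncertain in small
sibships (visible as lower phase yield without grandparent data);
unrelated individuals receive essentially no information (no LD model —
the deliberate scope boundary of a pedigree method); multi-allelic sites,
sex chromosomes and per-individual error rates are out of scope. The
experiment pedigrees are random mating graphs, not a literature breeding
structure; orderings (full pedigree ≥ family-only; array density orders
imputation accuracy) replicate, absolute imputation accuracies at this
scale sit below the population-scale values.
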