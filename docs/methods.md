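# Methods

## Conventions and parameters

All models are haploid.  For a population of size N and a window of L bp
with per-bp per-generation mutation rate μ, the scaled mutation rate is
θ = 2NμL; one coalescent time unit is N generations, and mutations fall on
a genealogy as a Poisson process of rate θ/2 per lineage per unit.  The
scaled recombination rate is ρ = 2NcL (c the per-bp crossover rate) and the
scaled growth rate α = 2N₀r with r the per-generation growth rate of a
population of current size N₀ (N(t) = N₀e^{−rt} backward in time).
Defaults throughout: L = 50 000 bp, N = 20 000 for neutral theory and
coalescent simulation, N = 2000 for forward sweep simulation, θ ∈ {24, 48},
ρ ∈ {0, 25}, ℓ = 1.  `DemographyParams` centralizes the unit conversions
(`growth_rate`, `mu_per_bp`, `recomb_per_bp`).

Scores are computed with integer sample counts, never proportions, so all
score arithmetic is exact; the SFS identity
mean ℓ-HAF = (1/n) Σ_w ξ_w w^{ℓ+1} holds as rational arithmetic and is
tested as such.

## Expectations

**Constant size.**  E[ξ_w] = θ/w gives E[ℓ-HAF] = (θ/n) Σ_{w=1}^{n−1} wℓ.
A second, independent derivation decomposes the genealogy into epochs (the
span with exactly k lineages, k = n..2): the k clades of epoch k have sizes
W_{k,i} with rising-factorial moments E[(W_{k,i})^{(q)}] = q! n^{(q)}/k^{(q)},
converted to ordinary moments with Stirling numbers of the second kind
(w^ℓ = Σ_q (−1)^{ℓ−q} S(ℓ,q) w^{(q)}).  With constant-size epoch durations
E[T_k] = 2N/(k(k−1)) the two routes agree exactly in rational arithmetic
(`expected_ell_haf_constant_epoch`), which the suite verifies for random
(θ, n) at ℓ = 1, 2.

**Exponential growth.**  Epoch durations are obtained by the
conditional-expectation recursion, evaluated for k = n down to 2:

    r·t_k = e^{x_k} E₁(x_k),   x_k = k(k−1) e^{r·τ_k} / α,

with τ_k the accumulated time of the younger epochs.  This follows from
integrating the time-inhomogeneous coalescence rate k(k−1)e^{rt}/(2N₀); the
placement of e^{r·τ_k} in the numerator matters — the population shrinks
backward in time, so old epochs are short.  E₁ is evaluated with
scipy's `exp1` for x < 500 and a Lentz continued fraction for
e^x E₁(x) beyond (the product is needed directly; e^x alone overflows),
accurate to ~1e−14 across the switchover.  The ℓ-HAF expectation then sums
(r·t_k) against the same Stirling/rising-factorial machinery; only the E₁
evaluation is floating point.  At θ=48, n=200, α=80 this gives 126.9, and
the α→0 limit recovers the constant-size closed form to 0.1%.

**Sweep phase.**  With carrier fraction ν in a sample of n and strong
selection, the instant-sweep limit gives

    E[1-HAF | carrier]     ≈ θn( (ν+1)/2 − 1/((1−ν)n + 1) )
    E[1-HAF | non-carrier] ≈ θn( 1/2 + 1/(2n) − 1/((1−ν)n + 1) )

Both reduce exactly to the neutral mean θ(n−1)/2 at ν = 1/n (a single
carrier is statistically invisible).  Maximizing the carrier curve over ν
gives the peak θn(1 − 1/√(2n))² ≈ θn, attained just short of fixation and
independent of the selection coefficient s.  These are Ns → ∞
approximations: they model the carriers as collapsing instantaneously onto
the founder haplotype, with the remaining (1−ν)n + 1 lineages coalescing
neutrally.  In a finite-s Wright–Fisher population the non-carrier class
shrinks during the sweep, which accelerates coalescence among sampled
non-carriers (an effective bottleneck of order ∫dν/(Nσ ν(1−ν)²) pairwise
coalescence probability, σ = s/2 the haploid advantage).  This prunes rare
variation from non-carriers and fixes founder-background alleles in the
sample, pulling both curves a few percent of θn below the instant-sweep
limit near fixation — visibly so for θn large.  The simulator reproduces
the non-carrier curve to ±0.003·θn at mid-ν and tracks the carrier curve
within ~0.05·θn up to ν = 0.9 at s = 0.08, N = 2000; the residual
deviation at high ν is the finite-s effect, not simulator bias (it shrinks
as s or N grows).

## Simulators

**Internal coalescent (ρ = 0).**  Standard Kingman merges with
Exp(k(k−1)/2) epoch times; exponential growth by deterministic time
rescaling (the cumulative hazard inverts in closed form, so all epoch times
are drawn vectorized).  Mutations are Poisson per (epoch × lineage) in one
flattened draw; infinite-sites positions are uniform on the window with
collisions redrawn.  Each replicate records its full genealogy (node
table + mutation placements), from which the haplotype matrix is built by
the contiguous-clade leaf ordering.  The epoch decomposition
(`genealogy_epoch_decomposition`) recomputes per-epoch lineage mutation
counts and clade sizes from node times alone and must reproduce every
haplotype's ℓ-HAF exactly — an internal consistency oracle run on 10⁴
trees in the suite.

**Recombination backend (ρ > 0).**  Delegated to msprime
(`sim_ancestry`, ploidy = 1, so one time unit = N generations, matching the
haploid θ convention — verified empirically in the suite via Watterson's
estimator and pairwise TMRCA) with infinite-sites binary mutations.  These
samples carry no single-tree genealogy.  Recombination leaves the
expectations unchanged and shrinks the between-sample variance of the mean
score, which the suite asserts.

**Forward Wright–Fisher sweeps.**  N haploid genomes; carriers of the
favored allele have viability 1 + s/2 (half the diploid homozygote
advantage — the heterozygosity-0.5 convention for phased data).  Each
generation: every offspring draws a uniform parent (two parents and a
single uniform crossover with probability ρ/(2N)), survives rejection
sampling proportional to fitness, and gains Poisson(θ/(2N)) new
infinite-sites mutations.  Genomes are persistent nodes (parent pointer +
private mutations, or a crossover node), so copying is O(1) and full
mutation sets are resolved only for sampled individuals.  The population
starts at mutation–drift equilibrium, seeded from a coalescent sample of
all N genomes (without this standing variation the θn scale of the carrier
curve cannot arise).  Hard sweeps place the favored mutation on one random
genome (ν₀ = 1/N); soft sweeps from standing variation promote the
existing neutral allele whose frequency is closest to the requested ν₀.
Trajectories that lose the favored allele restart with a fresh origin and
random stream, keeping the trial's standing variation; restarts are logged.
Samples of n haplotypes are drawn without replacement as the population
carrier fraction crosses each requested threshold, with carrier truth
recorded from the favored site.  At s = 0 the engine is an unbiased
neutral drift (martingale), asserted in the suite.

## PreCIOSS

1-D two-component Gaussian mixture fitted by EM to the in-sample ℓ-HAF
scores; each haplotype goes to its maximum-posterior component and the
higher-mean component is labeled "carrier".  Design choices (the procedure
itself fixes none of these): 5 restarts — the first deterministic, seeding
the components from the median-split halves, the rest from random
responsibilities of the seeded generator — best final log-likelihood wins;
convergence at relative log-likelihood change < 1e−6 or 500 iterations;
variance floor 1e−6 × sample variance against collapse on duplicated
scores; posterior ties (exactly 0.5) go to the carrier component.  When the
two means are closer than 2·max(sd) the fit is flagged low-confidence —
labels are still emitted, but the two-cluster assumption is unsupported
(e.g. neutral samples).  At exactly 4 pooled-SD separation the
Bayes-optimal error is Φ(−2) ≈ 2.3%; the suite asserts near-Bayes recovery
(< 3.5% at 4 SD, < 1% at 5 SD).  sklearn's GaussianMixture serves as an
independent cross-check in tests, never as the implementation.

Evaluation: balanced accuracy ½(TP/(TP+FN) + TN/(FP+TN)), robust to the
severe class imbalance at either end of a sweep (single-class truth returns
the one defined rate, flagged); carrier/non-carrier separation by the
two-sided Wilcoxon rank-sum test (exact enumeration when both groups ≤ 20
and tie-free, tie-corrected normal approximation otherwise); in-sample
percentile ranks with mid-rank ties.

## I/O and polarization

ms/msms-style text is the interchange format (positions as window
fractions, scaled by a window length on read); carrier truth travels in a
JSON sidecar.  VCF ingestion takes phased diploid genotypes (two rows per
sample), polarized so 1 = non-ancestral allele; an explicit outgroup table
takes precedence over the VCF `AA` tag.  Multi-allelic, unphased,
ancestral-unknown and ancestral-mismatch sites are dropped and counted in
the log (total in = kept + dropped).  Coordinates are 1-based inclusive at
the VCF boundary.  Windows default to 50 kb centered on a focal
coordinate, width configurable.

## Problem sizes and determinism

Every stochastic routine takes an integer seed (numpy `SeedSequence`,
spawned per replicate), and identical seeds give bit-identical streams.
The test suite uses: 2000 replicates for constant-size neutral concordance
and 20 000 for the growth and recombination checks; 1500 forward trials
per (θ, n) for the sweep-phase curves (the carrier check is strict 3-SE
banding and is expected to flag the high-ν bins at θ=48, n=200 — see the
finite-s discussion above); 200 trials each for the peak-vs-s and
carrier-recovery checks; 10⁴ trees for the decomposition oracle.  The
acceptance script simulates 20 000 replicates per target.  The synthetic
generators emulate equilibrium panmictic populations with infinite-sites
mutation; they do not model population structure, gene conversion,
genotyping error, unphased or missing calls, or mispolarization, so
passing tests demonstrate correctness of the statistics and algorithms
under the stated models, not robustness of PreCIOSS to those real-data
complications.

## Known limitations

- The variance of the ℓ-HAF score has no closed form here; only means are
  predicted.
- Demography is constant-size or single-epoch exponential growth; arbitrary
  piecewise histories are out of scope (externally simulated data can be
  ingested via the ms reader).
- Sweep-phase theory is the instant-sweep limit (see above); hard/soft
  sweep discrimination is not attempted.
- Soft sweeps are single-origin from standing variation only; recurrent
  mutation and multiple adaptive origins are not modeled.
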