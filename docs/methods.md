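# Methods

This note documents the statistical models implemented in `valleypop`, the
choices made where the methods literature leaves room, and what the
synthetic-data generator does and does not emulate.

## Data model

Genotypes are diploid, unordered pairs of opaque positive integer allele
codes per sample × locus (`GenotypeTable`, an `(n, L, 2)` array).  A call
is either fully typed or fully missing; half-missing calls (one allele
coded missing) are promoted to fully missing at load with a logged count,
because every downstream estimator assumes complete diploid calls.  No
repeat-motif arithmetic is applied to allele codes: all analyses use allele
identity only, so fragment lengths, bin indices or arbitrary labels behave
identically.  Sample order is canonicalised (sorted by ID) when tables are
joined, making permutation tests reproducible regardless of input file
order.

## Diversity and marker screening

* Observed heterozygosity H_O is the fraction of typed genotypes with two
  distinct alleles.
* Expected heterozygosity uses Nei's unbiased estimator
  H_E = (2n/(2n−1))(1 − Σp_i²), with n the number of typed genotypes.
* The Hardy–Weinberg test is the exact conditional test given allele
  counts.  For biallelic loci the heterozygote-count distribution is fully
  enumerated; for more alleles a Monte Carlo version repeatedly re-pairs a
  random shuffle of the observed allele copies (default 10,000 draws,
  seeded, add-one p-value).  The test statistic is the conditional
  probability itself, so the test is two-sided.  Monomorphic loci are
  assigned p = 1 by convention.
* The null-allele estimate is Brookfield's r = (H_E − H_O)/(1 + H_E);
  negative values are reported as-is.
* The locus screen discards a locus only when it BOTH departs from
  Hardy–Weinberg at a Bonferroni-corrected α = 0.05 AND has an estimated
  null-allele frequency above 0.2 — i.e. the deficit looks like a
  genotyping artefact rather than population-level inbreeding, which in
  this study system is real and must not cost loci.  Both thresholds are
  configurable, and α = 0 disables the filter.  This is a generic screen:
  it reproduces the shape of a 27-loci → 24-loci screening workflow without
  claiming to replicate any particular study's unpublished criteria, and
  reports say so.

## Three-level AMOVA and F-statistics

The distance between two allele copies is the number of different alleles
(0 or 1 per locus) — the F_ST-style metric, not the repeat-size R_ST
metric, which is out of scope.  For a set of M copies with allele tallies
m_k, the sum of squares is (M − Σm_k²/M)/2, algebraically identical to the
(1/M)Σ_{i<j}d²_ij pairwise form that the test suite uses as its
independent brute-force oracle.

Per locus, with N typed individuals in P populations (2N copies):

| stratum | df | E[MS] |
|---|---|---|
| among populations | P−1 | σ²_c + 2σ²_b + n_c·σ²_a |
| among individuals within populations | N−P | σ²_c + 2σ²_b |
| within individuals | N | σ²_c |

with n_c = (2N − Σ_p(2n_p)²/2N)/(P−1) the unequal-sample-size coefficient.
Solving the moment equations gives the per-locus components.  Missing
genotypes are handled locus-wise complete-case: an individual missing at a
locus is dropped for that locus only, so each locus has its own df.  The
df reported for the multi-locus table are the complete-data values
(P−1, N−P, N, 2N−1).

Multi-locus F-statistics are ratios of variance components summed over
loci (the Weir–Cockerham "ratio of sums" convention), which is the primary
output; the per-locus ratio mean ("mean of ratios") is also reported
because published tables do not always say which convention they used and
the two differ noticeably when per-locus totals vary.  Negative component
estimates are reported raw and truncated at zero only for the percentage
column; both values are kept.

Permutation schemes follow standard AMOVA practice: F_ST permutes whole
individuals among populations; F_IS permutes allele copies among
individuals within each population; F_IT permutes allele copies among all
individuals.  p = (#{perm ≥ obs} + 1)/(n_perm + 1), never exactly zero.

## Admixture model

The sampler is a Gibbs scheme over the classic admixture model.  Updates
per sweep: allele-copy origins z (categorical ∝ q_ik·p_klj); cluster
frequencies p (Dirichlet conjugate); memberships q (Dirichlet(α + counts));
the symmetric Dirichlet parameter α by Metropolis with uniform prior on
(0, 10], initial 1.0, proposal sd 0.1.  Under the correlated-frequency
model each cluster's frequencies are drawn around shared ancestral
frequencies with concentration p_A(1−F_k)/F_k; the per-cluster drift F_k
has a uniform (0, 1) prior, Metropolis proposal sd 0.05, initial 0.05,
updated every 5th sweep (a blocked-Gibbs schedule: F mixes much faster
than it is consumed, and thinning its update roughly halves the per-sweep
gammaln cost without changing the stationary distribution).

Two deliberate simplifications:

* The ancestral frequency vector p_A is fixed at the empirical overall
  sample frequencies (with a small floor so every observed allele has
  support) instead of being sampled.  With a single data set and moderate
  K, p_A mixes slowly and its posterior concentrates near the pooled
  frequencies anyway; fixing it removes a slow-mixing block at negligible
  cost to the cluster assignments, which are what downstream analyses use.
* The sampling-location prior (the LOCPRIOR extension) is not implemented.
  The config reserves a `locprior` key (rejected if enabled) and pipeline
  reports state the deviation.  For data with divergence strong enough to
  select K = 2 at all, the location prior mainly sharpens memberships; the
  cluster-count decision the package validates does not need it.

Missing genotypes contribute no likelihood term (marginalised by
omission).  The recorded trace is the observed-data log-likelihood
ln P(X|p, q) at each thinned sweep; desk-scale defaults are 20,000 sweeps,
5,000 burn-in, thinning 10, 5 replicates, K = 1–5.  Production-scale
settings (10⁶ sweeps, 10⁵ burn-in, K to 10) are plain config values.

Model evidence per K is estimated as mean(lnL) − var(lnL)/2 (unbiased
sample variance).  ΔK(K) = |L″(K)|/sd(L(K)) uses replicate means for the
first and second differences and the between-replicate standard deviation;
it is undefined at the smallest and largest K tested, and a zero sd is
flagged (NaN) rather than divided by.  Because ΔK cannot point at the
boundary K = 1, one-cluster data are diagnosed by the ln P(X|K) plateau
instead — documented behaviour, shared with the criterion's original form.

Label switching across replicates is resolved by permuting each
replicate's columns to minimise the summed absolute difference to the
first replicate — exhaustive over K! permutations for K ≤ 8, Hungarian
assignment above (both exact for this separable cost).

## P_ST vs F_ST

Trait variance components come from the one-way unequal-n moment method:
σ²_W = MS_within, σ²_B = (MS_between − MS_within)/n₀ with
n₀ = (N − Σn_i²/N)/(k−1).  A moment estimator (rather than REML) keeps the
estimate closed-form, exactly testable and consistent with how P_ST is
usually computed from field data; with two groups and these sample sizes
the two differ negligibly.  No year or sex adjustment is applied by
default; sex pre-centering for size traits is a documented option left off
because the trait model here does not generate sex effects.

P_ST(g, h²) = gσ²_B/(gσ²_B + 2h²σ²_W), evaluated on a default grid
g ∈ {0.1, …, 1.0} × h² ∈ {0.2, 0.4, 0.6, 0.8, 1.0} — a dense decade grid
covering the "low heritability" and "g > 0.4" regions that matter for
sensitivity statements; the published analyses' exact grid is not known,
and the grid is configurable.  The headline classification compares
P_ST(1,1) with the multi-locus AMOVA F_ST; the critical ratio
(g/h²)* = 2F_ST·σ²_W/((1−F_ST)σ²_B) marks where the classification flips,
and the fraction of grid points agreeing with the headline is reported as
a robustness measure.  Bootstrap CIs resample individuals within groups;
a degenerate resample with zero within-variance contributes P_ST = 1.

## Synthetic data generator

Genotypes: Balding–Nichols.  Per locus, an allele count J ~ 2 +
Poisson(mean − 2) clipped to [2, 40] (default mean 14), ancestral
frequencies Dirichlet(1), population frequencies
Dirichlet(p_anc(1−F_ST)/F_ST), so E[divergence] = F_ST with the Beta/
Dirichlet moment identity Var(p_pop) = F_ST·p(1−p) exactly testable.
Inbreeding: with probability f one allele is drawn and duplicated,
otherwise two independent draws — P(hom i) = p_i² + f·p_i(1−p_i), giving
E[F_IS] = f.  Missingness is uniform at a configured rate (default 0.02;
real missingness is locus-dependent but no per-locus rates are published).
Defaults emulate the study conditions: populations of 78 and 93, 24 loci,
F_ST = 0.016, f = 0.19.

Traits: population mean offsets plus Normal(0, σ²_W) noise, with clutch
size rounded to a positive integer.  The offsets are fixed (not redrawn
per replicate) and scaled by √(n₀σ²_B·(k−1)/(n₁n₂N)) so the moment
estimator recovers the configured σ²_B in expectation — the natural model
for a habitat-driven slope effect (a fixed ~0.5-egg clutch difference),
and the only way a k = 2 design can have a stable generating P_ST: with
group effects drawn at random, the χ²₁ spread of the realised
between-group variance would swamp any recovery test.  Target P_ST values
at g = h² = 1 back-solve σ²_B = 2σ²_W·P_ST/(1−P_ST); defaults are clutch
size 0.052 (σ²_W = 1.44 eggs²), body mass 0.013 (0.36 g²), tarsus length
0.005 (0.25 mm²).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage and genealogical correlation between
loci (loci are independent given the F-model), mutation dynamics
(stepwise or otherwise), per-locus missingness patterns, null alleles and
scoring artefacts (injected only in dedicated screening tests), year and
observer effects on traits, G×E, and spatially explicit dispersal.  The
recapture simulator is plain binomial sampling with a fixed cross-slope
probability, not a survival/detection model.

## Numerical and reproducibility choices

* All randomness flows from `numpy.random.default_rng` seeds; identical
  seed + config ⇒ bit-identical MCMC traces and reports.  The pipeline
  derives stage seeds as global seed + fixed per-stage offsets (screen
  +100, AMOVA +200, admixture +300, P_ST +400, simulation +500) so adding
  a stage never perturbs earlier stages' streams.
* Exact-test probabilities are computed in log space (`gammaln`); p-values
  are clipped to 1 against accumulated floating-point excess; comparisons
  against the observed probability use a 1e−9 log-tolerance so ties count
  as at-least-as-extreme.
* Mixture likelihoods clip probabilities at 1e−300 before logs; Dirichlet
  draws with zero shape return exactly zero frequency for unobserved
  allele slots.
* AMOVA with a non-positive total variance raises rather than returning
  ratios of noise; F_IS is NaN when σ²_b + σ²_c ≤ 0 (no within-population
  variation at all).
* Problem sizes in the validation suite (chosen to keep a laptop-scale run
  while leaving Monte-Carlo error well inside the asserted tolerances):
  parameter recovery at 2×75 individuals × 100 loci × 20 seeds per F_ST
  level; permutation type-I calibration at 2×15 × 6 loci × 99 permutations
  × 500 simulations; ΔK model choice at 2×75 × 24 loci × 10 alleles with
  5×(20,000 + 5,000)-sweep chains for K = 1–5.

## Known limitations

* Only 3-level hierarchies (no forests-within-slopes nesting) and no R_ST.
* No LOCPRIOR, no linkage model, no CLUMPAK-style major/minor mode
  clustering of replicates (alignment is to the first replicate).
* P_ST is not Q_ST: without common-garden or pedigree data the g and h²
  scalars are assumptions, which is exactly why the sensitivity grid and
  critical ratio are first-class outputs.
* The locus screen is a generic HWE/null-allele filter, not a
  reconstruction of any study's unpublished screening appendix.
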