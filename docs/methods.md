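# Methods notes

This note records the statistical models implemented in `ucbridge`, the
assumptions behind them, the defaults that matter, and the design
choices made where more than one reading was defensible.

## Population and genotype conventions

The package targets BC1S2 bridging families: an elite *recipient* line R
is crossed to a genetic-resource *donor* line D, the F1 is backcrossed
to R, and each BC1 plant is selfed for two generations by single-seed
descent (exactly one offspring advanced per plant per generation).
Under this pedigree the expected donor-genome fraction is 1/4, the
expected donor-allele dosage at a segregating locus is 1/2, and the
residual heterozygosity at such a locus is (1/2)·(1/4) = 1/8, giving
single-locus genotype frequencies {11/16, 1/8, 3/16} and a dosage
variance of 5/8.

Parental lines are assumed fully inbred and coded 0/2 (copies of the
donor-type allele); progeny carry dosages 0/1/2. Map positions are in
Morgans; tied positions are allowed (markers mapped to the same genetic
location co-segregate).

## Meiosis model

Crossover counts per chromosome are Poisson with mean equal to the
chromosome length in Morgans and crossover positions are uniform — the
Haldane model, no interference. Two implementations are provided and
tested against each other: a literal Poisson-process single-gamete
simulator, and a batch simulator that uses the Markov property of the
crossover process over ordered marker loci (the inherited strand
switches between adjacent markers with probability equal to the Haldane
recombination fraction of the interval). The two produce identically
distributed gametes at the marker loci; the batch route is what the
family simulator uses.

## Family model (REML)

Per family, `y = 1·mu + A + E` with `A ~ N(0, K·sigma2_A)` and
`E ~ N(0, I·sigma2_E)`. `K` is the NOIA additive kinship: dosage
columns centred by the genotype frequencies of the *exact subset being
analysed* (the family for family fits; training ∪ validation individuals
for GBLUP), normalised so `trace(K) = n`. The restricted likelihood is
profiled down to the variance ratio via a single spectral decomposition
of `K` (eigenvalues clipped at zero, which handles singular kinships)
and maximised by a 49-point log-ratio grid bracket followed by bounded
Brent search, tolerance 1e-8 on the log ratio. The `sigma2_A = 0`
boundary is always compared against the interior optimum. Variances
below 1e-10 are reported as exactly zero. A dense, unprofiled evaluator
of the restricted likelihood is exposed separately and used as an
independent check of the optimiser.

GBLUP prediction estimates the variance components on the training block
of `K` and back-solves `A_hat = sigma2_A K[:,TS] V_TS^{-1} (y − mu_hat)`
for all individuals, `mu_hat` by GLS. Within one cross-validation
repetition the validation draw is shared across training-set
compositions so predictive abilities are paired; the 2/3 validation
fraction is sampled uniformly without stratification. Degenerate
repetitions (constant observed or predicted values, or a fully
monomorphic training subset) are recorded as missing and dropped from
averages with a logged count.

The additive-only restriction is deliberate: the same model must serve
single-family and multi-family training sets, and the intended use case
(flint × dent testcross hybrids) is dominated by additive variation.

## Parental fixed-effects model

The benchmark mean predictor is an additive two-way OLS fit
`y = mu + donor_i + recipient_j` under sum-to-zero constraints per
factor. The constraint is a reporting convention only — predicted cross
means are constraint-invariant. A disconnected donor/recipient bipartite
graph leaves parental contrasts aliased; connectivity is checked by
union-find and a violation raises an error naming the aliased groups.

## Bayesian ridge regression

`y = X beta + E` with an unpenalised intercept, a common normal prior on
marker effects and scaled-inverse-chi-square priors on both variances.
The scale convention is `sigma2 ~ Scale-inv-chi2(nu, tau)` with prior
mode `tau/(nu+2)` and full conditional `(tau + SS)/chi2(nu + k)`.
Default hyperparameters follow the convention of standard whole-genome
regression software: `nu = 5` for both variances, the error scale set so
its prior mode equals `Var(y)(1 − R2)` and the effect scale so its mode
equals `Var(y)·R2 / Σ_j Var(x_j)`, with an a-priori marker `R2 = 0.5`.

Sampling is single-site Gibbs over markers with the residual vector
maintained incrementally (numba-compiled; O(nM) per sweep). Chain
defaults: 20 000 iterations, 5 000 burn-in, every 5th post-burn-in draw
retained (3 000 samples). The genotype matrix is used as coded — raw
0/1/2 dosages, no centring or scaling — with centring available as an
explicit flag recorded in the chain metadata. Dosage coding (rather
than collapsing heterozygotes into a 0/2 scheme) is the package's
reading for BC1S2 material, where residual heterozygotes are real;
collapsing them would discard the distinction at one-eighth of
segregating genotypes. Both variance updates can be frozen, which turns
the sampler into a fixed-ridge conjugate draw used by the tests against
the closed-form ridge solution.

## Cross prediction and the usefulness criterion

The progeny mean of an untested cross is the backcross-weighted parental
score `3/4 x_R beta_hat + 1/4 x_D beta_hat`, with the posterior-mean
intercept added once (not per parent). The progeny variance is the
quadratic form of effects in the progeny marker covariance
`Sigma_ij = D^p_ij (1−2c_ij)(3−2c_ij)`, assembled blockwise per
chromosome (cross-chromosome entries are exact zeros because c = 1/2
makes the first factor vanish). VPM evaluates the form at the
posterior-mean effects; PMV averages the form over retained samples, so
`PMV − VPM = trace(Sigma · Cov(beta))` ≥ 0 whenever `Sigma` is positive
semidefinite.

Two properties of the working `c_ij` expression deserve note. First, it
does not vanish at zero distance: `c(0) = 1/8`, so the single-locus
variance contribution is `(1/4)(3/4)(11/4) = 33/64` per unit effect,
whereas direct BC1S2 genotype-frequency algebra gives `Var(dosage) =
5/8 = 40/64`. The expression is implemented exactly as specified for
this population type, and the package carries a brute-force simulation
oracle (`simdata.empirical_progeny_variance`) that quantifies the gap;
the two routes agree to a near-constant factor, so cross *rankings* are
preserved (rank correlation ≥ 0.9 across synthetic crosses in the
acceptance suite), which is what cross selection uses. Second, the UC
is computed on the *variance* scale by default, `UC = mu + i·h·sigma2`,
matching the working equations of the method; the classical
standard-deviation form `mu + i·h·sigma` is exposed as an option and the
scale used is recorded in every prediction. Defaults `i = 2.07` (5%
selected fraction) and `h = 1` (selection directly on genetic effects).

## Training-set compositions

Relative to a target family: `F` (the family itself), `OFO` (all other
families), `R` / `D` (families sharing the recipient / the donor),
`RD` (their union) and `Disc` (families sharing neither parent), each
optionally augmented with the target family's non-validation third. As
individual sets, `RD = R ∪ D`, `Disc` is disjoint from `RD`, and
`OFO = RD ∪ Disc`; these identities are asserted in tests. An empty
resolved composition (e.g. `R` for a recipient used in a single cross)
raises; the pipeline driver skips such compositions with a log entry.

## H criterion

HEBVs are windowed sums of genotype-weighted posterior-mean effects;
windows slide by `step` markers (default 20) with width `window_size`
(default 100) and restart at each chromosome. Trailing windows are
truncated at the chromosome end and kept, so no marker is uninspected;
duplicate windows (possible when a chromosome holds fewer markers than
one step) are dropped. `lambda = step/window_size = 0.2` compensates
the overlap. Forward selection greedily adds the candidate maximising
`H`, ties broken lexicographically by donor id for determinism; percent
gains are relative to the recipient + initial-donors baseline. `H` is
non-decreasing along a trajectory and invariant to candidates dominated
window-wise — both asserted on random instances.

## Synthetic-data generator

The generator emulates the statistical shape of a cooperative maize
introgression experiment: 7 elite recipients, 9 donors, 20 connected
families of 38–66 BC1S2 individuals (round-robin incomplete design,
2–3 crosses per recipient, unique pairs), a 10 × 1.6 Morgan genome with
uniformly placed markers, and additive phenotypes emitted directly at
the adjusted-hybrid-mean level, one record per individual.

Parental alleles are drawn from pool-specific Beta-distributed per-marker
frequencies (recipients centred at 0.15 donor-type allele frequency,
donors at 0.5, concentration 8), which makes elite lines more similar to
one another than to donors while keeping most pairs polymorphic. Traits
are polygenic Gaussian (default effect SD 0.1 per dosage unit,
individual-level h² = 0.5, error variance resolved against the realised
genetic variance).

By default one quarter of the simulated loci act as causal QTL and are
*removed from the genotype tables the analysis sees*. This mirrors a
real SNP array, which tags causal variation through co-segregation
rather than containing it, and it is what gives relatedness its role:
marker–QTL phase is family-specific, so prediction transfers between
families through shared parental haplotypes, not through directly
estimated causal effects. With every causal locus genotyped
(`hidden_qtl_fraction = 0`), marker effects transfer to any family and
disconnected training sets predict nearly as well as related ones — a
regime real data do not show. Features deliberately not emulated:
trial/tester structure, spatial field effects, G×E, dominance,
selection during family development, and population-level LD between
adjacent markers in the parental pools. Passing tests therefore
demonstrate the estimators' correctness and the relatedness-driven
ordering mechanism, not field-scale effect sizes.

## Problem sizes in the test and pipeline defaults

The pipeline driver defaults to a 5 × 60-marker genome and 20 CV
repetitions; the acceptance suite uses 200 REML replicates of n = 300,
a 400 × 100 Bayesian-ridge recovery, 20 crosses × 10⁴ simulated progeny
for the variance-ranking check, 10⁵-individual Monte-Carlo transmission
checks, and 10 replicate designs (20 families of 30–40, 4 × 40 markers,
6 target families, 20 CV repetitions) for the training-set ordering —
sizes chosen to make the full suite a desk-scale run while keeping each
assertion's Monte-Carlo error well below its tolerance.

## Known limitations

* The analytic progeny variance inherits the constant-factor offset of
  the working `c_ij` expression discussed above; absolute variance
  levels should be read with that in mind, rankings are unaffected.
* REML standard errors are not computed; the parameter-recovery tests
  use empirical (replicate-based) spread instead.
* The Gibbs sampler reports no convergence diagnostics beyond
  reproducibility and the recovery checks; chains at the default length
  were amply sufficient on all tested problems.
* `Sigma` is exact only for the BC1S2 generation; other generations
  (DH, RIL, advanced selfing) would need their own recombination
  expectations and are out of scope.
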