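# Methods

`gefam` compares three ways of testing gene-environment (GE) interaction on
a quantitative trait measured repeatedly in twin families: a classical ACE
twin path model applied to time-averaged outcomes, a linear mixed model
(LMM) with a kinship-structured random intercept applied to all repeated
measures, and the nonparametric partition-based score I (PBI) test with a
family-constrained permutation p-value. A trajectory simulator generates
the longitudinal twin cohorts on which type-I error and power are
estimated. This note records the models, the generating process, the
numerical choices, and the places where the design was genuinely open.

## The data-generating model

Cohorts mimic a birth cohort of twin pairs followed from birth to about
five years. The default skeleton is 168 MZ + 226 DZ pairs (788
individuals), six visits per individual with age 0 (birth) at the first
visit and subsequent visit ages drawn per family from normal distributions
with means (6.28, 19.49, 31.77, 49.85, 62.25) months and SDs (0.74, 0.75,
0.96, 1.82, 3.23), truncated to be strictly increasing; co-twins share the
family schedule. Sex-pair composition is FF 0.42 / MM 0.35 / FM 0.23, with
opposite-sex pairs restricted to DZ. The skeleton is generated rather than
taken from a real cohort, which preserves the statistical structure the
methods see (family clustering, zygosity mix, visit spacing) but not any
real-data irregularities such as informative missingness; an optional
per-visit missing-completely-at-random dropout probability (default 0) is
the only missingness mechanism.

One biallelic locus is simulated per cohort under random mating: each
parent's genotype is the sum of two Bernoulli(MAF) alleles (MAF 0.3 by
default) and each child receives one allele from each parent with
Mendelian segregation probabilities; MZ co-twins share a single
transmission, DZ co-twins get independent ones. The binary exposure is
i.i.d. Bernoulli(0.3) per individual, independent even within pairs.

BMI at visit k for individual j of pair i is

    Y_ijk = (b0 + C0_ij) + bS*S_ij + (bT + CT_ij)*T_ijk + bT'*T'_ijk
            + bG*G_ij + bGT*G_ij*T_ijk + bE*E_ij + theta_ijk + eps_ijk

with T' = 0 at the first two visits and T - 6 afterwards (fast infant
growth then plateau), eps ~ N(0, sigma2_E), and pairwise bivariate-normal
random intercepts/slopes whose covariance encodes the ACE structure:
variance sigma2_A + sigma2_C, covariance sigma2_A + sigma2_C for MZ and
sigma2_A/2 + sigma2_C for DZ (tau2 analogously for slopes). Intercept and
slope vectors are independent of each other. Defaults: b0 = 11 kg/m^2,
bS = 0.5, bT = 0.8 and bT' = -0.8 per month, sigma2_A = 3, sigma2_C = 1.5,
tau2_A = tau2_C = 0.001, sigma2_E = 1.5.

The interaction term theta is bGE * M[G, E] when the effect acts on the
outcome average, and bGTE * M[G, E] * T when it acts on the rate of change
(the minimal reading of an effect "on the rate of change": the matrix
entry scales a slope). M is a 3x2 multiplier matrix with named presets
(below). Scenario presets tie nuisance effect sizes together the way the
study design does: in the "no effect on average" nulls beta_E = 2*beta_G,
and in the "no effect on change" nulls beta_E = 40*beta_GT.

## Interaction patterns

- `linear`: M[g, e] = g * e, the multiplicative pattern every regression
  product term assumes.
- `conditional_dominant`: additive genetic effect unexposed (0, 1, 2),
  dominant/plateaued exposed (0, 2, 2).
- `small_marginal`: recessive effect expressed only under exposure
  (only M[2, 1] = 1).
- `xor`: heterozygote advantage when unexposed (0, 1.5, 0), recessive
  effect when exposed (0, 0, 2).

The XOR preset deserves its own paragraph because the choice was genuinely
open. An "XOR-like" pattern should be one a multiplicative product term
cannot represent. Any 3x2 matrix decomposes over the model span
{1, g, e, g*e} plus a residual; the product-term coefficient that a
regression estimates converges to the weighted-least-squares slope of the
exposure contrast delta(g) = M[g,1] - M[g,0] on g under the genotype
distribution. A matrix with straight-line columns of opposite slope (for
instance columns (0,1,2) and (2,1,0)) has delta linear in g, is therefore
*exactly* a linear interaction in disguise, and regression tests detect it
with maximal power — the opposite of XOR behavior. The shipped preset
instead makes delta(g) = (0, -1.5, +2) orthogonal to g under
Hardy-Weinberg weights at MAF 0.3 (0.49, 0.42, 0.09): the additive product
term carries asymptotically zero signal, while the genetic effect pattern
still flips entirely with exposure (which genotype group is affected
changes), the plasticity-gene reading of XOR. All matrices are
user-overridable in `ScenarioConfig`.

## The three tests

**Twin model.** Outcomes are first averaged per individual over available
visits (individuals with fewer than 2 of 6 usable visits are dropped).
The model is Y_ij = x_ij' beta + a A_ij + c C_ij + e E_ij with A, C, E
standard-normal latents; complete pairs contribute a bivariate normal
density with common variance a^2 + c^2 + e^2 and covariance a^2 + c^2 (MZ)
or a^2/2 + c^2 (DZ); incomplete pairs are kept as univariate margins
rather than dropped. Fixed effects: intercept, sex, mean age, genotype
(additive count or co-dominant indicators), exposure, and the
genotype-exposure product. Fitting is ML: fixed effects are profiled out
by GLS at each variance evaluation (reduced to O(p^2) sufficient
statistics per zygosity group), and the three variance components are
optimized by bounded L-BFGS-B from three starts (equal split of the
empirical variance, e-dominant, a-dominant), which reaches the a^2 -> 0 /
c^2 -> 0 boundaries smoothly. Note the latent E here is the unique-
environment deviate of the variance decomposition, a different object from
the observed exposure covariate in x.

The intercept of this model is *not* the generating b0: because the
averaged outcome is adjusted for mean age, the fitted intercept is an
extrapolation to mean age zero along a nearly unidentified slope (all
individuals share almost the same mean age), with per-fit standard errors
around 5. Parameter-recovery checks for b0 therefore use the LMM; the twin
model's recovery is checked on the sex effect.

**Kinship LMM.** All repeated measures enter. Each individual has one
random intercept; across individuals the intercepts have covariance
sigma2_g times the relationship matrix (2 x kinship: diagonal 1, MZ
co-twin 1, DZ co-twin 0.5), which simultaneously induces the longitudinal
correlation within an individual and the familial correlation within a
pair. Var(Y) = sigma2_g Z K Z' + sigma2_res I. Fixed effects: intercept,
sex, age, a segmented age trend, genotype, exposure, and the tested
interaction; for the rate-of-change target (G:E:T) all lower-order
products (G:T, E:T, G:E) are included (hierarchy principle). The default
segmented basis is the hinge max(0, T - 6 months), matching how such
trends are specified on real data; a `visit_rule` basis reproducing the
generator's segmentation exactly (zero at the first two visits) is
available and is what the parameter-recovery checks use, since only under
it are the generating coefficients exactly identified. Fitting is ML (so
fixed-effect LRTs are valid; a REML toggle exists for variance reporting),
with beta profiled by GLS and the two variance components optimized on the
log scale. Family blocks are grouped by covariance pattern and rotated
once into the eigenbasis of the random-effect structure, after which every
likelihood evaluation is O(#eigenvalues x p^2) regardless of cohort size;
MZ blocks being rank-1 is harmless because the marginal covariance adds
sigma2_res I and stays positive definite.

**Wald / LRT convention (both models).** Single-column effects use a Wald
z against the standard normal (large-sample ML convention, matching the R
mixed-model packages practitioners use here); effects spanning several
columns (co-dominant interactions, 2 df) use a likelihood-ratio test
against a refitted null. Non-convergence yields a flagged fit and a
missing p-value, never a silent number.

**PBI test.** For a partition of the sample into cells i = 1..k the
dispersion statistic is I = sum_i (n_i/n) (ybar_i - ybar)^2 / (s2_y /
n_i); the interaction statistic is I_T = I_GE - max(I_G, I_E), computed on
per-individual mean outcomes with the genotype (3 levels) crossed with the
exposure (2 levels, or quartile categories for continuous exposures). s2_y
uses the n-1 divisor — the choice is recorded in the result metadata and
cancels from the permutation p-value. Empty cells are skipped; constant
outcomes define I = 0 with a warning; I_T may be negative (crossing a
partition can dilute cells) and is reported untruncated. Significance:
outcomes are permuted within each family (a fair-coin swap for twin
pairs), each individual keeps their (G, E) pair, and the one-sided
upper-tail p is (1 + exceedances) / (B + 1) with B = 10,000 by default.
Permuting outcomes versus permuting (G, E) pairs is equivalent for
two-member families, which is the only family size supported.

## Simulation studies and their scale

Power and type-I error are estimated as the proportion of interaction
p-values below alpha = 0.05 over seeded replicates; replicate r uses seed
base_seed + r, so tables are reproducible independent of scheduling or
worker count, and Monte-Carlo standard errors sqrt(p(1-p)/R) are reported.
The package's own studies use R = 1000 replicates for the regression-model
type-I error runs, R = 500 for PBI nulls and power orderings, and R = 300
for the PBI inflation plateau, with 1000 permutations per PBI call; these
sizes give Monte-Carlo standard errors of 0.007-0.03 on a proportion,
small against the effects being compared, while keeping a full study run
in minutes on one core.

Two documented behaviors of the PBI test are reproduced rather than
"fixed": it is exact (level <= alpha) only under the pure-noise null,
because within-family permutation destroys the outcome's association with
the *individual-level* main effects as well as with the interaction; and
under a strong gene-time trend plus environment main effect (null
rate-of-change scenarios) its false-positive rate inflates far above
nominal and plateaus, because the crossed partition then explains the two
main effects jointly better than either margin alone, pushing the observed
I_T up while the permutation null stays centered. On the synthetic
skeleton the plateau sits near 0.4 (about 0.39 +/- 0.02 at beta_GT = 0.02,
beta_E = 0.8); with a real cohort skeleton (different age dispersion and
missingness) the level of this plateau shifts, and values around one half
are in the same regime.

What passing these simulations does *not* show about real data: the
generator has complete six-visit follow-up, a single locus, exactly
Hardy-Weinberg genotypes, an exposure independent of everything, and
exactly normal random effects, so the studies quantify the methods'
behavior under the stated model, not robustness to missingness,
confounding, scale transforms or model misspecification beyond the
interaction shape.

## Data preparation operators

- `mean_over_time`: unweighted mean of available visits; default minimum
  2 usable visits of 6.
- `quartile_categorize`: 4 levels by sample quartiles; boundary ties go to
  the lower category (an arbitrary but fixed convention for determinism).
- `followup_proportion`: carry-forward exposure summaries — a status
  holds until the next visit; intervals with unknown length or unknown
  starting status drop out of numerator and denominator.
- `variant_qc`: drops variants with MAF < 0.05, missingness > 10% or
  Hardy-Weinberg chi-square p < 0.01. The HWE test runs on one individual
  per family (lowest id) because duplicated MZ genotypes and sib sharing
  inflate the chi-square on related samples; this thinning is a design
  choice, not an estimate of what any particular study did.
- `bonferroni_threshold`: alpha / n_tests, applied within one exposure
  (default 9 variant tests per exposure) in the scan.

## Known limitations

Only twin pairs (no larger sibships or general pedigrees; the LMM accepts
any PSD relationship matrix but construction supports twins only). One
locus per cohort, no LD or haplotypes. Time-constant exposures. No AE/CE
submodel selection, no sex-limitation models, no bootstrap CIs for
variance components, no covariate adjustment inside the PBI test (it is
applied unadjusted, as the comparison intends).
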