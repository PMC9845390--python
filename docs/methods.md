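# Methods

## Overview

The package asks a single question under controlled conditions: when a
dietary item is derived from repeated 24-hour-recall questionnaires either
crudely (per-person proportion or average) or by Empirical Bayes shrinkage,
which derivation carries more SNP heritability, and how does the answer
depend on the item's test–retest reliability? Because the motivating
cohort's individual-level data are restricted, every input is synthetic, and
the generator is therefore a first-class, tested model whose ground truth
(latent heritability, per-item ICC) the downstream estimators must recover.

## Synthetic cohort

**Genotypes.** Two latent haplotypes per individual follow a first-order
autoregressive Gaussian process along a single synthetic chromosome
(1-based positions, fixed 1 kb spacing); each site is thresholded at the
normal quantile of its allele frequency (drawn uniformly on the configured
MAF range, default 0.05–0.5) and the haplotypes are summed to a {0,1,2}
dosage. A single AR coefficient yields nearly constant LD scores, which
leaves LD-score regression with almost no leverage, so the default study
condition draws one coefficient per 25-SNP block uniformly from
`rho_range = (0.1, 0.95)`; this mimics the block structure of real LD and is
what makes summary-statistic heritability estimable at a few thousand SNPs.
The single-coefficient path remains available (`rho_range=None`).

**Latent traits.** Each item has its own unit-variance liability: effects
drawn i.i.d. normal on a causal subset of standardized dosages, rescaled so
the genetic share equals the target h² exactly, plus independent Gaussian
noise. The default architecture is polygenic (causal fraction 1/2):
consumption behaviours are expected to be highly polygenic, and sparse
architectures make the placement of causal SNPs the dominant source of
replicate noise in LD-score regression.

**Questionnaires.** Each individual completes k ∈ 1..5 questionnaires with
probabilities proportional to the cohort's observed completion counts
(81,081 / 46,893 / 31,818 / 15,000 / 2,066 — i.e. 54% of 176,858 complete at
least two). Day-level responses follow a two-part model driven by a person
effect e (by default the item's liability): consumption is Bernoulli with
logit μ + s·e, and, for quantity items, the portion count given consumption
is a Poisson with log-rate log(q̄) + s·e/2 truncated to the integer grid
1..10 (cups/servings), zero otherwise. The scale s is calibrated by 1-D root
search so the *expected* one-way ICC of the raw item equals its target
within 0.01; the expectation integrals use piecewise Gauss–Legendre
quadrature over the person effect with segment boundaries at the sigmoid and
truncated-Poisson transition points, because a fixed Gauss–Hermite rule
saturates once the person-effect link approaches a step (targets ≥ ~0.85).
ICC = 1 items are generated as deterministic functions of the person.
Records also carry total energy (kJ), typical-diet/completion flags,
duration, completion hour, weekend flag and pregnancy/cancer recency; a
configurable fraction (default 2% per rule) is made to violate each
credibility filter.

**What the generator does not emulate.** Population structure, relatedness,
realistic allele-frequency spectra, seasonal or weekday consumption effects,
item–item correlation beyond what the shared liability induces,
energy–item coupling, and item-level missingness within completed
questionnaires. Passing tests therefore demonstrate internal consistency of
the statistical machinery under a well-specified model, not robustness to
the confounding present in real cohort data.

## Quality control and derivation

A record is retained iff energy ∈ [1,000 kJ, 20 MJ (male) / 18 MJ (female)],
the typical-diet and completion flags pass, duration ≥ 5 min, and no
pregnancy or cancer within the year. All bounds are inclusive. Exclusions
are attributed to the first failing rule in the order energy-low,
energy-high, typical-diet, duration, completion, pregnancy, cancer; the
retained set is order-independent (rules are evaluated jointly), so the
order affects only the report. Within a completed questionnaire a missing
item response codes as "not consumed", never missing.

Crude and EB phenotypes follow the formulas in the README. Numerical
choices:

- **Zero-one-inflated beta.** p₀/p₁ are the empirical masses at exactly 0
  and 1; (α, β) maximise the interior beta likelihood via L-BFGS-B on
  (log α, log β) with analytic gradients, method-of-moments start, gradient
  tolerance 10⁻⁸ per observation. Items with fewer than 50 interior values
  (configurable) are flagged non-converged; a configured donor item's
  (α, β) — or, by default, the converged item with the most similar overall
  mean — is substituted. Non-convergence with no donor available is a hard
  error, never a silent crude fallback. Only (α, β) enter the EB update; the
  inflation masses are reported but deliberately excluded, exactly as the
  posterior-mean formula implies.
- **Dirichlet-multinomial.** Fitted per item (not pooled across items) on
  the matrix of response-category counts, categories being the distinct
  quantities rounded to a configurable precision (default integers, zero
  included). Maximum likelihood by the standard digamma fixed point from a
  moment-matched start, stopping when the log-likelihood moves < 10⁻⁸.
  Because counts never exceed five, all digamma/gammaln sums run over value
  histograms, so iterations cost O(k_max · categories) and the generous
  iteration cap (2·10⁵) is affordable; the fixed point converges slowly for
  strongly zero-dominated items.

## Reliability

One-way random-effects ICC (single-rater consistency form): from subjects
with a complete, equal set of ratings, σ²_between = max(0, (MSB − MSW)/r),
σ²_within = MSW, ICC = σ²_b/(σ²_b + σ²_w), clamped to [0, 1]. The reference
analysis uses subjects completing all five questionnaires; at smaller scales
the table falls back to the first r retained questionnaires of subjects with
k ≥ r, choosing the largest feasible r. ICC is always computed on raw
per-questionnaire item values, never on derived phenotypes.

## Association and heritability

Each phenotype is residualised on an intercept plus covariates (sex, age in
months, age², assessment centre one-hot dropping a reference level, weekend
proportion, mean duration winsorized at 25 min, number of questionnaires,
two genotype principal components); dosages are residualised on the same
design, so per-SNP OLS slopes and chi-squares equal the joint multiple
regression by Frisch–Waugh–Lovell, with the matching degrees of freedom.
SNPs are pre-filtered on MAF > 0.5%, MAC > 10, missingness < 10%. This
per-SNP least-squares scan deliberately replaces the original whole-genome
ridge (mixed-model) step — the major fidelity gap of the desk-scale
re-implementation; no relatedness is simulated, so nothing is lost here,
but the substitution must be remembered when comparing against cohorts with
cryptic relatedness.

**LD scores** are computed in-sample (the synthetic data has no external
reference panel) on true sample correlations within a ±500 kb window, with
the small-sample adjustment r²−(1−r²)/(N−2) so null pairs contribute zero on
average; scores are floored at 0.05.

**LD-score regression** fits χ²_j on ℓ_j by a single weighted pass
(weights 1/max(ℓ_j, 1)) with a free intercept; h² = slope·M/N. The slope's
standard error comes from a delete-one-block jackknife over 50 contiguous
SNP blocks: chi-squares of SNPs in LD are strongly correlated, and a
pointwise heteroskedasticity sandwich understates the uncertainty by a
factor of ~3 at these scales. The free intercept absorbs the constant
inflation that in-sample LD estimation adds to every chi-square.

**Haseman–Elston regression** regresses y_i·y_j (standardized) on GRM_ij
over pairs i < j, with a closed-form delete-one-individual jackknife for the
standard error. At N in the low thousands it is the more precise estimator
by a wide margin — LDSC precision is limited by the number of independent
LD blocks rather than by N — so the pipeline uses the HE Wald test
(one-sided, h² > 0) for the significance-retention filter while keeping the
LDSC point estimates for the crude-vs-EB comparison itself, mirroring the
original design where LDSC supplies the compared heritabilities.

## Benchmark

The effective number of independent phenotypes uses the (Σ√λ)²/Σλ
eigenvalue formula on the correlation matrix of covariate-adjusted
phenotypes (the alternative counting rule Σ[I(λ≥1) + frac(λ)] is available
behind `method="li_ji"`); the significance threshold is 0.05/M_eff. A
(crude, EB) pair is retained iff at least one version clears the threshold.
Winners are decided on the heritability point estimates with an equality
band of 10⁻⁶; ICC quartiles are computed empirically within phenotype class
(proportion vs. average), since the two classes have different reliability
distributions. Clumping is greedy: repeatedly take the most significant
unabsorbed SNP below 5×10⁻⁸ and absorb everything within a ±500 kb radius
(the radius interpretation is a flag), ties broken by (p, chr, bp, id).
Locus concordance collapses the crude and EB loci of each phenotype into
shared windows and asks whether the window's smallest lead p belongs to the
version with higher h²; the percent difference used for the top-25%/top-10%
strata is |h²_crude − h²_EB| over the symmetric mean of the two.

## Study conditions and problem sizes

The reliability benchmark runs 20 low-ICC (0.10–0.20) and 20 high-ICC
(0.70–0.90) binary consumption items on one latent h² of 0.85, N = 4,000
individuals and M = 8,000 SNPs. These sizes come from a power analysis of
the retention filter: with the cohort-shaped completion distribution the
observed heritability of a low-ICC crude proportion is ~0.1–0.15, and the
HE Wald statistic needs N ≈ 4,000 to clear a 0.05/M_eff ≈ 10⁻³ threshold
reliably, while LDSC needs M in the thousands for usable point estimates.
Estimator-recovery experiments use N = M = 2,000 with h² = 0.25 (50 LDSC /
20 HE replicates), matching the cross-validation targets asserted in the
test suite. The toy pipeline default (N = 500, M = 500, 4 items) exists for
smoke tests and completes in under a second.

## Known limitations

- LD-score regression at desk scale is noisy (per-phenotype se ~0.1); only
  paired comparisons and replicate means are meaningful, and the exact
  per-replicate estimate carries a small (~5%) downward structural bias from
  normalising the realized genetic variance within each replicate.
- In-sample LD scores and the free intercept absorb, rather than remove,
  the resulting calibration shifts.
- The benchmark's qualitative conclusions (where EB shrinkage helps) are
  statements about this generative model; episodic foods, covariate-driven
  consumption and measurement-error-correction methods beyond simple EB
  shrinkage are out of scope.
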