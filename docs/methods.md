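# Methods

This note records the models, parameter choices and numerical details
behind `grskit`, and what its validation does and does not establish.

## Score construction

The score is a plain weighted allele count: dosage of the risk allele
times the natural log of the per-allele discovery odds ratio, summed
over loci. Natural logs (not log10) make the score a log-odds quantity,
so a logistic coefficient on the standardized score is directly a
log-OR per SD. Weights are not divided by the number of alleles; the
SNP set is fixed by the weight table (no p-value thresholding or
clumping).

Standardization uses the pooled case+control mean and the n−1 sample
SD. Pooled (rather than control-only) standardization is the
conventional choice in GRS software and makes the per-SD unit refer to
the analysis sample itself.

Missing dosages are handled at scoring time, after harmonization, by
one of three policies: per-SNP mean imputation over the pooled sample
(default, mirroring standard score-profile behavior), complete-case
deletion, or zero-fill. With complete data all policies coincide
(tested). A SNP missing in every sample is an error under mean
imputation rather than a silent drop.

## Allele harmonization

Genotype columns are re-oriented so each counts the weight table's risk
allele: identity is kept, the opposite-allele presentation is flipped
(d → 2−d), and strand-complement presentations are complemented first.
Matching is by rs identifier, not genomic position, because weight
tables often carry positions on unspecified genome builds. Palindromic
(A/T, C/G) SNPs cannot be strand-resolved from alleles alone without
frequency information, which the package deliberately does not use;
the default excludes them with a warning (overridable to keep or
error). An enumeration test verifies that every resolvable
presentation of a non-palindromic SNP yields the same oriented dosages.

## Association model

Unmatched (unconditional) logistic regression, fit by Newton maximum
likelihood (statsmodels) to tolerance 1e-8 within 100 iterations, with
standard errors from the inverse observed information. Age enters as a
three-level category (7–9, 10–14, 15–19 years) matching how such
cohorts report it; sex and country are likewise dummy-coded with fixed
reference levels (male; 7–9; Sweden). Reference choice does not affect
the score coefficient. Confidence intervals and p-values are Wald
(symmetric on the log scale, deterministic); a likelihood-ratio p for
the score is reported alongside since some studies print that instead.

Perfect separation is detected both from the fitter's diagnostics and
from a coefficient-magnitude guard (|β| > 30), and surfaces as a typed
error naming the problem rather than a silently divergent estimate.

Variance explained: Cox–Snell R² = 1 − exp(2(ll₀−ll₁)/n), Nagelkerke
R² rescales by the maximum 1 − exp(2 ll₀/n). The score's contribution
is Nagelkerke(full) − Nagelkerke(reduced), both rescaled against the
intercept-only null.

## Liability-scale heritability

The observed-scale quantity fed into the liability transform is the
Cox–Snell R². When the input is a Nagelkerke value (as association
reports usually print), the Nagelkerke rescaling is first undone by
multiplying with 1 − exp(2(P ln P + (1−P) ln(1−P))); this is the only
reading under which the reference chain 0.012 → 0.003 (K = 0.04%,
P = 245/734) is numerically consistent — transforming the Nagelkerke
value directly gives ≈0.004. The transform itself is the standard
ascertainment-corrected form R²·K²(1−K)²/(z²P(1−P)). Normal quantile
and density come from scipy at double precision (`isf` for the exact
upper tail; validated to 1e-10 against independent evaluation for K
from 1e-5 to 0.5). The transform is exactly linear in R², so the
ΔR² (not the full-model R²) is the quantity to feed it.

A simulation consistency test generates a liability-threshold trait
with known liability-scale variance explained (v = 0.05, K = 0.01,
400k population), ascertains cases and controls, and recovers v through
the observed-scale R² and the transform within Monte-Carlo tolerance.

## Power

The analytic minimum detectable OR uses the allele-based (2N alleles
per group) Wald test with the *null* standard error
sqrt((1/2N_ca + 1/2N_co)/(f(1−f))). Defaults are two-sided
α = 0.05/92 — Bonferroni across a 92-SNP genotyping panel — and power
0.80, both overridable; f refers to the control/population risk-allele
frequency. At these defaults and mid-range f, a 245/489 design detects
per-allele ORs of about 1.6.

The null-variance closed form is an approximation: under the
alternative the case-group frequency shifts toward 0.5 for f < 0.5,
shrinking the realized SE, so empirical power at the analytic minimum
OR exceeds the nominal target away from f = 0.5 (by ~0.1 at f = 0.2
with the Bonferroni α). The simulation oracle (binomial allele-count
tables, Wald test, +0.5 continuity correction on tables with empty
cells) quantifies this; tests document close agreement near f = 0.5
and the conservative (power-overshooting) direction of the error at
off-center frequencies. The simpler closed form is kept because its
inputs match what published power statements can be checked against.

## Synthetic cohorts

The generator emulates a childhood brain-tumor case-control study: 245
cases, 489 controls, five autosomal biallelic loci, population
prevalence 0.04%, covariate margins (sex, three age bands, four
countries) drawn status-specifically from the emulated cohort's
composition. Risk-allele frequencies default to (0.49, 0.42, 0.31,
0.76, 0.77) — mid-range values chosen once for realism; the emulated
study publishes none, and none of the analyses is sensitive to the
choice because the score is standardized.

Genotypes are unlinked and in Hardy–Weinberg equilibrium. The effect
is placed on the population-standardized score (default β = ln 1.25
per population SD), with a per-SNP mode (β_j equal to each table
log-OR) available for more granular realism. Because prevalence is
~4e-4, prospective simulation would discard thousands of individuals
per case; instead the 3^m genotype states are enumerated exactly:
population probabilities from HWE, penetrances expit(μ + β·z), the
intercept μ solved by Brent's method to ~1e-12 on prevalence, and
cases/controls drawn from the exact conditional distributions
(retrospective sampling). Closed-form binomial moments of the raw
score (mean Σ2f_j w_j, variance Σ2f_j(1−f_j)w_j²) are used for the
standardization and are verified against the enumeration to 1e-12.

What the generator does **not** emulate: linkage disequilibrium
(including between the two RTEL1 loci), genotyping error and
missingness, population stratification, and covariate–genotype
dependence. Passing recovery tests therefore validate the estimation
machinery under the stated model, not robustness to those real-data
features.

### Expected variance explained under the generator

Simulate-and-refit at the default design recovers the generating
per-SD OR essentially unbiasedly (mean ≈ 1.25–1.27 over 200
replicates). The mean Nagelkerke ΔR², however, sits near 0.017, not at
the single-study reference value 0.012: the difference statistic is
(asymptotically) a noncentral 1-df chi-square scaled by 1/(n·R²_max),
so its *expectation* carries a +1 noise degree of freedom on top of
the noncentrality (≈(1+8.2)/(734·0.720)), and the generator's
complete-data SE (≈0.078) is smaller than a real cohort's. This is a
property of the estimand, not an estimation bias; the examples and
validation report it as computed.

## Problem sizes

The validation suites use 200 replicates for recovery studies, 2000
replicates for empirical power, and a 400k-individual population for
the liability consistency check — sizes at which Monte-Carlo error is
well below the tolerances being asserted while the full suite runs in
well under a minute.
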