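# grskit

Weighted genetic risk scores (GRS) for case-control studies: score
construction from published SNP weights, logistic association with
covariate adjustment, liability-scale SNP heritability under
case-control ascertainment, minimum-detectable-odds-ratio power
analysis, and an exact synthetic cohort generator for validation.

`grskit` is aimed at epidemiologists and statistical geneticists who
want to test whether susceptibility loci discovered in one population
(e.g. an adult-glioma GWAS) carry over to another (e.g. childhood brain
tumors), using a small fixed SNP panel and an unmatched case-control
sample.

## The method

For sample *i* with harmonized risk-allele dosages `d_ij ∈ {0,1,2}` and
per-allele discovery odds ratios `OR_j`, the score is the weighted sum

    GRS_i = Σ_j d_ij · ln(OR_j)

standardized by the pooled sample mean and SD. Association is the
unconditional logistic regression

    logit P(case) = β₀ + β·z(GRS) + sex + age group + country

and the per-SD odds ratio is `exp(β)` with a 95% Wald interval. The
score's variance explained is the Nagelkerke pseudo-R² difference
between the full and the covariate-only model, where

    R²_CS = 1 − exp(2(ll₀ − ll₁)/n),   R²_N = R²_CS / (1 − exp(2 ll₀/n)).

Under the liability-threshold model with population prevalence *K*
(threshold `t = Φ⁻¹(1−K)`, density `z = φ(t)`) and sample case fraction
*P*, the observed-scale (Cox–Snell) R² maps to liability-scale
heritability with ascertainment correction:

    h²_liab = R²_obs · K²(1−K)² / (z² · P(1−P)).

The power module gives the smallest detectable per-allele OR from the
allele-count Wald test, `exp((z_{1−α/2} + z_{power})·se₀)` with
`se₀ = sqrt((1/2N_ca + 1/2N_co)/(f(1−f)))`, backed by a simulation
oracle.

The synthetic cohort generator enumerates the full genotype state space
under Hardy–Weinberg equilibrium, solves the logistic penetrance
intercept to hit a target prevalence exactly, and samples cases and
controls retrospectively from the exact conditional distributions — so
pipeline tests have a known ground truth without any data download.

## Worked example

```python
import grskit as gk

# five bundled adult-glioma loci (TERT, CDKN2A/B, PHLDB1, 2x RTEL1)
spec = gk.SimulationSpec(seed=7)           # 245 cases / 489 controls
cohort, truth = gk.sample_cohort(spec)     # true OR per SD = 1.25
scores = gk.score_cohort(cohort)
result = gk.associate(scores, cohort.phenotypes)
print(result.or_per_sd, result.p_value, result.delta_r2_nagelkerke)

h2 = gk.full_chain(0.012, prevalence_K=0.0004, case_fraction_P=245/734)
print(h2.h2_liability)
```

prints (see `examples/01_score_and_associate.py` and
`examples/02_liability_heritability.py` for the narrated versions):

```
OR per SD      : 1.230 [95% CI 1.050-1.442]
Wald p         : 0.0104
Nagelkerke dR2 : 0.0125
h2 (liability scale)  : 0.00298  -> rounds to 0.003
```

The estimated 1.23 per-SD odds ratio recovers the generating 1.25
within sampling error; the liability chain turns a 1.2% Nagelkerke R²
into ≈0.3% of liability variance once the 34%-case sample is
re-referenced to a 0.04%-prevalence population.

The same analyses are available from a shell:

```sh
grskit simulate --out-dir cohort --seed 7
grskit run --genotypes cohort/genotypes.vcf --phenotypes cohort/phenotypes.tsv \
           --weights cohort/weights.tsv --out-dir results
grskit h2 --r2 0.012 -k 0.0004 -p 0.3338
grskit power --n-cases 245 --n-controls 489 --raf 0.5
```

## Layout

- `src/grskit/` — the library (weights, genotypes, scoring,
  association, liability, power, simulate, pipeline, cli)
- `examples/` — short narrative scripts, one per capability
- `tests/` — unit, property and end-to-end validation suites
- `docs/methods.md` — modeling assumptions, parameter choices and
  numerical details
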