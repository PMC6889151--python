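"""Synthetic case-control cohorts with an exact genotype-distribution oracle.

The generator reproduces the statistical structure the GRS analysis
assumes: unlinked biallelic SNPs in Hardy-Weinberg equilibrium, a
logistic penetrance acting through the population-standardized weighted
score, and retrospective (case-control) ascertainment from a
low-prevalence population.

For a handful of SNPs the full genotype state space (3^m states) is
enumerable, so instead of prospectively simulating a huge population at
prevalence of order 10^-4, the generator computes the exact population,
case and control distributions over states and samples cohorts directly
from them:

    pop_prob(g)     = prod_j Binom(d_j; 2, f_j)          (HWE)
    penetrance(g)   = expit(mu + beta * z(g))
    case_prob(g)    = pop_prob(g) penetrance(g) / K
    control_prob(g) = pop_prob(g) (1 - penetrance(g)) / (1 - K)

where ``z(g)`` is the raw weighted score standardized by its exact
population moments (mean ``sum_j 2 f_j w_j``, variance ``sum_j
2 f_j (1-f_j) w_j^2``) and the intercept ``mu`` is solved numerically so
the population prevalence equals ``K``.

Covariates (sex, age group, country) are drawn independently of
genotype from case- and control-specific margins; the defaults follow
the CEFALO childhood brain-tumor study's cohort composition (245 cases,
489 controls from Sweden, Norway, Denmark and Switzerland).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ComputationError, ValidationError
from .genotypes import (
    AGE_LEVELS,
    COUNTRY_LEVELS,
    SEX_LEVELS,
    CohortData,
)
from .weights import SnpWeight, glioma_discovery_weights

# Case/control covariate margins of the emulated study (fractions of
# 245 cases and 489 controls respectively).
DEFAULT_MARGINS = {
    "case": {
        "sex": (136 / 245, 109 / 245),
        "age_group": (48 / 245, 108 / 245, 89 / 245),
        "country": (106 / 245, 24 / 245, 62 / 245, 53 / 245),
    },
    "control": {
        "sex": (261 / 489, 228 / 489),
        "age_group": (112 / 489, 219 / 489, 158 / 489),
        "country": (174 / 489, 62 / 489, 134 / 489, 119 / 489),
    },
}

# Risk-allele frequencies are not dictated by the emulated study (it
# reports none); any mid-range values exercise the pipeline equally.
DEFAULT_FREQS = (0.49, 0.42, 0.31, 0.76, 0.77)

DEFAULT_PREVALENCE = 0.0004        # 0.04% population prevalence
DEFAULT_BETA_PER_SD = math.log(1.25)


def _default_weights() -> list[SnpWeight]:
    return glioma_discovery_weights()


@dataclass
class SimulationSpec:
    """Generating conditions for one synthetic cohort."""

    weights: list[SnpWeight] = field(default_factory=_default_weights)
    risk_allele_freqs: tuple[float, ...] = DEFAULT_FREQS
    beta_per_sd: float = DEFAULT_BETA_PER_SD
    prevalence_K: float = DEFAULT_PREVALENCE
    n_cases: int = 245
    n_controls: int = 489
    covariate_margins: dict = field(default_factory=lambda: DEFAULT_MARGINS)
    seed: int = 0
    effect_mode: str = "score"  # "score": beta on standardized GRS; "per_snp": beta_j = w_j

    def __post_init__(self) -> None:
        if len(self.risk_allele_freqs) != len(self.weights):
            raise ValidationError(
                "risk_allele_freqs length must equal the number of weights"
            )
        if not all(0.0 < f < 1.0 for f in self.risk_allele_freqs):
            raise ValidationError("allele frequencies must lie in (0, 1)")
        if not 0.0 < self.prevalence_K < 1.0:
            raise ValidationError("prevalence must lie in (0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValidationError("cohort sizes must be positive")
        if self.effect_mode not in ("score", "per_snp"):
            raise ValidationError("effect_mode must be 'score' or 'per_snp'")


@dataclass
class GenotypeDistribution:
    """Exact state-space distributions behind the generator."""

    states: np.ndarray          # (3^m, m) dosage vectors
    pop_prob: np.ndarray
    case_prob: np.ndarray
    control_prob: np.ndarray
    intercept_mu: float
    pop_mean_raw: float
    pop_sd_raw: float
    penetrance: np.ndarray


def _hwe_probs(f: float) -> np.ndarray:
    """Genotype probabilities (dosage 0, 1, 2) at risk-allele frequency f."""
    return np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])


def exact_distribution(spec: SimulationSpec) -> GenotypeDistribution:
    """Enumerate the exact population/case/control genotype distributions.

    Limited to m <= 12 SNPs (3^m states).  The penetrance intercept is
    solved by Brent root finding so the population prevalence matches
    ``spec.prevalence_K`` to ~1e-12.
    """
    m = len(spec.weights)
    if m > 12:
        raise ValidationError("exact enumeration supported for at most 12 SNPs")
    log_w = np.array([w.log_weight for w in spec.weights])
    freqs = np.asarray(spec.risk_allele_freqs, dtype=float)

    states = np.array(list(itertools.product((0, 1, 2), repeat=m)), dtype=float)
    per_snp = np.stack([_hwe_probs(f) for f in freqs])  # (m, 3)
    pop_prob = np.prod(
        per_snp[np.arange(m), states.astype(int)], axis=1
    )

    raw = states @ log_w
    pop_mean = float(2.0 * (freqs * log_w).sum())
    pop_var = float((2.0 * freqs * (1.0 - freqs) * log_w**2).sum())
    pop_sd = math.sqrt(pop_var)

    if spec.effect_mode == "score":
        linear = spec.beta_per_sd * (raw - pop_mean) / pop_sd
    else:  # per-SNP effects equal to the table's log odds ratios
        linear = raw - pop_mean

    K = spec.prevalence_K

    def prevalence_gap(mu: float) -> float:
        return float(np.dot(pop_prob, expit(mu + linear))) - K

    span = float(np.abs(linear).max()) + 1.0
    lo = math.log(K / (1 - K)) - span - 35.0
    hi = math.log(K / (1 - K)) + span + 35.0
    if prevalence_gap(lo) > 0 or prevalence_gap(hi) < 0:
        raise ComputationError(
            "cannot bracket the penetrance intercept; check beta and prevalence"
        )
    mu = brentq(prevalence_gap, lo, hi, xtol=1e-13, rtol=8.9e-16)

    penetrance = expit(mu + linear)
    K_exact = float(np.dot(pop_prob, penetrance))
    case_prob = pop_prob * penetrance / K_exact
    control_prob = pop_prob * (1.0 - penetrance) / (1.0 - K_exact)
    return GenotypeDistribution(
        states=states,
        pop_prob=pop_prob,
        case_prob=case_prob,
        control_prob=control_prob,
        intercept_mu=float(mu),
        pop_mean_raw=pop_mean,
        pop_sd_raw=pop_sd,
        penetrance=penetrance,
    )


def _draw_covariates(
    rng: np.random.Generator,
    n: int,
    margins: dict,
) -> pd.DataFrame:
    cols = {}
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("age_group", AGE_LEVELS),
        ("country", COUNTRY_LEVELS),
    ):
        probs = np.asarray(margins[col], dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(levels), size=n, p=probs)
        cols[col] = pd.Categorical.from_codes(draws, categories=list(levels))
    return pd.DataFrame(cols)


def sample_cohort(
    spec: SimulationSpec,
    distribution: GenotypeDistribution | None = None,
) -> tuple[CohortData, dict]:
    """Draw one retrospectively ascertained cohort under the spec.

    Cases and controls are sampled from the exact case/control state
    distributions; covariates come from status-specific margins,
    independent of genotype.  Returns the cohort plus a sidecar dict of
    the true generating parameters for recovery tests.  Deterministic
    for a fixed ``spec.seed``.
    """
    dist = distribution if distribution is not None else exact_distribution(spec)
    rng = np.random.default_rng(spec.seed)

    case_idx = rng.choice(len(dist.states), size=spec.n_cases, p=dist.case_prob)
    ctrl_idx = rng.choice(len(dist.states), size=spec.n_controls, p=dist.control_prob)
    dosage = np.vstack([dist.states[case_idx], dist.states[ctrl_idx]])

    status = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    sample_ids = [f"case_{i + 1:04d}" for i in range(spec.n_cases)] + [
        f"ctrl_{i + 1:04d}" for i in range(spec.n_controls)
    ]
    cov_cases = _draw_covariates(rng, spec.n_cases, spec.covariate_margins["case"])
    cov_ctrls = _draw_covariates(rng, spec.n_controls, spec.covariate_margins["control"])
    phenotypes = pd.concat([cov_cases, cov_ctrls], ignore_index=True)
    phenotypes.insert(0, "status", status)
    phenotypes.insert(0, "sample_id", sample_ids)

    cohort = CohortData(
        sample_ids=sample_ids,
        dosage_matrix=dosage,
        weights=list(spec.weights),
        phenotypes=phenotypes,
    )
    truth = {
        "beta_per_sd": spec.beta_per_sd,
        "effect_mode": spec.effect_mode,
        "prevalence_K": spec.prevalence_K,
        "risk_allele_freqs": list(spec.risk_allele_freqs),
        "intercept_mu": dist.intercept_mu,
        "pop_mean_raw": dist.pop_mean_raw,
        "pop_sd_raw": dist.pop_sd_raw,
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
        "seed": spec.seed,
    }
    return cohort, truth


def parameter_recovery(
    n_reps: int = 200,
    master_seed: int = 42,
    spec: SimulationSpec | None = None,
) -> dict:
    """Repeated simulate-and-refit study under one set of generating conditions.

    Draws ``n_reps`` cohorts from the exact distribution of ``spec``
    (defaults: the emulated study's design), runs scoring and the
    full/reduced logistic analysis on each, and summarizes the estimates.
    Per-replicate seeds derive from ``master_seed``.
    """
    from .association import associate
    from .scoring import score_cohort

    base = spec if spec is not None else SimulationSpec()
    dist = exact_distribution(base)
    rng = np.random.default_rng(master_seed)
    ors: list[float] = []
    delta_r2: list[float] = []
    for _ in range(n_reps):
        rep = SimulationSpec(
            weights=base.weights,
            risk_allele_freqs=base.risk_allele_freqs,
            beta_per_sd=base.beta_per_sd,
            prevalence_K=base.prevalence_K,
            n_cases=base.n_cases,
            n_controls=base.n_controls,
            covariate_margins=base.covariate_margins,
            seed=int(rng.integers(2**31)),
            effect_mode=base.effect_mode,
        )
        cohort, _ = sample_cohort(rep, dist)
        result = associate(score_cohort(cohort), cohort.phenotypes)
        ors.append(result.or_per_sd)
        delta_r2.append(result.delta_r2_nagelkerke)
    ors_arr = np.array(ors)
    dr2_arr = np.array(delta_r2)
    return {
        "n_reps": n_reps,
        "true_or_per_sd": math.exp(base.beta_per_sd),
        "or_per_sd": ors_arr,
        "delta_r2_nagelkerke": dr2_arr,
        "mean_or_per_sd": float(ors_arr.mean()),
        "mean_delta_r2": float(dr2_arr.mean()),
    }


# ---------------------------------------------------------------------------
# Plain-text writers round-trippable through the genotype readers.

def write_vcf(cohort: CohortData, path: str | Path) -> None:
    """Write cohort genotypes as a minimal VCF 4.2 (REF=other, ALT=risk)."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom in dict.fromkeys(w.chrom for w in cohort.weights):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(cohort.sample_ids)
    )
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, w in enumerate(cohort.weights):
        col = cohort.dosage_matrix[:, j]
        gts = "\t".join(
            "./." if np.isnan(d) else gt_codes[float(d)] for d in col
        )
        lines.append(
            f"{w.chrom}\t{w.pos_bp}\t{w.snp_id}\t{w.other_allele}\t"
            f"{w.risk_allele}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_dosage_tsv(cohort: CohortData, path: str | Path) -> None:
    """Write cohort genotypes in the dosage-TSV dialect."""
    header = ["sample_id"] + [
        f"{w.snp_id}_{w.risk_allele}_{w.other_allele}" for w in cohort.weights
    ]
    rows = [header]
    for i, sid in enumerate(cohort.sample_ids):
        row = [sid] + [
            "NA" if np.isnan(d) else str(int(d))
            for d in cohort.dosage_matrix[i]
        ]
        rows.append(row)
    Path(path).write_text("\n".join("\t".join(r) for r in rows) + "\n")


def write_phenotypes(cohort: CohortData, path: str | Path) -> None:
    """Write the phenotype/covariate TSV."""
    cohort.phenotypes.to_csv(path, sep="\t", index=False)
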