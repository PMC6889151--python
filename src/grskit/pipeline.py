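"""End-to-end run: weights -> genotypes -> score -> association -> liability -> power.

:func:`run` reads the input files named in a :class:`RunConfig`,
executes the full analysis chain, and writes three artifacts into the
output directory: ``report.json`` (full-precision machine-readable
results), ``summary.txt`` (rounded human summary) and ``scores.tsv``
(per-sample raw and standardized scores).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .association import AssociationResult, associate
from .errors import ValidationError
from .genotypes import PalindromicPolicy, harmonize, read_dosage_tsv, read_phenotypes, read_vcf
from .liability import LiabilityResult, full_chain
from .power import PowerQuery, PowerResult, min_detectable_or_analytic
from .scoring import MissingPolicy, score_cohort
from .weights import load_weights

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths and analysis settings for one pipeline run."""

    weights_path: str
    genotypes_path: str
    phenotypes_path: str
    output_dir: str
    genotype_format: str = "auto"  # auto | vcf | dosage
    missing_policy: str = MissingPolicy.MEAN_IMPUTE.value
    palindromic_policy: str = PalindromicPolicy.EXCLUDE.value
    covariates: tuple[str, ...] = ("sex", "age_group", "country")
    prevalence_K: float = 0.0004
    power_alpha: float = 0.05 / 92
    power_power: float = 0.80
    power_freqs: tuple[float, ...] | None = None  # per-SNP risk-allele freqs

    def validate(self) -> None:
        for attr in ("weights_path", "genotypes_path", "phenotypes_path"):
            path = Path(getattr(self, attr))
            if not path.exists():
                raise ValidationError(f"{attr}: no such file {path}")

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["covariates"] = list(self.covariates)
        if self.power_freqs is not None:
            out["power_freqs"] = list(self.power_freqs)
        return out


@dataclass
class RunReport:
    """Everything one pipeline run computed, plus provenance."""

    association: AssociationResult
    liability: LiabilityResult
    power: dict[str, PowerResult]
    config: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "association": self.association.to_dict(),
            "liability": self.liability.to_dict(),
            "power": {k: v.to_dict() for k, v in self.power.items()},
            "config": self.config,
            "version": self.version,
        }


def _summary_text(report: RunReport) -> str:
    a = report.association
    h = report.liability
    lines = [
        "Genetic risk score association summary",
        "--------------------------------------",
        f"samples analysed : {a.n} ({a.case_fraction:.1%} cases)",
        f"OR per SD of GRS : {a.or_per_sd:.2f} [95% CI {a.ci_low:.2f}-{a.ci_high:.2f}]",
        f"Wald p-value     : {a.p_value:.3g}  (LRT p = {a.p_value_lrt:.3g})",
        f"Nagelkerke dR2   : {a.delta_r2_nagelkerke:.3f} (full - reduced)",
        f"prevalence K     : {h.prevalence_K:.4%}",
        f"liability h2     : {h.h2_liability:.3f}",
    ]
    if report.power:
        lines.append("minimum detectable per-allele OR:")
        for snp, res in report.power.items():
            lines.append(f"  {snp}: {res.min_detectable_or:.2f}")
    return "\n".join(lines) + "\n"


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis chain described by ``config``."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    weights = load_weights(config.weights_path)

    fmt = config.genotype_format
    if fmt == "auto":
        fmt = "vcf" if str(config.genotypes_path).endswith((".vcf", ".vcf.gz")) else "dosage"
    reader = read_vcf if fmt == "vcf" else read_dosage_tsv
    records, sample_ids = reader(config.genotypes_path)
    phenotypes = read_phenotypes(config.phenotypes_path)

    cohort = harmonize(
        records, weights, phenotypes, sample_ids,
        palindromic=PalindromicPolicy(config.palindromic_policy),
    )
    n_missing = np.isnan(cohort.dosage_matrix).sum(axis=0)
    for w, nm in zip(cohort.weights, n_missing):
        logger.info("SNP %s: %d missing dosages", w.snp_id, int(nm))

    scores = score_cohort(cohort, config.missing_policy)
    logger.info(
        "standardization: mean=%.6g sd=%.6g policy=%s",
        scores.mean_used, scores.sd_used, config.missing_policy,
    )
    association = associate(scores, cohort.phenotypes, config.covariates)
    liability = full_chain(
        association.delta_r2_nagelkerke,
        config.prevalence_K,
        association.case_fraction,
    )

    power: dict[str, PowerResult] = {}
    if config.power_freqs is not None:
        if len(config.power_freqs) != len(cohort.weights):
            raise ValidationError("power_freqs length must match analysed SNPs")
        n_cases = int(cohort.phenotypes["status"].sum())
        n_controls = cohort.n_samples - n_cases
        for w, f in zip(cohort.weights, config.power_freqs):
            power[w.snp_id] = min_detectable_or_analytic(
                PowerQuery(
                    n_cases=n_cases,
                    n_controls=n_controls,
                    risk_allele_freq=f,
                    alpha=config.power_alpha,
                    power=config.power_power,
                )
            )

    report = RunReport(
        association=association,
        liability=liability,
        power=power,
        config=config.to_dict(),
    )
    try:
        (out_dir / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=float) + "\n"
        )
        (out_dir / "summary.txt").write_text(_summary_text(report))
        scores.write_tsv(out_dir / "scores.tsv")
    except Exception:
        for name in ("report.json", "summary.txt", "scores.tsv"):
            (out_dir / name).unlink(missing_ok=True)
        raise
    return report
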