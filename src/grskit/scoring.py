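"""Weighted genetic risk score computation and standardization.

The raw score of sample *i* is the plain weighted sum

    GRS_i = sum_j d_ij * ln(OR_j)

over the harmonized risk-allele dosages ``d_ij``.  Scores are then
standardized with the mean and sample standard deviation (n-1
denominator) of the pooled case+control analysis sample, so the odds
ratio attached to the standardized score reads as the change in odds
per one SD of GRS.

Missing dosages are handled by policy: the default replaces a missing
dosage with the SNP's mean dosage over non-missing samples (the
behavior of conventional score-profile tools), ``complete_case`` drops
any sample with a missing genotype, and ``zero`` counts it as zero risk
alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ComputationError, DegenerateScoreError, ValidationError
from .genotypes import CohortData


class MissingPolicy(str, Enum):
    MEAN_IMPUTE = "mean_impute"
    COMPLETE_CASE = "complete_case"
    ZERO = "zero"


@dataclass
class ScoreSet:
    """Raw and standardized GRS per sample, with the moments used."""

    sample_ids: list[str]
    raw_score: np.ndarray
    std_score: np.ndarray
    mean_used: float
    sd_used: float
    n_snps_used: np.ndarray  # per sample: SNPs with a non-missing dosage

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw_score": self.raw_score,
                "std_score": self.std_score,
                "n_snps_used": self.n_snps_used,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def compute_grs(
    cohort: CohortData,
    missing_policy: MissingPolicy | str = MissingPolicy.MEAN_IMPUTE,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Raw weighted score per sample.

    Returns ``(raw_scores, kept_sample_ids, n_snps_used)``; under
    ``complete_case`` the kept ids may be a subset of the cohort.
    """
    missing_policy = MissingPolicy(missing_policy)
    if cohort.n_samples == 0:
        raise ValidationError("empty cohort")
    if cohort.n_snps == 0:
        raise ValidationError("no SNPs left to score")

    dosages = cohort.dosage_matrix.astype(float).copy()
    missing = np.isnan(dosages)
    n_used = (~missing).sum(axis=1)
    log_weights = np.array([w.log_weight for w in cohort.weights])

    if missing_policy is MissingPolicy.COMPLETE_CASE:
        keep = ~missing.any(axis=1)
        if not keep.any():
            raise ComputationError("complete_case: every sample has a missing dosage")
        dosages = dosages[keep]
        ids = [s for s, k in zip(cohort.sample_ids, keep) if k]
        return dosages @ log_weights, ids, n_used[keep]

    if missing_policy is MissingPolicy.ZERO:
        dosages[missing] = 0.0
    else:  # mean imputation over the pooled sample
        for j in range(dosages.shape[1]):
            col_missing = missing[:, j]
            if col_missing.all():
                raise ComputationError(
                    f"SNP {cohort.weights[j].snp_id}: all dosages missing; "
                    "mean imputation impossible"
                )
            if col_missing.any():
                dosages[col_missing, j] = dosages[~col_missing, j].mean()
    return dosages @ log_weights, list(cohort.sample_ids), n_used


def standardize(
    raw_scores: np.ndarray,
    sample_ids: list[str] | None = None,
    n_snps_used: np.ndarray | None = None,
) -> ScoreSet:
    """Standardize raw scores to mean 0, SD 1 over the pooled sample."""
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size < 2:
        raise ValidationError("standardization requires at least two samples")
    mean = float(raw.mean())
    sd = float(raw.std(ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateScoreError("raw scores are constant; SD is zero")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(raw.size)]
    if n_snps_used is None:
        n_snps_used = np.full(raw.size, -1)
    return ScoreSet(
        sample_ids=list(sample_ids),
        raw_score=raw,
        std_score=(raw - mean) / sd,
        mean_used=mean,
        sd_used=sd,
        n_snps_used=np.asarray(n_snps_used),
    )


def score_cohort(
    cohort: CohortData,
    missing_policy: MissingPolicy | str = MissingPolicy.MEAN_IMPUTE,
) -> ScoreSet:
    """Convenience: compute raw scores and standardize in one step."""
    raw, ids, n_used = compute_grs(cohort, missing_policy)
    return standardize(raw, ids, n_used)
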