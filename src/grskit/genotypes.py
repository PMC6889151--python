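"""Genotype and phenotype input, and allele harmonization.

Genotypes arrive either as a VCF (GT genotypes, biallelic sites) or as
a simple dosage TSV whose column names carry the counted allele, e.g.
``rs2736100_C_A`` for "count of C, other allele A".  Either route yields
per-SNP :class:`GenotypeRecord` objects holding hard-call dosages in
{0, 1, 2} with NaN for missing.

Harmonization orients every dosage column so that it counts the weight
table's risk allele: a column counting the other allele is flipped
``d -> 2 - d``; a strand-complement presentation (e.g. weights C/A,
genotypes G/T) is complemented first.  Palindromic SNPs (A/T or C/G)
cannot be strand-resolved from alleles alone and are excluded by
default.  SNPs are matched by rs identifier, not position.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import (
    FormatError,
    HarmonizationError,
    MissingSnpError,
    ValidationError,
)
from .weights import SnpWeight

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SEX_LEVELS = ("male", "female")
AGE_LEVELS = ("7-9", "10-14", "15-19")
COUNTRY_LEVELS = ("SE", "NO", "DK", "CH")

_DOSAGE_COLUMN = re.compile(r"^(?P<snp>\S+)_(?P<counted>[ACGT])_(?P<other>[ACGT])$")


@dataclass
class GenotypeRecord:
    """Hard-call dosages of one biallelic SNP.

    ``allele_a`` is the counted allele of the stored dosages and
    ``allele_b`` the alternative; missing calls are NaN.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        observed = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValidationError(
                f"{self.snp_id}: dosages must be 0, 1, 2 or missing"
            )


@dataclass
class CohortData:
    """Analysis-ready cohort: risk-allele dosage matrix joined to phenotypes.

    ``dosage_matrix`` is samples x SNPs with columns in weight-table
    order, each counting the corresponding risk allele; ``weights``
    holds the (possibly palindromic-filtered) weight records the columns
    align to.  ``phenotypes`` is indexed like ``sample_ids``.
    """

    sample_ids: list[str]
    dosage_matrix: np.ndarray
    weights: list[SnpWeight]
    phenotypes: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.dosage_matrix.shape
        if n != len(self.sample_ids):
            raise ValidationError("dosage matrix row count != number of samples")
        if m != len(self.weights):
            raise ValidationError("dosage matrix column count != number of weights")
        if len(self.phenotypes) != n:
            raise ValidationError("phenotype table does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.weights)


class PalindromicPolicy(str, Enum):
    """What to do with A/T and C/G weight-table SNPs during harmonization."""

    EXCLUDE = "exclude"  # drop the SNP with a warning (default)
    KEEP = "keep"        # assume same strand; orient by allele identity
    ERROR = "error"      # refuse to proceed


def read_vcf(path: str | Path) -> tuple[list[GenotypeRecord], list[str]]:
    """Read GT genotypes from a VCF into ALT-dosage records.

    Only biallelic records are retained (others are skipped with a
    warning).  The counted allele is ALT; ``./.`` becomes NaN.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    with vcf:
        if "GT" not in vcf.header.formats:
            raise FormatError(f"VCF {path} has no GT FORMAT field")
        sample_ids = list(vcf.header.samples)
        records: list[GenotypeRecord] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                logger.warning(
                    "skipping non-biallelic record %s at %s:%s",
                    rec.id, rec.chrom, rec.pos,
                )
                continue
            dosages = np.full(len(sample_ids), np.nan)
            for i, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                dosages[i] = sum(1 for a in gt if a == 1)
            records.append(
                GenotypeRecord(
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=str(rec.chrom),
                    pos_bp=rec.pos,
                    allele_a=str(rec.alts[0]),
                    allele_b=str(rec.ref),
                    dosages=dosages,
                )
            )
    return records, sample_ids


def read_dosage_tsv(path: str | Path) -> tuple[list[GenotypeRecord], list[str]]:
    """Read a dosage TSV: ``sample_id`` then one ``snp_counted_other`` column per SNP.

    Cells must be 0, 1, 2 or NA.  Positions are unknown in this dialect
    and recorded as 0 with chromosome '.'.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.columns[0] != "sample_id":
        raise FormatError(f"dosage TSV {path}: first column must be 'sample_id'")
    sample_ids = frame["sample_id"].astype(str).tolist()
    records: list[GenotypeRecord] = []
    for col in frame.columns[1:]:
        match = _DOSAGE_COLUMN.match(col)
        if not match:
            raise FormatError(
                f"dosage TSV {path}: column {col!r} is not of the form "
                "'snpid_countedAllele_otherAllele'"
            )
        cells = frame[col]
        dosages = np.full(len(cells), np.nan)
        for i, cell in enumerate(cells):
            if pd.isna(cell) or cell == "NA":
                continue
            if cell not in ("0", "1", "2"):
                raise ValidationError(
                    f"dosage TSV {path}: row {i + 1}, column {col}: "
                    f"value {cell!r} not in {{0,1,2,NA}}"
                )
            dosages[i] = float(cell)
        records.append(
            GenotypeRecord(
                snp_id=match["snp"],
                chrom=".",
                pos_bp=0,
                allele_a=match["counted"],
                allele_b=match["other"],
                dosages=dosages,
            )
        )
    return records, sample_ids


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/covariate TSV.

    Columns: sample_id (unique), status (1=case, 0=control), sex,
    age_group, country.  Categorical columns are returned as ordered
    pandas Categoricals with the package's fixed level order so that
    dummy coding is reproducible.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "status", "sex", "age_group", "country"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(
            f"phenotype table {path} missing column(s): {', '.join(missing)}"
        )
    if frame["sample_id"].duplicated().any():
        dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id(s): {dupes}")
    if not frame["status"].isin(("0", "1")).all():
        raise ValidationError("status must be 0 (control) or 1 (case)")
    out = pd.DataFrame({"sample_id": frame["sample_id"].astype(str)})
    out["status"] = frame["status"].astype(int)
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("age_group", AGE_LEVELS),
        ("country", COUNTRY_LEVELS),
    ):
        bad = set(frame[col]) - set(levels)
        if bad:
            raise ValidationError(f"{col}: unknown level(s) {sorted(bad)}")
        out[col] = pd.Categorical(frame[col], categories=levels)
    return out


def _orient(record: GenotypeRecord, weight: SnpWeight) -> np.ndarray | None:
    """Return record dosages oriented to count ``weight.risk_allele``.

    Tries direct identity, allele flip, then strand complement of both.
    Returns None when no presentation matches.
    """
    a, b = record.allele_a, record.allele_b
    risk, other = weight.risk_allele, weight.other_allele
    if (a, b) == (risk, other):
        return record.dosages.copy()
    if (a, b) == (other, risk):
        return 2.0 - record.dosages
    ca, cb = COMPLEMENT[a], COMPLEMENT[b]
    if (ca, cb) == (risk, other):
        return record.dosages.copy()
    if (ca, cb) == (other, risk):
        return 2.0 - record.dosages
    return None


def harmonize(
    records: Sequence[GenotypeRecord],
    weights: Sequence[SnpWeight],
    phenotypes: pd.DataFrame,
    sample_ids: Sequence[str],
    palindromic: PalindromicPolicy = PalindromicPolicy.EXCLUDE,
) -> CohortData:
    """Align genotype records to a weight table, oriented to risk alleles.

    Every weight-table SNP must appear exactly once among ``records``
    (matched by snp_id).  Phenotypes are joined by sample_id and
    restricted/reordered to ``sample_ids``.
    """
    by_id: dict[str, GenotypeRecord] = {}
    for rec in records:
        if rec.snp_id in by_id:
            raise ValidationError(f"genotype SNP {rec.snp_id} appears more than once")
        by_id[rec.snp_id] = rec

    absent = [w.snp_id for w in weights if w.snp_id not in by_id]
    if absent:
        raise MissingSnpError(absent)

    kept_weights: list[SnpWeight] = []
    columns: list[np.ndarray] = []
    for weight in weights:
        if weight.is_palindromic:
            if palindromic is PalindromicPolicy.ERROR:
                raise HarmonizationError(
                    f"{weight.snp_id}: palindromic alleles "
                    f"{weight.risk_allele}/{weight.other_allele}"
                )
            if palindromic is PalindromicPolicy.EXCLUDE:
                logger.warning(
                    "excluding palindromic SNP %s (%s/%s): strand unresolvable",
                    weight.snp_id, weight.risk_allele, weight.other_allele,
                )
                continue
        oriented = _orient(by_id[weight.snp_id], weight)
        if oriented is None:
            rec = by_id[weight.snp_id]
            raise HarmonizationError(
                f"{weight.snp_id}: genotype alleles {rec.allele_a}/{rec.allele_b} "
                f"irreconcilable with weight alleles "
                f"{weight.risk_allele}/{weight.other_allele}"
            )
        kept_weights.append(weight)
        columns.append(oriented)

    pheno = phenotypes.set_index("sample_id", drop=False)
    unknown = [s for s in sample_ids if s not in pheno.index]
    if unknown:
        raise ValidationError(f"samples without phenotype rows: {unknown[:5]}")
    pheno = pheno.loc[list(sample_ids)].reset_index(drop=True)

    matrix = (
        np.column_stack(columns)
        if columns
        else np.empty((len(sample_ids), 0))
    )
    return CohortData(
        sample_ids=list(sample_ids),
        dosage_matrix=matrix,
        weights=kept_weights,
        phenotypes=pheno,
    )
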