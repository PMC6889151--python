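"""SNP weight tables for genetic risk scores.

A weight table lists the susceptibility loci that enter the score: for
each biallelic SNP, the risk allele (the allele whose count increases
the score), the other allele, and the per-allele odds ratio estimated in
an external discovery GWAS.  The score weight is the natural logarithm
of the odds ratio, so that the weighted allele count is a log-odds
quantity commensurate with logistic-regression coefficients.

The on-disk format is a UTF-8 TSV with header columns ``snp_id``,
``chrom``, ``pos_bp``, ``risk_allele``, ``other_allele``, ``odds_ratio``.
Extra columns (confidence intervals, p-values) are accepted and ignored.

The package ships one table: the five adult-glioma susceptibility loci
(TERT, CDKN2A/B, PHLDB1 and two RTEL1 variants) with discovery-sample
odds ratios 1.29, 1.28, 1.14, 1.34 and 1.36, available through
:func:`glioma_discovery_weights`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import FormatError, ValidationError

VALID_ALLELES = frozenset("ACGT")

REQUIRED_COLUMNS = (
    "snp_id",
    "chrom",
    "pos_bp",
    "risk_allele",
    "other_allele",
    "odds_ratio",
)


@dataclass(frozen=True)
class SnpWeight:
    """One scored locus: alleles, per-allele odds ratio, log weight.

    ``log_weight`` is derived (natural log of ``odds_ratio``) and must
    not be supplied independently.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    risk_allele: str
    other_allele: str
    odds_ratio: float
    log_weight: float = field(init=False)

    def __post_init__(self) -> None:
        if self.risk_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: risk allele {self.risk_allele!r} not one of A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} not one of A/C/G/T"
            )
        if self.risk_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: risk and other allele identical")
        if not (isinstance(self.odds_ratio, (int, float)) and self.odds_ratio > 0):
            raise ValidationError(
                f"{self.snp_id}: odds ratio must be a positive number, "
                f"got {self.odds_ratio!r}"
            )
        if self.pos_bp < 1:
            raise ValidationError(f"{self.snp_id}: position must be 1-based positive")
        object.__setattr__(self, "log_weight", math.log(self.odds_ratio))

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G pairs, whose strand is unresolvable."""
        return {self.risk_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


def load_weights(path: str | Path) -> list[SnpWeight]:
    """Read a weight table TSV into an ordered list of :class:`SnpWeight`.

    Row order is preserved.  Raises :class:`FormatError` if a required
    column is missing and :class:`ValidationError` for a non-positive or
    non-numeric odds ratio or a duplicated SNP id.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse weight table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(
            f"weight table {path} is missing required column(s): {', '.join(missing)}"
        )
    weights: list[SnpWeight] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        snp_id = str(row["snp_id"]).strip()
        if snp_id in seen:
            raise ValidationError(f"duplicate snp_id in weight table: {snp_id}")
        seen.add(snp_id)
        try:
            odds_ratio = float(row["odds_ratio"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{snp_id}: odds ratio {row['odds_ratio']!r} is not numeric"
            ) from exc
        weights.append(
            SnpWeight(
                snp_id=snp_id,
                chrom=str(row["chrom"]).strip(),
                pos_bp=int(row["pos_bp"]),
                risk_allele=str(row["risk_allele"]).strip().upper(),
                other_allele=str(row["other_allele"]).strip().upper(),
                odds_ratio=odds_ratio,
            )
        )
    return weights


def write_weights(weights: Iterable[SnpWeight], path: str | Path) -> None:
    """Write a weight table TSV (the dialect :func:`load_weights` reads)."""
    frame = pd.DataFrame(
        [
            {
                "snp_id": w.snp_id,
                "chrom": w.chrom,
                "pos_bp": w.pos_bp,
                "risk_allele": w.risk_allele,
                "other_allele": w.other_allele,
                "odds_ratio": repr(w.odds_ratio),
            }
            for w in weights
        ],
        columns=list(REQUIRED_COLUMNS),
    )
    frame.to_csv(path, sep="\t", index=False)


def glioma_discovery_weights() -> list[SnpWeight]:
    """The five published adult-glioma GRS loci shipped with the package.

    Returns the loci in score order with their discovery-sample
    per-allele odds ratios (1.29, 1.28, 1.14, 1.34, 1.36).
    """
    ref = resources.files("grskit").joinpath("data/glioma_grs_weights.tsv")
    with resources.as_file(ref) as path:
        return load_weights(path)
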