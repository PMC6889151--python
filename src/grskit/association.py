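"""Logistic association of the standardized GRS with case status.

The analysis is an unmatched (unconditional) logistic regression:

    full model     status ~ std_score + sex + age_group + country
    reduced model  status ~ sex + age_group + country
    null model     status ~ 1

Categorical covariates are dummy-coded with the first declared level as
reference (male; 7-9 years; Sweden).  The per-SD odds ratio is
``exp(beta)`` for the standardized score, with a 95% Wald interval
``exp(beta +/- 1.959964 SE)`` and a two-sided Wald p-value.  Variance
explained is summarized by Cox-Snell and Nagelkerke pseudo-R^2; the
score's contribution is the Nagelkerke difference between the full and
reduced models.  A likelihood-ratio p-value for the score is reported
alongside the Wald one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import ComputationError, SeparationError, ValidationError
from .scoring import ScoreSet

Z_95 = 1.959964  # two-sided 95% normal quantile

DEFAULT_COVARIATES = ("sex", "age_group", "country")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficients, SEs, log-likelihood."""

    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    converged: bool
    design_labels: list[str]

    def coef_of(self, label: str) -> tuple[float, float]:
        i = self.design_labels.index(label)
        return float(self.coef[i]), float(self.se[i])


@dataclass
class AssociationResult:
    """Summary of the GRS association analysis."""

    or_per_sd: float
    ci_low: float
    ci_high: float
    p_value: float
    p_value_lrt: float
    beta: float
    se: float
    loglik_full: float
    loglik_reduced: float
    loglik_null: float
    r2_nagelkerke_full: float
    r2_nagelkerke_reduced: float
    delta_r2_nagelkerke: float
    r2_coxsnell_full: float
    n: int
    case_fraction: float
    term_table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "or_per_sd", "ci_low", "ci_high", "p_value", "p_value_lrt",
                "beta", "se", "loglik_full", "loglik_reduced", "loglik_null",
                "r2_nagelkerke_full", "r2_nagelkerke_reduced",
                "delta_r2_nagelkerke", "r2_coxsnell_full", "n", "case_fraction",
            )
        }
        if self.term_table is not None:
            out["terms"] = self.term_table.to_dict(orient="records")
        return out


def fit_logistic(
    response: np.ndarray,
    design: np.ndarray,
    design_labels: Sequence[str] | None = None,
) -> LogisticFit:
    """Fit a logistic regression by Newton/IRLS maximum likelihood.

    ``design`` must include the intercept column.  Convergence at
    max |delta coef| < 1e-8 within 100 iterations; SEs come from the
    inverse observed information.  Raises :class:`SeparationError` on
    perfect separation and :class:`ValidationError` for a single-class
    response or rank-deficient design.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("response must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise ValidationError("response has a single class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")
    if design_labels is None:
        design_labels = [f"x{i}" for i in range(X.shape[1])]

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise ComputationError("logistic fit did not converge in 100 iterations")
    if np.abs(res.params).max() > 30:
        raise SeparationError("diverging coefficients suggest perfect separation")
    return LogisticFit(
        coef=np.asarray(res.params),
        se=np.asarray(res.bse),
        loglik=float(res.llf),
        n=len(y),
        converged=True,
        design_labels=list(design_labels),
    )


def pseudo_r2(loglik_model: float, loglik_null: float, n: int) -> tuple[float, float]:
    """Cox-Snell and Nagelkerke pseudo-R^2 of a fitted model.

    Cox-Snell: ``1 - exp(2 (ll0 - ll1) / n)``; Nagelkerke rescales by
    the maximum attainable value ``1 - exp(2 ll0 / n)``.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    if loglik_model < loglik_null - 1e-8:
        raise ValidationError(
            f"model log-likelihood {loglik_model} below null {loglik_null}"
        )
    r2_cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    r2_max = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(r2_cs), float(r2_cs / r2_max)


def build_design(
    phenotypes: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    std_score: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix with intercept (first level = reference)."""
    n = len(phenotypes)
    cols: list[np.ndarray] = [np.ones(n)]
    labels: list[str] = ["intercept"]
    if std_score is not None:
        cols.append(np.asarray(std_score, dtype=float))
        labels.append("std_score")
    for cov in covariates:
        series = phenotypes[cov]
        if not isinstance(series.dtype, pd.CategoricalDtype):
            series = series.astype("category")
        dummies = pd.get_dummies(series, drop_first=True)
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy(dtype=float))
            labels.append(f"{cov}[{level}]")
    return np.column_stack(cols), labels


def associate(
    scores: ScoreSet,
    phenotypes: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> AssociationResult:
    """Full/reduced logistic analysis of the standardized GRS.

    ``phenotypes`` must cover exactly the scored samples (matched by
    sample_id).  Returns the per-SD odds ratio with Wald CI and p, the
    pseudo-R^2 of both models and their Nagelkerke difference.
    """
    pheno = phenotypes.set_index("sample_id", drop=False)
    missing = [s for s in scores.sample_ids if s not in pheno.index]
    if missing:
        raise ValidationError(f"scored samples without phenotypes: {missing[:5]}")
    pheno = pheno.loc[scores.sample_ids].reset_index(drop=True)

    y = pheno["status"].to_numpy(dtype=float)
    n = len(y)
    case_fraction = float(y.mean())

    X_full, labels_full = build_design(pheno, covariates, scores.std_score)
    X_red, labels_red = build_design(pheno, covariates, None)

    try:
        fit_full = fit_logistic(y, X_full, labels_full)
        fit_red = fit_logistic(y, X_red, labels_red)
    except SeparationError as exc:
        raise SeparationError(f"association model: {exc}") from exc
    fit_null = fit_logistic(y, np.ones((n, 1)), ["intercept"])

    beta, se = fit_full.coef_of("std_score")
    z = beta / se
    p_wald = 2.0 * stats.norm.sf(abs(z))
    lrt = 2.0 * (fit_full.loglik - fit_red.loglik)
    p_lrt = float(stats.chi2.sf(max(lrt, 0.0), df=1))

    r2_cs_full, r2_nag_full = pseudo_r2(fit_full.loglik, fit_null.loglik, n)
    _, r2_nag_red = pseudo_r2(fit_red.loglik, fit_null.loglik, n)

    term_table = pd.DataFrame(
        {
            "term": fit_full.design_labels,
            "coef": fit_full.coef,
            "se": fit_full.se,
            "or": np.exp(fit_full.coef),
            "p": 2.0 * stats.norm.sf(np.abs(fit_full.coef / fit_full.se)),
        }
    )

    return AssociationResult(
        or_per_sd=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        p_value=float(p_wald),
        p_value_lrt=p_lrt,
        beta=float(beta),
        se=float(se),
        loglik_full=fit_full.loglik,
        loglik_reduced=fit_red.loglik,
        loglik_null=fit_null.loglik,
        r2_nagelkerke_full=r2_nag_full,
        r2_nagelkerke_reduced=r2_nag_red,
        delta_r2_nagelkerke=r2_nag_full - r2_nag_red,
        r2_coxsnell_full=r2_cs_full,
        n=n,
        case_fraction=case_fraction,
        term_table=term_table,
    )
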