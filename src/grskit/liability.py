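"""Liability-scale heritability from the variance explained by a score.

Under the liability-threshold model, disease occurs when a latent
standard-normal liability exceeds ``t = Phi^-1(1 - K)`` for population
prevalence ``K``.  Variance explained measured on the observed (0/1)
scale in a case-control sample over-represents cases (sample case
fraction ``P`` instead of ``K``); the ascertainment-corrected
transformation to the liability scale is

    h2_liability = R2_obs * K^2 (1 - K)^2 / (z^2 * P (1 - P))

with ``z`` the standard-normal density at the threshold ``t``.

The observed-scale R^2 fed into this transform is the Cox-Snell value.
When the association stage reports a Nagelkerke R^2 (which rescales
Cox-Snell by its maximum attainable value), :func:`nagelkerke_to_observed`
undoes that rescaling first; :func:`full_chain` composes the two steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError


@dataclass
class LiabilityResult:
    """The transform's inputs, intermediates and liability-scale h^2."""

    r2_observed: float
    prevalence_K: float
    case_fraction_P: float
    threshold_t: float
    density_z: float
    h2_liability: float
    r2_nagelkerke_in: float | None = None

    def to_dict(self) -> dict:
        return {
            "r2_nagelkerke_in": self.r2_nagelkerke_in,
            "r2_observed": self.r2_observed,
            "prevalence_K": self.prevalence_K,
            "case_fraction_P": self.case_fraction_P,
            "threshold_t": self.threshold_t,
            "density_z": self.density_z,
            "h2_liability": self.h2_liability,
        }


def nagelkerke_to_observed(r2_nagelkerke: float, case_fraction_P: float) -> float:
    """Recover the Cox-Snell (observed-scale) R^2 from a Nagelkerke R^2.

    Multiplies by the Nagelkerke maximum ``1 - exp(2 ll0 / n)`` where
    ``ll0 / n = P ln P + (1-P) ln(1-P)`` is the per-observation null
    log-likelihood at case fraction ``P``.
    """
    if not 0.0 <= r2_nagelkerke <= 1.0:
        raise ValidationError("Nagelkerke R^2 must lie in [0, 1]")
    if not 0.0 < case_fraction_P < 1.0:
        raise ValidationError("case fraction must lie strictly in (0, 1)")
    P = case_fraction_P
    ll0_per_obs = P * math.log(P) + (1.0 - P) * math.log(1.0 - P)
    r2_max = 1.0 - math.exp(2.0 * ll0_per_obs)
    return r2_nagelkerke * r2_max


def liability_transform(
    r2_observed: float,
    prevalence_K: float,
    case_fraction_P: float,
) -> LiabilityResult:
    """Ascertainment-corrected observed-to-liability variance transform."""
    if not 0.0 < prevalence_K < 1.0:
        raise ValidationError("prevalence K must lie strictly in (0, 1)")
    if not 0.0 < case_fraction_P < 1.0:
        raise ValidationError("case fraction P must lie strictly in (0, 1)")
    if not 0.0 <= r2_observed <= 1.0:
        raise ValidationError("observed-scale R^2 must lie in [0, 1]")
    K, P = prevalence_K, case_fraction_P
    t = float(stats.norm.isf(K))  # Phi^-1(1 - K), exact upper-tail quantile
    z = float(stats.norm.pdf(t))
    h2 = r2_observed * K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))
    return LiabilityResult(
        r2_observed=r2_observed,
        prevalence_K=K,
        case_fraction_P=P,
        threshold_t=t,
        density_z=z,
        h2_liability=h2,
    )


def full_chain(
    r2_nagelkerke: float,
    prevalence_K: float,
    case_fraction_P: float,
) -> LiabilityResult:
    """Nagelkerke R^2 -> Cox-Snell R^2 -> liability-scale h^2."""
    r2_obs = nagelkerke_to_observed(r2_nagelkerke, case_fraction_P)
    result = liability_transform(r2_obs, prevalence_K, case_fraction_P)
    result.r2_nagelkerke_in = r2_nagelkerke
    return result
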