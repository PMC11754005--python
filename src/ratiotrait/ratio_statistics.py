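"""Closed-form and sample statistics for ratio traits.

A ratio trait ``p0 = p1 / p2`` is a quotient of two component traits that
are jointly normally distributed (e.g., feed efficiency = gain / intake,
fat percentage = fat yield / milk yield). This module provides

* the phenotypic covariance between the component traits implied by their
  heritabilities and genetic/environmental correlations,
* delta-method (second-order Taylor) approximations of the mean and
  variance of the ratio trait,
* a delta-method approximation of the ratio trait's heritability, and
* four-moment sample summaries (mean, variance, skewness, excess kurtosis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GeneticParams",
    "DeltaMoments",
    "DeltaHeritabilityInputs",
    "MomentSummary",
    "component_covariance",
    "genetic_covariance",
    "environmental_covariance",
    "delta_mean",
    "delta_variance",
    "delta_moments",
    "delta_heritability",
    "moment_summary",
]


@dataclass(frozen=True)
class GeneticParams:
    """Bivariate genetic parameterization of the two component traits.

    Parameters
    ----------
    mu1, mu2
        Trait means (trait units). ``mu2`` must be non-zero because the
        ratio trait divides by Trait 2.
    varp1, varp2
        Phenotypic variances, both strictly positive.
    h2_1, h2_2
        Narrow-sense heritabilities, each in [0, 1].
    r_g
        Genetic correlation between the breeding values of the two traits.
    r_e
        Environmental correlation between the residual deviations.
    """

    mu1: float
    mu2: float
    varp1: float = 1.0
    varp2: float = 1.0
    h2_1: float = 0.3
    h2_2: float = 0.3
    r_g: float = 0.0
    r_e: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_1 <= 1.0 and 0.0 <= self.h2_2 <= 1.0):
            raise ValueError("heritabilities must lie in [0, 1]")
        if not (-1.0 <= self.r_g <= 1.0 and -1.0 <= self.r_e <= 1.0):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.varp1 <= 0 or self.varp2 <= 0:
            raise ValueError("phenotypic variances must be positive")
        if self.mu2 == 0:
            raise ValueError("mu2 must be non-zero (ratio divides by Trait 2)")


@dataclass(frozen=True)
class DeltaMoments:
    """Delta-method mean and variance of the ratio trait.

    ``cov_p`` is the phenotypic covariance between the component traits
    that both approximations consume.
    """

    e_p0: float
    var_p0: float
    cov_p: float


@dataclass(frozen=True)
class DeltaHeritabilityInputs:
    """Assumed mean breeding values for the ratio-heritability approximation.

    Breeding values are relative quantities, so their expected values are a
    modelling choice rather than a property of the population; the
    approximation divides by ``eg2`` and therefore requires it non-zero.
    """

    eg1: float
    eg2: float

    def __post_init__(self) -> None:
        if self.eg2 == 0:
            raise ValueError("eg2 must be non-zero (approximation divides by it)")


@dataclass(frozen=True)
class MomentSummary:
    """First four moments of a sample: mean, variance, skewness, kurtosis.

    Variance, skewness and kurtosis use population (divide-by-n) central
    moments; kurtosis is reported as EXCESS kurtosis, so a normal sample
    gives ≈ 0.
    """

    n: int
    mean: float
    variance: float
    skewness: float
    kurtosis: float


def genetic_covariance(params: GeneticParams) -> float:
    """Additive-genetic covariance ``r_G·√(h₁²σ_p1²·h₂²σ_p2²)``."""
    return params.r_g * math.sqrt(
        params.h2_1 * params.varp1 * params.h2_2 * params.varp2
    )


def environmental_covariance(params: GeneticParams) -> float:
    """Environmental covariance ``r_E·√((1−h₁²)σ_p1²·(1−h₂²)σ_p2²)``."""
    return params.r_e * math.sqrt(
        (1.0 - params.h2_1) * params.varp1 * (1.0 - params.h2_2) * params.varp2
    )


def component_covariance(params: GeneticParams) -> float:
    """Phenotypic covariance between the component traits.

    cov(p₁,p₂) = [r_G·h₁h₂ + r_E·√((1−h₁²)(1−h₂²))]·σ_p1·σ_p2, where
    h_j = √(h_j²). Equals the sum of the genetic and environmental
    covariances. With unit phenotypic variances this reduces to the
    familiar r_G h₁h₂ + r_E √((1−h₁²)(1−h₂²)).
    """
    return genetic_covariance(params) + environmental_covariance(params)


def delta_mean(params: GeneticParams, cov_p: float) -> float:
    """Second-order delta-method approximation of E(p₁/p₂).

    E(p₀) ≈ μ₁/μ₂ − cov(p₁,p₂)/μ₂² + μ₁·σ_p2²/μ₂³
    """
    mu1, mu2 = params.mu1, params.mu2
    if mu2 == 0:
        raise ValueError("mu2 must be non-zero")
    return mu1 / mu2 - cov_p / mu2**2 + mu1 * params.varp2 / mu2**3


def delta_variance(params: GeneticParams, cov_p: float) -> float:
    """First-order delta-method approximation of var(p₁/p₂).

    var(p₀) ≈ σ_p1²/μ₂² + μ₁²·σ_p2²/μ₂⁴ − 2·μ₁·cov(p₁,p₂)/μ₂³
    """
    mu1, mu2 = params.mu1, params.mu2
    if mu2 == 0:
        raise ValueError("mu2 must be non-zero")
    return (
        params.varp1 / mu2**2
        + mu1**2 * params.varp2 / mu2**4
        - 2.0 * mu1 * cov_p / mu2**3
    )


def delta_moments(params: GeneticParams, cov_p: float | None = None) -> DeltaMoments:
    """Delta-method mean and variance packaged together.

    If ``cov_p`` is omitted it is computed from the genetic parameters via
    :func:`component_covariance`.
    """
    if cov_p is None:
        cov_p = component_covariance(params)
    return DeltaMoments(
        e_p0=delta_mean(params, cov_p),
        var_p0=delta_variance(params, cov_p),
        cov_p=cov_p,
    )


def delta_heritability(
    params: GeneticParams, dh: DeltaHeritabilityInputs | None = None
) -> float:
    """Delta-method approximation of the ratio trait's heritability h₀².

    The numerator applies the ratio-variance expansion to the breeding
    values g₁/g₂ around the assumed means (E(g₁), E(g₂)); the denominator
    is the phenotypic :func:`delta_variance`. Mean breeding values default
    to the trait means (μ₁, μ₂) since breeding value is a relative scale.

    h₀² ≈ [σ_g1²/E(g₂)² + E(g₁)²σ_g2²/E(g₂)⁴ − 2E(g₁)cov(g₁,g₂)/E(g₂)³]
          / [σ_p1²/μ₂² + μ₁²σ_p2²/μ₂⁴ − 2μ₁(cov_g + cov_e)/μ₂³]
    """
    if dh is None:
        dh = DeltaHeritabilityInputs(eg1=params.mu1, eg2=params.mu2)
    eg1, eg2 = dh.eg1, dh.eg2
    var_g1 = params.h2_1 * params.varp1
    var_g2 = params.h2_2 * params.varp2
    cov_g = genetic_covariance(params)
    numerator = (
        var_g1 / eg2**2
        + eg1**2 * var_g2 / eg2**4
        - 2.0 * eg1 * cov_g / eg2**3
    )
    denominator = delta_variance(params, component_covariance(params))
    if denominator == 0:
        raise ZeroDivisionError("delta-method phenotypic variance is zero")
    return numerator / denominator


def moment_summary(values: np.ndarray) -> MomentSummary:
    """Mean, variance, skewness and excess kurtosis of a sample.

    Uses population (divide-by-n) central moments without small-sample bias
    correction; intended for the ≥10⁴-record samples the simulations
    produce. Raises if the sample has fewer than 4 values or is constant
    (skewness/kurtosis undefined).
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 values for four moments, got {n}")
    variance = float(np.var(x))
    if variance == 0:
        raise ValueError("sample variance is zero; skewness/kurtosis undefined")
    return MomentSummary(
        n=n,
        mean=float(np.mean(x)),
        variance=variance,
        skewness=float(stats.skew(x, bias=True)),
        kurtosis=float(stats.kurtosis(x, fisher=True, bias=True)),
    )
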