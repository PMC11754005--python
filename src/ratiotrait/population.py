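"""Two-generation pedigreed population simulator for ratio traits.

Simulates a base generation (G0) of unrelated, unselected, non-inbred
parents with two jointly normal traits, mates each sire to a fixed number
of dams (each dam producing a fixed number of full-sib offspring), and
generates the offspring generation (G1) with Mendelian sampling through
the Cholesky factor of the genetic covariance matrix:

    g₁ = (g_s1 + g_d1)/2 + √0.5·Lg₁₁·z₁
    g₂ = (g_s2 + g_d2)/2 + √0.5·(Lg₂₁·z₁ + Lg₂₂·z₂)

The √0.5 scaling gives the within-family (Mendelian-sampling) deviations
covariance ½G, so that — added to the ½G variance of the midparent mean —
G1 genetic variance equals G0's and the population is stationary across
generations. Phenotypes are p_j = μ_j + g_j + e_j with environmental
deviations drawn through the Cholesky factor of E; the ratio trait is
p₀ = p₁/p₂.

Also provides the independent-record generator used to study the ratio
trait's distribution as a function of the component means and CVs alone.

Trait tables are pandas DataFrames with columns
``id, generation, sire_id, dam_id, g1, g2, p1, p2, p0``; a missing parent
is coded 0, as in common pedigree-file conventions. In G0 the first
``n_sires`` rows are the sires and the remaining rows the dams.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ratio_statistics import GeneticParams

__all__ = [
    "CovStructure",
    "PopulationDesign",
    "IndependentRatioSpec",
    "TRAIT_COLUMNS",
    "build_cov_structure",
    "simulate_base_generation",
    "simulate_offspring",
    "simulate_population",
    "simulate_independent_records",
    "write_trait_table",
    "read_trait_table",
]

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ["id", "generation", "sire_id", "dam_id", "g1", "g2", "p1", "p2", "p0"]

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class CovStructure:
    """Genetic (G), environmental (E) and phenotypic (P = G + E) 2×2
    covariance matrices with their lower Cholesky factors Lg, Le."""

    G: np.ndarray
    E: np.ndarray
    P: np.ndarray
    Lg: np.ndarray
    Le: np.ndarray


@dataclass(frozen=True)
class PopulationDesign:
    """Mating design: each sire is mated to ``dams_per_sire`` dams and each
    dam produces ``offspring_per_dam`` full-sib offspring.

    Defaults give the full-scale population: 100,000 sires ×
    10 dams × 2 offspring = 2,000,000 G1 individuals.
    """

    n_sires: int = 100_000
    dams_per_sire: int = 10
    offspring_per_dam: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_sires, self.dams_per_sire, self.offspring_per_dam) < 1:
            raise ValueError("all design counts must be >= 1")

    @property
    def n_dams(self) -> int:
        return self.n_sires * self.dams_per_sire

    @property
    def n_offspring(self) -> int:
        return self.n_dams * self.offspring_per_dam

    def scaled(self, factor: float) -> "PopulationDesign":
        """Design with sire count multiplied by ``factor`` (at least 10)."""
        return replace(self, n_sires=max(10, int(round(self.n_sires * factor))))


@dataclass(frozen=True)
class IndependentRatioSpec:
    """Independent-record generator settings: component means, coefficients
    of variation, and sample size. Defaults draw the full-scale 2,000,000
    records."""

    mu1: float = 10.0
    mu2: float = 10.0
    cv1: float = 0.10
    cv2: float = 0.10
    n_records: int = 2_000_000

    def __post_init__(self) -> None:
        if self.mu1 <= 0 or self.mu2 <= 0:
            raise ValueError("component means must be positive")
        if self.cv1 <= 0 or self.cv2 <= 0:
            raise ValueError("coefficients of variation must be positive")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")


def _chol2(m: np.ndarray, name: str) -> np.ndarray:
    """Lower Cholesky factor of a 2×2 positive SEMIdefinite matrix.

    np.linalg.cholesky rejects singular matrices, but zero heritability
    (or h² = 1 on the environmental side) legitimately produces them.
    """
    a, b, c = float(m[0, 0]), float(m[1, 0]), float(m[1, 1])
    if a < -_PSD_TOL or c < -_PSD_TOL:
        raise ValueError(f"{name} matrix has a negative diagonal; not PSD")
    l11 = math.sqrt(max(a, 0.0))
    if l11 > 0:
        l21 = b / l11
    elif abs(b) <= _PSD_TOL:
        l21 = 0.0
    else:
        raise ValueError(
            f"{name} matrix is not positive semidefinite: zero variance for "
            f"trait 1 but non-zero covariance {b!r}"
        )
    rem = c - l21 * l21
    if rem < -_PSD_TOL:
        raise ValueError(f"{name} matrix is not positive semidefinite")
    l22 = math.sqrt(max(rem, 0.0))
    return np.array([[l11, 0.0], [l21, l22]])


def build_cov_structure(params: GeneticParams) -> CovStructure:
    """Build G, E, P and their lower Cholesky factors from the genetic
    parameters: diag(G) = (h₁²σ_p1², h₂²σ_p2²), off-diagonal r_G·√(G₁₁G₂₂),
    and analogously for E with 1 − h²."""
    vg1 = params.h2_1 * params.varp1
    vg2 = params.h2_2 * params.varp2
    ve1 = (1.0 - params.h2_1) * params.varp1
    ve2 = (1.0 - params.h2_2) * params.varp2
    cg = params.r_g * math.sqrt(vg1 * vg2)
    ce = params.r_e * math.sqrt(ve1 * ve2)
    G = np.array([[vg1, cg], [cg, vg2]])
    E = np.array([[ve1, ce], [ce, ve2]])
    return CovStructure(G=G, E=E, P=G + E, Lg=_chol2(G, "genetic"), Le=_chol2(E, "environmental"))


def _bivariate_deviates(n: int, L: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n draws from N(0, L·Lᵀ) as an (n, 2) array."""
    z = rng.standard_normal((n, 2))
    return z @ L.T


def _ratio(p1: np.ndarray, p2: np.ndarray, mu2: float) -> np.ndarray:
    near_zero = np.abs(p2) < 1e-6 * abs(mu2)
    if near_zero.any():
        # ratio computed as-is: truncation/rejection would bias the moments
        logger.warning(
            "%d denominator phenotype(s) within 1e-6·|mu2| of zero", int(near_zero.sum())
        )
    return p1 / p2


def simulate_base_generation(
    params: GeneticParams,
    design: PopulationDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the unrelated base generation G0.

    Produces ``n_sires`` males (ids 1..n_sires) followed by ``n_dams``
    females. Breeding values are i.i.d. N(0, G) via Lg·z and environmental
    deviations N(0, E) via Le·z; p_j = μ_j + g_j + e_j, p₀ = p₁/p₂.
    """
    if rng is None:
        rng = np.random.default_rng([design.seed, 0])
    cov = build_cov_structure(params)
    n = design.n_sires + design.n_dams
    g = _bivariate_deviates(n, cov.Lg, rng)
    e = _bivariate_deviates(n, cov.Le, rng)
    p1 = params.mu1 + g[:, 0] + e[:, 0]
    p2 = params.mu2 + g[:, 1] + e[:, 1]
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1, dtype=np.int64),
            "generation": "G0",
            "sire_id": np.zeros(n, dtype=np.int64),
            "dam_id": np.zeros(n, dtype=np.int64),
            "g1": g[:, 0],
            "g2": g[:, 1],
            "p1": p1,
            "p2": p2,
            "p0": _ratio(p1, p2, params.mu2),
        }
    )


def simulate_offspring(
    g0: pd.DataFrame,
    params: GeneticParams,
    design: PopulationDesign,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the offspring generation G1 from a base generation.

    Dams are shuffled under the run seed and partitioned into consecutive
    blocks of ``dams_per_sire`` per sire (monogamous sires, no selection,
    no inbreeding); each dam produces ``offspring_per_dam`` full sibs.
    Offspring breeding values are midparent mean plus √0.5-scaled
    Mendelian sampling through Lg; phenotypes add μ_j and environmental
    deviations through Le.
    """
    if rng is None:
        rng = np.random.default_rng([design.seed, 1])
    expected = design.n_sires + design.n_dams
    if len(g0) != expected:
        raise ValueError(
            f"base generation has {len(g0)} rows; design requires "
            f"{design.n_sires} sires + {design.n_dams} dams = {expected}"
        )
    cov = build_cov_structure(params)
    sires = g0.iloc[: design.n_sires]
    dams = g0.iloc[design.n_sires :]

    dam_order = rng.permutation(design.n_dams)
    k = design.offspring_per_dam
    dam_idx = np.repeat(dam_order, k)
    sire_of_dam = np.repeat(np.arange(design.n_sires), design.dams_per_sire)
    sire_idx = np.repeat(sire_of_dam, k)

    gs = sires[["g1", "g2"]].to_numpy()[sire_idx]
    gd = dams[["g1", "g2"]].to_numpy()[dam_idx]
    mid = 0.5 * (gs + gd)

    n_off = design.n_offspring
    z = rng.standard_normal((n_off, 2))
    Lg, Le = cov.Lg, cov.Le
    root_half = math.sqrt(0.5)
    g1 = mid[:, 0] + root_half * Lg[0, 0] * z[:, 0]
    g2 = mid[:, 1] + root_half * (Lg[1, 0] * z[:, 0] + Lg[1, 1] * z[:, 1])
    ze = rng.standard_normal((n_off, 2))
    p1 = params.mu1 + g1 + Le[0, 0] * ze[:, 0]
    p2 = params.mu2 + g2 + Le[1, 0] * ze[:, 0] + Le[1, 1] * ze[:, 1]

    start = int(g0["id"].max()) + 1
    return pd.DataFrame(
        {
            "id": np.arange(start, start + n_off, dtype=np.int64),
            "generation": "G1",
            "sire_id": sires["id"].to_numpy()[sire_idx],
            "dam_id": dams["id"].to_numpy()[dam_idx],
            "g1": g1,
            "g2": g2,
            "p1": p1,
            "p2": p2,
            "p0": _ratio(p1, p2, params.mu2),
        }
    )


def simulate_population(
    params: GeneticParams, design: PopulationDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate G0 and G1 in one call; returns ``(g0, g1)``.

    Reproducible: the same seed, design and parameters give bit-identical
    tables (independent RNG streams are derived for each generation from
    ``design.seed``).
    """
    g0 = simulate_base_generation(params, design)
    g1 = simulate_offspring(g0, params, design)
    return g0, g1


def simulate_independent_records(
    spec: IndependentRatioSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ratio records p₁/p₂ from independent normal component traits.

    p₁ ~ N(μ₁, (CV₁μ₁)²) and p₂ ~ N(μ₂, (CV₂μ₂)²), independent.
    """
    if rng is None:
        rng = np.random.default_rng()
    p1 = rng.normal(spec.mu1, spec.cv1 * spec.mu1, spec.n_records)
    p2 = rng.normal(spec.mu2, spec.cv2 * spec.mu2, spec.n_records)
    return _ratio(p1, p2, spec.mu2)


def write_trait_table(table: pd.DataFrame, path) -> None:
    """Write a trait table as TSV with header; missing parent coded 0."""
    table.to_csv(path, sep="\t", index=False, columns=TRAIT_COLUMNS)


def read_trait_table(path) -> pd.DataFrame:
    """Read a trait table TSV written by :func:`write_trait_table`."""
    return pd.read_csv(
        path,
        sep="\t",
        dtype={"id": np.int64, "sire_id": np.int64, "dam_id": np.int64},
    )
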