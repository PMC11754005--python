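"""Midparent–offspring estimation of heritability.

For unrelated, unselected parents the covariance between the midparent
phenotype m = (p_sire + p_dam)/2 and an offspring phenotype is ½σ_g², and
var(m) = ½σ_p². The estimator therefore returns

    σ̂_g² = 2·cov(m, o),   σ̂_p² = 2·var(m),   ĥ² = σ̂_g²/σ̂_p²

with sample (divide-by-n) covariance and variance over families. Applied
to a component trait it is unbiased for that trait's h²; applied to the
ratio trait p₀ = p₁/p₂ — where each parent contributes its own ratio
phenotype — it defines the ratio trait's realized heritability h₀².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["HeritabilityEstimate", "estimate_h2_parent_offspring"]


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Parent–offspring variance components and their ratio.

    ``h2`` is ``sigma2_g / sigma2_p`` exactly and is deliberately NOT
    clamped to [0, 1]: sampling noise can push a raw estimate outside the
    parametric range and downstream replicate averages need the raw value.
    """

    sigma2_g: float
    sigma2_p: float
    h2: float
    n_families: int


def estimate_h2_parent_offspring(
    parents: pd.DataFrame,
    offspring: pd.DataFrame,
    trait: str = "p0",
    per_offspring: bool = False,
) -> HeritabilityEstimate:
    """Estimate σ_g², σ_p² and h² of ``trait`` from midparent–offspring data.

    Parameters
    ----------
    parents, offspring
        Trait tables (see :mod:`ratiotrait.population`); every offspring's
        ``sire_id`` and ``dam_id`` must resolve to a parent row.
    trait
        Column to analyse: ``"p0"`` (ratio), ``"p1"`` or ``"p2"``.
    per_offspring
        If False (default), one pair per family: the midparent against the
        family mean of its offspring records. If True, each offspring
        record is paired with its midparent, so a family contributes
        ``offspring_per_dam`` pairs. The expectations coincide — only the
        sampling noise differs.
    """
    if trait not in ("p0", "p1", "p2"):
        raise ValueError(f"trait must be one of p0, p1, p2; got {trait!r}")
    parent_vals = pd.Series(
        parents[trait].to_numpy(), index=parents["id"].to_numpy()
    )
    sire_ids = offspring["sire_id"].to_numpy()
    dam_ids = offspring["dam_id"].to_numpy()
    for label, ids in (("sire", sire_ids), ("dam", dam_ids)):
        missing = ~np.isin(ids, parent_vals.index.to_numpy())
        if missing.any():
            bad = np.unique(ids[missing])[:5]
            raise ValueError(
                f"offspring reference {label} ids not present in parents: {bad}"
            )
    midparent = 0.5 * (
        parent_vals.loc[sire_ids].to_numpy() + parent_vals.loc[dam_ids].to_numpy()
    )
    o_vals = offspring[trait].to_numpy()

    if per_offspring:
        m, o = midparent, o_vals
        n_families = int(pd.unique(dam_ids).size)
    else:
        fam = pd.DataFrame({"dam_id": dam_ids, "m": midparent, "o": o_vals})
        grouped = fam.groupby("dam_id", sort=False).agg(m=("m", "first"), o=("o", "mean"))
        m = grouped["m"].to_numpy()
        o = grouped["o"].to_numpy()
        n_families = len(grouped)

    if n_families < 2:
        raise ValueError(f"need at least 2 families, got {n_families}")

    m_c = m - m.mean()
    o_c = o - o.mean()
    sigma2_g = 2.0 * float(np.mean(m_c * o_c))
    sigma2_p = 2.0 * float(np.mean(m_c * m_c))
    if sigma2_p <= 0:
        raise ValueError("midparent variance is zero; heritability undefined")
    return HeritabilityEstimate(
        sigma2_g=sigma2_g,
        sigma2_p=sigma2_p,
        h2=sigma2_g / sigma2_p,
        n_families=n_families,
    )
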