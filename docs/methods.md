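# Methods

## Model and assumptions

Two component traits are jointly normally distributed with phenotypic
decomposition p_j = μ_j + g_j + e_j. Additive-genetic effects (g₁, g₂) have
covariance matrix **G** with variances h_j²σ²_pj and correlation r_G;
environmental deviations (e₁, e₂) have matrix **E** with variances
(1 − h_j²)σ²_pj and correlation r_E; genetic and environmental effects are
mutually independent, so **P** = **G** + **E**. The ratio trait is
p₀ = p₁/p₂. The model is purely additive: no dominance, epistasis,
maternal effects, selection, or inbreeding.

Correlated pairs are generated through the lower Cholesky factors Lg, Le of
**G** and **E** applied to independent standard-normal deviates. The 2×2
factorization is done in closed form rather than via `numpy.linalg.cholesky`
because positive *semi*definite matrices are legitimate inputs (a trait
with h² = 0 has zero genetic variance), and the library routine rejects
singular matrices; the closed form also lets error messages name the
offending matrix.

## Two-generation simulation

The base generation (G0) consists of `n_sires` males and
`n_sires × dams_per_sire` females, unrelated, unselected and non-inbred,
with (g₁, g₂) ~ N(0, **G**) i.i.d. Each sire is mated to a block of
`dams_per_sire` dams (dams shuffled under the run seed, then partitioned
deterministically — monogamous dams, no polyandry); each dam produces
`offspring_per_dam` full sibs. Offspring breeding values are

    g₁ = (g_s1 + g_d1)/2 + √0.5 · Lg₁₁ z₁
    g₂ = (g_s2 + g_d2)/2 + √0.5 · (Lg₂₁ z₁ + Lg₂₂ z₂)

The **√0.5 Mendelian-sampling scale** is a deliberate choice: it gives the
within-family deviation covariance ½**G** which, added to the ½**G**
variance of the midparent mean, keeps G1 genetic variance equal to G0's
for non-inbred, unselected parents. A literal 0.5 scale would shrink
genetic variance by a quarter per generation and bias every downstream
heritability estimate; it is intentionally not supported.

G1 phenotypes are p_j = μ_j + g_j + (Le z)_j; the trait mean is included in
both generations so the ratio trait is centered near μ₁/μ₂ in each.

**Near-zero denominators.** The ratio is computed as-is, with no truncation
or rejection — truncation would bias the moments. At the default setting
(μ₂ = 10 phenotypic SDs from zero) a non-positive denominator has
probability below 10⁻²³; a warning is logged if any |p₂| < 10⁻⁶·|μ₂|.

**Reproducibility.** Each generation draws from an independent
`numpy` SeedSequence stream derived from `design.seed`; grid experiments
derive one stream per (base seed, experiment, cell, replicate), so results
are independent of evaluation order and a given configuration is
bit-reproducible.

## Independent-record generator

For distribution studies divorced from pedigree structure, p₁ and p₂ are
drawn independently as N(μ_j, (CV_j·μ_j)²) and the ratio returned. This
emulates single uncorrelated phenotypic records only: no genetic
structure, no covariance between numerator and denominator. The
default mean-ratio grid is the seven reciprocal pairs {10/25, 10/20,
10/15, 10/10, 15/10, 20/10, 25/10}, spanning ratios from 0.4 to 2.5.

## Moment summaries

`moment_summary` reports mean, variance, skewness and kurtosis using
population (divide-by-n) central moments with no small-sample bias
correction — samples of interest are ≥ 10⁴ records, where the corrections
are negligible. Kurtosis is reported as **excess** kurtosis so a normal
sample scores 0, making the normality baseline directly testable. Samples
shorter than 4 or with zero variance are rejected.

## Heritability estimation

For each full-sib family, the midparent value m = (p_sire + p_dam)/2 is
paired with the offspring value o. With unrelated parents,
cov(m, o) = ½σ²_g and var(m) = ½σ²_p, so

    σ̂²_g = 2·cov(m, o),   σ̂²_p = 2·var(m),   ĥ² = σ̂²_g / σ̂²_p

with divide-by-n sample statistics over families. By default o is the
family mean of the offspring records: the covariance expectation is
unchanged (cov(m, mean of sibs) = ½σ²_g) while the estimator noise drops;
a `per_offspring` flag instead pairs every offspring record with its
midparent for sensitivity analysis — the two modes agree in expectation
and share var(m) exactly. For the ratio trait each parent contributes its
*own* ratio phenotype p₁/p₂ (not the ratio of midparent components).
Estimates are deliberately not clamped to [0, 1]; replicate averaging
needs the raw values.

## Delta-method closed forms

Second-order Taylor expansion of p₁/p₂ around (μ₁, μ₂) gives

    E(p₀)  ≈ μ₁/μ₂ − cov(p₁,p₂)/μ₂² + μ₁σ²_p2/μ₂³
    var(p₀) ≈ σ²_p1/μ₂² + μ₁²σ²_p2/μ₂⁴ − 2μ₁cov(p₁,p₂)/μ₂³

with cov(p₁,p₂) = [r_G h₁h₂ + r_E √((1−h₁²)(1−h₂²))]·σ_p1σ_p2 (the
unit-variance formula generalized by σ_p1σ_p2, forced by dimensional
analysis). The expansion is accurate in the small-CV regime (CV₂ ≲ 0.1,
within ~10% on the variance); the discrepancy grows with CV₂ because the
quotient's heavy right tail is invisible to a second-order expansion.

The heritability approximation applies the same variance expansion to the
breeding-value ratio g₁/g₂ around assumed means (E(g₁), E(g₂)) and divides
by the phenotypic delta variance. Breeding value is a relative scale, so
the offsets are explicit user inputs defaulting to (μ₁, μ₂) rather than a
hard-coded choice. The monotonicity claims — h₀² falls as r_G rises and
rises with r_E — are treated as grid-checked properties of the general
expression, not theorems, and are asserted over the full 81-point
parameter grid in the tests.

## Experiment grids and problem sizes

Experiment drivers replicate each grid cell with independent streams and
report the mean and divide-by-n SD across replicates (so a single
replicate yields SD 0). The default profile is **desk scale**: 2,000
sires × 10 dams × 2 offspring (20,000 families, 40,000 G1 records),
100,000 independent records, 20 replicates per cell. At this size the
replicate means of ĥ₀² reproduce full-scale expectations to about ±0.02
and the G1 ratio-trait variance to ±0.01, while a full 81-cell sweep runs
in minutes on one CPU. The full-size profile — 100,000 sires (2,000,000
G1 records), 2,000,000 independent records, 100 replicates — is available
via `ExperimentConfig.full_scale()`; its per-cell SDs are ~√50 smaller
but the means agree with desk scale in expectation. The ratio-trait
variance is additionally reported ×10 (`variance_x10`), a convenient
scale for plotting it alongside the other moments.

## What the generator does and does not emulate

Passing tests show that the machinery reproduces the distributional and
heritability behaviour of ratio traits *under the stated model*: bivariate
normal components, additive inheritance, balanced nested mating, equal
family sizes, no selection. Real livestock data depart from this in known
ways — non-normal components, unbalanced pedigrees, selection and
assortative mating, common-environment (litter) effects inflating full-sib
resemblance, measurement error correlated between numerator and
denominator (e.g., both derived from the same weighing). None of these are
modelled; conclusions about real populations require the usual caution.

## Known limitations

* Two generations only; no selection response, no inbreeding accumulation.
* The parent–offspring estimator assumes unrelated, non-inbred parents;
  it is not a REML/animal-model substitute and reports no standard error
  for a single replicate (uncertainty is the SD across replicates).
* The exact density of a ratio of correlated normals (Hinkley's formula)
  is deliberately out of scope; the delta method plus simulation covers
  the regimes of interest.
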