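# Methods

## Rate decomposition and the trio regression

The package models each trio's corrected de novo mutation count U as
Poisson with mean 2L·(μ_E + μ_OS·Ā), where L is the callable haploid
genome length, μ_E the prepuberty load per site per generation, μ_OS =
μ_O + μ_S the postpuberty germ-cell rate per site per year, and Ā =
ρ·A_P + (1−ρ)·A_M − P the sperm-fraction-weighted parental displacement
from the age of puberty P. Counts are accepted as reals because source
studies scale raw calls by multiplicative false-positive/false-negative
corrections; the likelihood's factorial term uses the continuous
extension lgamma(U+1), which is constant in the parameters and therefore
does not move the maximizer.

The additive mean makes this an identity-link Poisson regression with
exposure, which canned GLM implementations handle unreliably (the
canonical log link is the default and identity-link fits are not
guaranteed to respect mean positivity). The fit is therefore a direct
damped Newton maximization over (μ_E, μ_OS) with line-search steps
constrained to keep μ_E ≥ 0 and every fitted mean positive. The
log-likelihood is concave in the parameters (means are linear in them),
so Newton from a weighted-least-squares start converges in a handful of
iterations; Newton steps are affine-invariant, so the per-site 1e-9
scale of the parameters needs no rescaling. If the intercept is driven
to zero the fit pins it there and re-solves the one-dimensional slope
problem (boundary flagged). The all-zero-count dataset returns the
boundary point (0, 0).

McFadden's pseudo-R² is 1 − ℓ/ℓ₀ against the intercept-only
identity-link fit with the same exposures (closed form μ_E = ΣU/Σ2L);
with the lgamma normalizer both log-likelihoods are negative and the
statistic lies in [0, 1) whenever the alternative nests the null.

Negative Ā values (reproduction before the nominal species-level P) are
allowed with a warning rather than clamped: P is a species-level
approximation, and the fit itself guards against nonpositive means.

Uncertainty: nonparametric bootstrap over trios (default B = 1000),
percentile 95% intervals. Percentile rather than BCa because the
estimator is smooth in the resampled empirical measure and the intervals
are only used descriptively; unfittable resamples (no age variation) are
redrawn and counted. The characteristic anticorrelation between the
bootstrap draws of μ_E and μ_OS is the usual intercept/slope trade-off
of a shared regression.

Batch effects across source datasets are tested by a likelihood-ratio
chi-square comparing a pooled fit against per-dataset (μ_E, μ_OS) pairs,
df = 2(K−1). This realizes the categorical-source-with-interaction
ANOVA as a deviance test; the identity link is retained in both models
for consistency with the mean structure above.

## Sex-specific parameters and the sperm fraction

The phased-count likelihood is maximized over (μ_E,M, μ_E,P, μ_S, μ_O)
on the per-genome scale, exactly as the likelihood is written — it
carries no genome-length factor. Per-trio heterogeneity in L is
harmonized by scaling each trio's expected loads by L_i/L_ref, with
L_ref defaulting to the mean callable length; reported per-site values
divide by L_ref. Optimization is quasi-Newton (L-BFGS-B) on log
parameters with a floor of 1e-12 expected mutations per genome, five
multi-starts (one moment-based, four perturbed) seeded by
`random_state`; parameters ending within 10× the floor are flagged as
boundary estimates. Nonpositive expected loads paired with positive
counts evaluate to −∞ rather than raising, so the optimizer can back
away. Datasets with no phased mutations raise; the documented fallback
is the large-human-pedigree sperm fraction ρ = 0.75.

The grid-search alternative scans ρ over [0, 1] (step 0.01), refits the
Poisson regression at each ρ and reports the pseudo-R²-maximizing value
(ties to the smallest ρ). When paternal and maternal ages coincide in
every trio the curve is flat and a `no_power` flag is set.

## PGLS with Pagel's λ

The Brownian tip covariance C has C[i,j] = depth of the most recent
common ancestor of i and j from the root, built in one postorder
traversal. Pagel's λ multiplies off-diagonal entries only, profiled
over [0, 1] by a 101-point grid plus bounded refinement (xatol 1e-6);
values outside [0, 1] are not considered. Estimation is ML, not REML,
for both λ and σ². Conditional on λ̂, the slope's p-value is a t test
with n−2 degrees of freedom using the bias-corrected residual variance
σ̂²·n/(n−2); uncertainty in λ̂ itself is not propagated. Exact linear
relations give σ̂² = 0 and are reported with a `degenerate` flag, the
slope exact and the p-value at the floating-point minimum.

All cross-species regressions run on log10-transformed variables —
generation times and rate estimates are closer to lognormal than normal
— so slopes are base-invariant and intercepts are reported in base 10.

## Longevity models

The fixed-rate model μ(g) = μ_E,ref + span·μ_OS,ref supports both the
puberty-fraction span g·(1−p) (used for extrapolation curves) and the
explicit-P span g − P_ref (used with species-specific parameters); both
parameterizations exist because both are natural depending on whether a
reference species' P or the cross-species constant p is trusted. The
variable-rate model is μ(g) = μ_E(1)·g^α + (1−p)·μ_OS(1)·g^(β+1), with
α, β and the unit-generation-time intercepts taken from the PGLS fits.
The puberty fraction defaults to p = 0.42; `fit_puberty_fraction`
re-estimates it as the through-origin slope of P on g (the relationship
is summarized as a pure proportionality; the with-intercept fit is
returned as a diagnostic). Model families are compared by mean squared
log10 error of predicted versus observed μ over a species panel.

Species with several independent datasets (olive baboon, aye-aye) enter
any cross-species fit through exactly one row, selected by a source
preference defaulting to the Wang et al. calls — the source whose
pipeline also produced the cat, owl monkey and one rhesus dataset,
maximizing pipeline consistency. Pooled rows (human, rhesus) are single
rows already.

## Drift-barrier calculus

Thresholds follow from S > 1/(2N_e): U* = 1/(2 N_e E[s]) for
nonclocklike mutators and k* = 1/(2 g N_e (1−p) E[s]) for clocklike
ones, reading the threshold expressions with all factors in the
denominator, consistent with the S(U) > 1/(2N_e) criterion they derive
from. E[s] is a user-supplied scalar — it is not estimable from the
data this package consumes — so g·N_e curves are emitted in arbitrary
units with the proportionality constant factored out. N_e = π/(4μ).

## Synthetic data

`simulate_trios` draws maternal counts as Poisson(L·(μ_E,M + μ_O·(A_M−P)))
and paternal counts analogously, with per-site per-haploid-genome rates,
then phases each mutation to its true parent with probability φ
(Bernoulli thinning, the structure the phased likelihood consumes). The
total count then has the diploid 2L regression form with intercept
(μ_E,M+μ_E,P)/2 and slope (μ_S+μ_O)/2, exposed as `mu_E_regression` /
`mu_OS_regression` on the config. Defaults emulate a large human pedigree
study: rates equivalent to μ_E = 6.6e-9 per generation and μ_OS =
3.63e-10 per year on the regression scale with ρ = 0.75, P = 13 y,
paternal ages uniform on 18–45 and maternal on 18–42, L = 2.68 Gb, and
φ = 0.3 (roughly the fraction of DNMs that read-backed or transmission
phasing resolves in practice). φ is free because source studies differ
widely in phasing completeness.

`simulate_yule_tree` builds ultrametric pure-birth trees by forward
simulation. `simulate_trait_panel` evolves log10 g by Brownian motion
on the λ-attenuated tree covariance (normalized to unit depth so sigmas
are tip-level SDs), places log10 μ_E and log10 μ_OS on exact power laws
of g plus Brownian residuals, assembles μ through the decomposition
identity with P = p·g, and constructs π so that log N_e = γ·log g +
const holds exactly (plus optional noise).

What the generators do not emulate: overdispersion beyond Poisson
(family-specific mutation rate variation), phasing biases correlated
with parental origin, measurement error in parental ages or L,
correlated sampling of trios within pedigrees, and tree misspecification.
Passing recovery tests therefore demonstrate estimator correctness and
calibration under the assumed model, not robustness to these real-data
features.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the tolerances tested: 50 replicates for parameter-recovery
checks (assertions at 3 MC standard errors of the replicate mean), 200
replicates × B = 300 bootstrap draws for interval coverage (nominal 95%
coverage asserted within [90%, 99%]), 100 replicates for the batch-test
power check, and 64-tip trees for PGLS recovery. Week-to-year age
conversion uses 52.1775 (mean Gregorian weeks per year). Numeric trio
fields round-trip through TSV at 12 significant digits.

## Known limitations

- The packaged 8-taxon chronogram is an approximate stand-in assembled
  from consensus divergence times; PGLS λ and p-values on the packaged
  panel depend mildly on it, though the scaling-law signs are stable.
- The sex-specific likelihood treats phasing as missing completely at
  random; parent-of-origin-biased phasing would bias ρ.
- No overdispersion modeling: standard errors from the Poisson model are
  anticonservative if family effects are present (bootstrap intervals
  partially absorb this).
- λ is profiled on [0, 1] only, and slope inference conditions on λ̂.
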