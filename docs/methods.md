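# Methods

This note documents the models, the numerical choices, and the limits of
what the test suite demonstrates.

## Trait aggregation and classification

Literature-style report tables (one row per report) are collapsed to
species medians; a species' fecundity is the product of its median clutch
size and median clutch frequency, defined only when both traits have data.
Species fall into four latitudinal classes from the median and span of
their report latitudes relative to ±23.5°: Tropical (whole range within the
tropics), Temperate (whole range outside), and the two mixed classes
decided by the side of the median (Temp-trop, Trop-temp).  The binary zone
coarsens these by the median's side: {Temperate, Temp-trop} → temperate,
{Trop-temp, Tropical} → tropical.  Latitude enters all regressions as
|latitude| (distance from the equator): the life-history gradient is
equatorial–polar, not north–south, and the per-class latitude summaries
this mirrors are positive medians.

With CSV-only input the latitudinal range of a species is necessarily the
range of its report locations; compilations that augment ranges from
occurrence databases will classify borderline species differently.  Range
provenance is an input responsibility here.

## Random-intercept trait regression

The model is `y = Xβ + Zb + ε` with `b ~ N(0, σ²_b I)` over taxonomic
families and Gaussian residuals — equivalently, ridge-penalized family
indicator columns whose penalty 1/θ (θ = σ²_b/σ²_e) is chosen by REML.
Numerics:

- θ is profiled by `scipy.optimize.minimize_scalar` (bounded, xatol 1e-8)
  on ln θ over [−12, 12]; a solution pinned at the lower bound is treated
  as θ = 0 (no family variance), which reduces the fit exactly to OLS.
  The profiled criterion is `log|V| + log|XᵀV⁻¹X| + (n−p) log(rᵀV⁻¹r)` with
  `V = I + θZZᵀ` (Cholesky).  This 1-D profile search proved more robust
  than general-purpose gradient optimizers on these data: the test suite
  cross-checks against statsmodels' MixedLM, which needs its Powell
  fallback to agree on some replicates.
- The random term's effective degrees of freedom are
  `tr(C(CᵀC+P)⁻¹Cᵀ) − p` for `C = [X Z]` with the penalty on the Z block —
  0 at θ = 0, approaching (number of families − 1) as θ → ∞.
- Coefficients are standardized: the transformed response and all
  continuous covariates are centered and scaled to unit SD; 0/1 class
  contrasts stay unscaled with Temperate as the reference level.  Class
  contrasts for levels absent from a trait's subset are dropped.
- Survival is arcsin(√x)-transformed by default; plain arcsin(x) is a
  config option since "arcsine transformed" is ambiguous in parts of the
  comparative literature.  All other traits and carapace length are
  ln-transformed.
- AICc uses the Gaussian ML log-likelihood at the REML variance ratio with
  `k = (fixed coefficients) + (random-term edf) + 1` for the residual
  variance.  Because edf accounting differs across software, absolute AICc
  values are not comparable across implementations; ranks and weights are.
- Model-averaged predictions renormalize the Akaike weights of the 95%
  confidence set, include the family BLUP when the species' family was in
  the trait's training subset (zero otherwise, with a warning), and
  back-transform without smearing corrections — downstream use takes
  medians of predictions, which are order-preserving.

## Stage-structured demography

Three stages: egg (duration 1 yr, survival 0.2 by default — nest and
hatchling data are too sparse to estimate zone-specific values), juvenile,
and a terminal adult stage.  Stay/advance probabilities follow the
stationary age-within-stage equations; `P + G = p` is an algebraic
identity and is property-tested.  Near p = 1 the 0/0 forms are replaced by
their continuous limits (P → p(d−1)/d, G → p/d) within 1e-9 of the pole.
Non-integer durations are accepted verbatim (zone-median maturities are
non-integer).  Juvenile survival is 13% less than adult survival.

The dominant eigenpair is computed two independent ways: power iteration
on A and Aᵀ (tolerance 1e-12, the reference implementation) and the
largest real root of the characteristic cubic
`λ³ − (P1+P2)λ² + P1P2λ − FG1G2` (used in sweeps, where it is ~50× faster).
The two agree to 1e-10 over thousands of random matrices in the tests.
r is defined as ln λ; every threshold statement depends only on
sign(λ − 1), so the continuous/discrete-rate distinction never changes a
conclusion.

### Unstated conventions

Three modelling choices are genuinely open, and published tables of this
kind do not pin them down; `ConventionFlags` makes each explicit:

- `d_juv_includes_egg` (default True): maturation age counts the year in
  the egg, so d_juv = maturity − 1.
- `female_fraction` (default 0.5): a female-only model with an even
  primary sex ratio halves fecundity in the matrix.
- `couple_juvenile` (default True): the 13% rule is a derivation rule, so
  juvenile survival tracks adult survival when the latter is swept or
  resampled.  This flag affects only adult-focal sweeps; a juvenile-focal
  sweep always varies p_juv directly.

`convention_search` evaluates all 8 combinations against the packaged
reference elasticity/threshold tables and reports per-cell residuals.  On
those tables the closest combination is {d_juv = maturity−1,
female_fraction = 1.0, coupled}; no combination reproduces every printed
cell, which is why elasticity and r-min cells are covered by the
diagnostic plus property tests rather than exact assertions.  Notably,
under female_fraction = 0.5 the reference predicted inputs imply λ < 1 in
both zones, which would make the printed positive harvest margins
impossible — evidence that the source synthesis did not halve fecundity in
the matrix despite describing a female-only model.

## Harvest thresholds and uncertainty

`r_min` brackets the λ = 1 crossing by bisection (tolerance 1e-6 on the
parameter; |r| < 1e-5 at the returned value), validated in tests against
the closed-form boundary `FG1G2 = (1−P1)(1−P2)`.  "No finite threshold" is
a reported outcome, not an exception.  Margins are rounded to the nearest
integer, half away from zero, for reporting.

Jackknife bands redraw fecundity and adult survival (juvenile derived by
the 13% rule; egg fixed at 0.2) uniformly from the [2.5th, 97.5th]
percentile range of zone species values — the published procedure states
the range but not the shape, so uniform is the default and all parameters
are drawn jointly per iteration.  The focal parameter is never resampled:
bands express uncertainty in the parameters held constant.  Prediction
bands are pointwise 2.5/97.5 percentiles of 500 r draws; confidence bands
are mean ± 1.96 SD/√n_iter.  Stage durations are not resampled, matching
the stated procedure's parameter list.

## Synthetic data

The generator emulates a literature compilation of ~165 species in 12
families with ~2.8 reports per species (~460 reports): skewed family
sizes, signed latitudes over [−40, 55] mixing a northern-temperate mode, a
southern mode and a tropical block (roughly even zone split), bio10 linear
in |latitude| with noise tuned to |Spearman| ≈ 0.4 (negative slope —
warmer summers toward the equator), bio17 near-independent (≈ 0.04), and
carapace length independent of all model covariates (|r| < 0.25).  Traits
are built on their transformed scale as
`center + scale·(β·z + family intercept + residual)` with standardized
covariates and the residual SD chosen so the latent variance is 1 — the
configured effects (defaults: latitude +0.13 on ln clutch size, −0.09 on
ln clutch frequency, +0.06 on ln maturity, +0.04 on arcsin√ survival;
carapace 0.29/0.01/0.09/0.01) are therefore standardized coefficients by
construction.  Species-level missingness thins traits to expected counts
of 165/102/75/37.  Reports add small transformed-scale noise (SD 0.08,
a config knob — within-species report variance is not documented in the
sources this emulates) that median aggregation removes.

What the generator does *not* emulate: spatial clustering of study effort,
within-species covariance between traits, family-structured missingness,
or measurement conventions that differ between studies.  In particular,
because clutch size and clutch frequency are generated with symmetric
log-scale noise, the species-level fecundity median is the product of the
marginal medians (~16 eggs·yr⁻¹) — roughly twice the value real
compilations show, where frequency data concentrate in particular
families.  Passing recovery tests therefore demonstrate estimator
correctness under the assumed generative structure, not robustness to
these real-data pathologies.

## Problem sizes in the tests

The acceptance suite uses 50 fixed-seed replicates for parameter recovery
(n = 165 species each), 10⁴ random (p, d) pairs for the P+G identity, 10³
random matrices for the eigen/elasticity properties, and a 25-point sweep
grid without jackknife for the qualitative pipeline check; the acceptance
script uses a 100-point grid with 300 jackknife iterations.  These sizes
keep the whole suite under a minute while leaving every statistical margin
wide (coverage thresholds are crossed by several replicates, not one).
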