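# turtleharvest

Can freshwater turtles — temperate or tropical — sustain harvest?  This
package answers the question the way conservation demographers do: it
synthesizes life-history traits (clutch size, clutch frequency, age at
sexual maturity, annual adult survival) across turtle species, models their
latitudinal and climatic gradients, folds the zone-level trait medians into
a stage-structured matrix population model, and measures how far each
demographic parameter can be reduced before the population starts to
decline.  It is aimed at population ecologists and conservation planners
who need reference harvest margins for data-poor, long-lived species.

## The models

**Trait regression.**  Species are the replicates (report-level values are
collapsed to species medians).  For each trait, four candidate Gaussian
models are fitted on the transformed scale (natural log; arcsin√ for
survival): one focal term — continuous |latitude|, a four-level latitudinal
class factor, bio10 (mean temperature of the warmest quarter) or bio17
(precipitation of the driest quarter) — plus ln carapace length and a
taxonomic-family random intercept.  The random intercept is ridge-penalized
family indicators with REML-chosen penalty: the variance ratio
σ²_family/σ²_resid is profiled by a bounded 1-D search, fixed effects are
GLS at the optimum, and the random term's effective degrees of freedom are
the trace of its shrinkage projector.  Models are ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) define a 95% confidence set over which
per-species predictions are weight-averaged.

**Demography.**  A three-stage (egg, juvenile, adult) Lefkovitch matrix

```
A = | 0   0   F  |
    | G1  P1  0  |
    | 0   G2  P2 |
```

with stationary age-within-stage parameters from annual survival p and
stage duration d:

```
P = p (1 − p^(d−1)) / (1 − p^d)        G = p^d (1 − p) / (1 − p^d)
```

(P + G = p identically).  Juvenile survival follows the 13%-less rule
(p_juv = 0.87 p_adult), egg survival defaults to 0.2 over a one-year egg
stage, and the adult stage is terminal (P2 = p_adult).  The dominant
eigenvalue λ gives the intrinsic rate r = ln λ; elasticities
e_ij = (a_ij/λ) v_i w_j / ⟨v,w⟩ apportion λ among the five labeled vital
rates and sum to 1, with the single reproductive loop forcing
e(F) = e(G1) = e(G2).

**Harvest thresholds.**  For each parameter, bisection on the monotone map
parameter → r finds the λ = 1 threshold (equivalently
F·G1·G2 = (1−P1)(1−P2)); the percent margin is
100 (predicted − threshold)/predicted.  Jackknife randomizations redraw the
non-focal parameters from the 95% range of species-level values to put
confidence and prediction bands around each swept r-curve.

Because the published syntheses this mirrors leave a few conventions
unstated (does maturation age include the egg year? is fecundity halved for
the female fraction? is juvenile survival re-derived when adult survival is
swept?), a `convention_search` diagnostic evaluates all eight combinations
against the packaged reference tables and reports per-cell residuals.

## Worked example

```python
from turtleharvest import (ConventionFlags, DemographicParams, build_matrix,
                           eigen_analysis, elasticities, zone_margins)

conv = ConventionFlags(female_fraction=1.0)
params = DemographicParams.from_traits(
    p_adult=0.857, age_maturity=8.6, fecundity=7.3, conventions=conv
)
A = build_matrix(params, conv)
es = eigen_analysis(A)
el = elasticities(A)
print(f"lambda = {es.lam:.4f}   r = {es.r:.4f}")
print(f"stable stage distribution w = {es.w.round(3)}")
for name, value in el.as_dict().items():
    print(f"elasticity {name:18s} {value:.3f}")
hm = zone_margins(params, conv)
for focal in hm.margin_percent:
    print(f"{focal:18s} predicted {hm.predicted[focal]:.3f}  "
          f"r_min {hm.threshold[focal]:.3f}  margin {hm.margin_percent[focal]}%")
```

prints

```
lambda = 1.0082   r = 0.0082
stable stage distribution w = [0.549 0.375 0.076]
elasticity Egg survival       0.090
elasticity Juvenile P         0.220
elasticity Juvenile G         0.090
elasticity Adult survival     0.510
elasticity Annual fecundity   0.090
egg_survival       predicted 0.200  r_min 0.182  margin 9%
juvenile_survival  predicted 0.746  r_min 0.737  margin 1%
adult_survival     predicted 0.857  r_min 0.851  margin 1%
fecundity          predicted 7.300  r_min 6.657  margin 9%
```

These are reference temperate-zone inputs (adult survival 0.857, maturity
8.6 yr, fecundity 7.3 eggs·female⁻¹·yr⁻¹).  The population barely grows
(r ≈ 0.008); adult survival dominates the elasticities (0.51, more than
double the juvenile stay entry), so the adult stage carries almost no
harvest headroom (1%), while egg survival and fecundity could absorb ~9%
reductions.  That asymmetry — early stages harvestable, adults not — is the
package's central output.

The full pipeline (synthetic or user-supplied trait table → species
aggregation → model selection → demography → harvest) runs as

```
turtleharvest all --seed 1 --outdir out/
```

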