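# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `tidalcarbon`.

## Core standardization

Raw cores report arbitrary depth intervals with dry bulk density (BD,
g cm⁻³), loss-on-ignition organic-matter fraction (OM) and, sometimes,
measured organic-carbon fraction (OC). Profiles are discretized to 1-cm
cells and averaged within half-open 10-cm slabs [k·10, k·10+10) down to
1 m. If the deepest sample covers more than half of its terminal slab
(> 5 cm), its values are carried to the slab bottom and the slab is
flagged `extrapolated`; at ≤ 50% coverage with no other data the slab is
no-data. Carry-forward (rather than a trend extrapolation) is used because
nothing below the last sample constrains a trend; the flag lets users drop
extrapolated slabs.

OC is derived from OM with a quadratic calibration
OC = a·OM² + b·OM + c. The default coefficients are
(0.074, 0.421, −0.0080). The linear term is the deliberate design choice:
with a Craft-style linear coefficient near 0.4, OC(1) ≈ 0.487 and the
organic carbon-density ceiling k1·OC(1) ≈ 0.048 gC cm⁻³ is internally
consistent with the mixing model below; a variant set with linear term
0.0421 is available through the `coeffs` argument and covered by a
regression test. The polynomial is clipped to [0, 1] because it is
(unphysically) negative below OM ≈ 0.018. When OM is present, OC is always
recomputed from the calibration even if a measured OC exists — syntheses
mix OC methods across labs, and a single conversion keeps carbon densities
comparable; measured OC is used only when OM is absent. Carbon density is
BD × OC (gC cm⁻³; × 1000 = kgC m⁻³).

The carbon-density distribution is summarized by sample mean and s.d.
with a truncated-normal (support [0, ∞)) maximum-likelihood fit for shape
comparison against a log-normal alternative. For the log-normal fit only,
exact zeros are recast to 1e-5 gC cm⁻³ (0.01 kgC m⁻³), treating them as
below detection; zeros are not recast for the reported moments.

## Mixing model and threshold

BD(OM) = 1/(OM/k1 + (1−OM)/k2) is fitted by nonlinear least squares,
initialized at (0.1, 1.5) g cm⁻³ (physically motivated, near literature
values) with positivity bounds. Uncertainty comes from a case-resampling
bootstrap (default 1000 iterations, percentile 95% CIs); case resampling
rather than residual resampling because field data are heteroscedastic.
The organic-matter-density model OMD = OM·BD(OM) is an algebraic identity
on the same parameters.

The organic/mineral threshold is the breakpoint of a continuous
two-segment linear model of carbon density on OM, found by exhaustive grid
search over OM ∈ [0.02, 0.90] in steps of 0.001 (ties broken toward
smaller OM; the suffix-sum implementation solves all 881 normal-equation
systems in one vectorized pass). A case-resampling bootstrap gives the
breakpoint CI. If the SSE is minimized at a grid boundary the fit refuses
— single-segment data have no interior breakpoint. Classification R²
(one-way variance explained by the binary organic/mineral factor) is
reported at the fitted breakpoint and at the conventional 20% and 35%
thresholds. Threshold detection operates on slab-level records.

## Mixed-effects models

Carbon density at the increment level is modeled with categorical fixed
effects — climate zone (4 levels), salinity×vegetation class (4 levels +
unknown), soil class (organic/mineral at the 13.2% OM threshold), and
depth as a 10-level increment factor — plus a random submitter intercept
absorbing lab-level bias. Models are fitted by maximum likelihood (not
REML) so AICc is comparable across fixed structures; `dredge_models`
enumerates every subset of the candidate terms respecting marginality
(interactions only with their margins present) and ranks by AICc with
Akaike weights, refusing more than 2¹² structures. AICc uses
k = (fixed coefficients) + 2 (random-intercept variance and residual
variance). Design columns made collinear by empty interaction cells are
pruned by pivoted QR before fitting; predictions reuse the stored design
information, so fixed-effects-only prediction (`predict_fixed`, random
intercept = 0) is identical for seen and unseen submitters.

Effect sizes are adjusted ω² = (SS − df·MS_err)/(SS_total + MS_err)
computed from a Type-III ANOVA with sum-to-zero coding on the
fixed-effects design, with the random intercept profiled out; this is an
approximation to a full mixed-model decomposition, and with empty
interaction cells it falls back to Type II. Variance explained is
summarized by Nakagawa–Schielzeth marginal and conditional pseudo-R². The
random intercept s.d. is also reported standardized by the
calibration-set carbon-density s.d. (σ_c units).

## Soil-map emulation and bias correction

Soil maps follow the map-unit → component (percent share) → horizon
hierarchy. Horizons aggregate to slabs by the same 1-cm discretization;
where BD is present but OM missing, OM is taken as 0, and where BD is
missing the span is no-data. Map-unit values are component-percent
weighted means over hydric components, with weights renormalized over the
components that have data in each slab; zero-percent components are
ignored. Rock-fragment corrections are not applied (not relevant to tidal
wetland soils). Map carbon density uses the van Bemmelen factor
(0.58 gOC/gOM) — deliberately different from the empirical quadratic,
because that is the convention for soil-survey data. Classification is
organic iff OM strictly exceeds 0.132 (the boundary value itself is
mineral), scored by user's/producer's/total accuracy.

Bias correction re-expresses each mapped point as a standardized residual
about the map's own fitted mixing curve (r* = r/σ_map; defined as 0 when
σ_map = 0) and re-scales it onto the empirical calibration curve:
CBD = BD̂_cal(OM) + r*·σ_cal. The corrected values therefore mimic the
calibration mean and spread while preserving the map's anomaly pattern;
corrected values below zero are assigned the minimum pre-correction map
BD. σ here is the s.d. of mixing-model residuals (not of carbon density —
the two uses of the same symbol in the literature collide; the residual
meaning is the operative one).

## Skill metrics

All scores are normalized by the reference s.d.: B* = (μₘ−μᵣ)/σᵣ,
σ* = σₘ/σᵣ, RMSE*' = √(1 + σ*² − 2σ*R), RMSE* = √(RMSE*'² + B*²). The
sign in RMSE*' is negative: the positive-sign variant sometimes printed in
the literature violates the perfect-model identity (a model equal to its
reference would score RMSE*' = 2 instead of 0), and the identity is
asserted in the tests. Standard deviations use the population denominator
n, consistent with the 1/n covariance in R; whether n or n−1 was used in
the original target-diagram applications is not determinable, and the
choice is invisible after normalization at these sample sizes. A constant
strategy (the reference-mean baseline) has σ* = 0 and R defined as 0, so
RMSE* = 1 exactly — the baseline every strategy must beat. A strategy is
*accurate* if |B*| < 1 in every populated slab and *precise* if
RMSE*' < 1 in every slab.

## Stock accounting

total [Pg] = density [kgC m⁻³] × depth [m] × area [ha] × 10⁴/10¹².
Scenario tables report densities to 1 decimal and totals to 2 decimals
alongside unrounded values, and leave cells blank where a strategy has no
map coverage. Climate zones follow the U.S. GHG-inventory rules
(mediterranean: California south of 40°; subtropical: Gulf coast and
Atlantic below 30°; temperate warm: Atlantic 30–40°; temperate cool:
Pacific or Atlantic at/above 40°); boundary latitudes go to the cooler
class because "south of" is strict.

## Synthetic data: what it emulates, and what it does not

The generator emulates a large CONUS core synthesis: 1959 cores dominated
by estuarine emergent wetlands (class mix 1533/157/46/87/134, normalized
over the 1957 classified cores), exponential core lengths with mean 55 cm,
and reporting patterns (≈69% OM only, 24% OM+OC, 7% OC only). Each core is
organic- or mineral-dominated (organic fraction 0.47); mineral cores draw
a mean OM from a truncated normal TN(0.076, 0.03) on [0, 0.132] and
organic cores from TN(0.40, 0.10) on (0.132, 1], with within-core OM s.d.
0.02. BD is the mixing curve at OM (k1 = 0.098, k2 = 1.67 g cm⁻³) plus
N(0, 0.02) noise, floored at 0.01 g cm⁻³ for positivity. These mixture
parameters were calibrated once, by simulation, so the implied increment
carbon density matches the emulation targets (mean 0.027, s.d.
0.013 gC cm⁻³); they are fixed defaults, not fitting knobs.

The submitter random intercept (s.d. 6.24e-3 gC cm⁻³ across 49
submitters) is applied as an additive carbon-density offset, realized as a
BD shift of u/max(OC(OM), 0.05): exact in carbon-density units wherever
OC ≥ 0.05 (all organic soils) and damped in nearly carbon-free mineral
soils, where an exact offset would require unbounded BD shifts.

The map generator emulates soil-survey structure (1–3 components per unit
with integer percents summing to 100, horizons tiling 0–100 cm, ~5%
missing OM and ~3% missing BD) and two documented failure modes: an
inflated organic self-packing density (`k1_map_bias`, default 2.7×, which
reproduces mapped k1 ≈ 0.26 g cm⁻³ when truth is 0.098) and random soil-
class flips (`misclassification_rate`, default 0.232, giving ≈77% total
map accuracy).

What the generator does **not** emulate: spatial autocorrelation and
geography (classes are assigned, not mapped), depth trends in OM/BD (real
profiles compact downcore; generated cores are depth-stationary, so
per-slab fits differ only by sampling noise), method-specific measurement
error structure beyond a single Gaussian BD noise, carbonate interference
in organic-carbon measurements, and non-additive (karstic) soils. Passing
tests therefore demonstrate the correctness of the estimators under the
stated statistical structure, not the field accuracy of any particular
mapping product.

## Pipeline study design

The pipeline splits cores 50/50 into calibration and reference sets at the
core level (the split fraction is a parameter; an equal split gives both
phases comparable power), screens unusable-position cores from the
reference set, and evaluates six strategies on the same reference
increments: the calibration mean density, models 1 and 2 (AICc top models
with and without soil as a candidate) under true covariates (validation)
and under class-flipped covariates (application), and the emulated soil
map before and after bias correction, pairing each reference increment
with a random same-slab map value. Map-based strategy densities for the
stock table come from the map itself (its area-wide mean), as a mapped
product would be applied. Problem sizes in the shipped tests and
acceptance script (e.g. 100 bootstrap-coverage replicates at n = 500,
50 model-selection replicates at ~2000 increments, 300 map units) were
chosen to make the stochastic checks statistically decisive at the scale
of the emulated study.

## Known limitations

- ω² from the profiled-out OLS ANOVA slightly misattributes variance when
  the submitter design is very unbalanced.
- The breakpoint grid bounds [0.02, 0.90] assume the threshold is not in
  the extreme tails; data whose SSE minimum falls at a bound are refused
  rather than silently extrapolated.
- Fixed-effects prediction requires covariate levels seen in training
  (raising a named error otherwise); there is no partial pooling toward
  unseen levels.
- Totals treat area inputs as exact; no area uncertainty is propagated.
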