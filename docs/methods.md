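# Methods

This note documents the models, estimators and numerical choices behind
`thermovir`, and what its synthetic study designs do and do not emulate.

## Scientific setting

Entomopathogenic fungi such as *Metarhizium anisopliae* are deployed as
biopesticides against insect pests; their growth and the mortality they
inflict are strongly temperature-dependent. The package models three
linked questions: (i) how fast a fungal isolate grows as a function of
constant temperature, and between which thermal thresholds; (ii) how
lethal it is to an exposed insect cohort across temperatures, and how
fast it kills (LT50); (iii) where on a map, given monthly climate
normals, deployment would achieve high kill rates.

## Thermal performance models

**Linear rising limb.** `y(T) = a + bT` fitted by OLS to growth rates on
the rising limb only. The lower developmental threshold is the root

    T_min = -a / b,

with standard error

    SE(T_min) = (y_m / b) * sqrt( S^2 / (N y_m^2) + (SE_b / b)^2 ),

where `y_m` is the mean response, `S^2` the residual mean square, `SE_b`
the slope standard error and `N` the number of observations. By
convention the 33 and 35 degC observations are omitted from this fit
(configurable): they sit past the optimum and would drag the straight
line off the limb that the threshold formula assumes.

**Briere-1.** `r(T) = n T (T - T_min) sqrt(T_max - T)` on
`[T_min, T_max]`, defined as 0 outside the window (the square root is
undefined there and the biological rate is nil; the clamp also makes
spatial projection total over any temperature grid). Its optimum has the
closed form

    T_opt = [2 m T_max + (m+1) T_min
             + sqrt(4 m^2 T_max^2 + (m+1)^2 T_min^2 - 4 m^2 T_min T_max)]
            / (4 m + 2),

with the empirical exponent constant `m = 2` by the Briere-1 convention
(exposed as a parameter). For `T_min = 0` this reduces to
`(4m/(4m+2)) T_max`. Note the closed form marks the interior maximum
only for `T_min >= 0`; below 0 degC the cubic factor changes sign and
the curve's maximum can sit on the boundary. A grid-plus-golden-section
numeric argmax (`numeric_topt`, accurate to < 1e-6 degC) serves as the
independent check and as the only route for models without a closed
form.

**Logan-1.** `m(T) = y0 (e^{pT} - e^{p T_max - (T_max - T)/v})`:
exponential rise with a crash to exactly 0 at `T_max`, controlled by the
boundary-width constant `v` (degC).

**Logan-4.** A sigmoid rise times scale `alpha` minus a boundary
exponential:
`m(T) = alpha (1/(1 + k e^{-b(T - T_min)}) - e^{s (T_max - (T - T_min))/Dt})`.
Both the literal positive-exponent variant (`s = +1`,
`sign_corrected=False`) and the standard formulation (`s = -1`, the
default) are implemented; the positive exponent produces strongly
negative "mortalities" for realistic parameter sets, so fitting and
projection use the corrected variant.

Mortality models operate on proportions in [0, 1], never percentages.
Model evaluation never clips: clipping to [0, 1] happens only at the
spatial/reporting layer, so least-squares fitting sees the raw
functional form.

## Fitting and model selection

Replicates enter fits as individual observations (no pre-averaging),
preserving the error structure. Linear fits use the closed-form OLS
solution. Nonlinear fits minimise the residual sum of squares with a
bounded trust-region-reflective solver started from a seeded
Latin-hypercube of the parameter box (32 starts by default; scale
constants are sampled in log10 space). Threshold bounds are data-driven:
`T_min` in `[-15, min observed T]`, `T_max` in
`[max observed T, max + 5]`. The best start wins; if no start converges
the result is flagged, never silent.

Goodness of fit: RSS, R^2, adjusted R^2, RMSE, plus two selection
criteria that the package defines explicitly because curve-fitting
tools vary:

* AIC in the least-squares form `n ln(RSS/n) + 2k` (absolute values are
  therefore comparable only within this package);
* MSC (model selection criterion) `ln(TSS/RSS) - 2k/n`, bigger is
  better.

A perfect fit (RSS = 0) is reported with sentinels `AIC = -inf`,
`MSC = +inf`; constant observations (TSS = 0) leave R^2 undefined and
set a flag. Candidate models are ranked by ascending AIC; ties
(|dAIC| < 1e-9) break by higher adjusted R^2, then lower RMSE;
non-converged fits always rank last.

## Bioassay analysis

Final treatment mortalities are corrected for background death with
Abbott's formula `(T - C)/(1 - C)`, floored at 0, against the mean
control mortality of the matched isolate x temperature cell. The
correction is applied once at the end point before temperature-virulence
fitting; for LT50 curves the daily cumulative proportions are corrected
against the matched control curve and re-monotonised (a design choice —
the field practice is ambiguous — controlled by a flag, corrected by
default).

**LT50.** Per replicate, cumulative mortality is regressed on day with a
binomial-logit GLM (cohort size as variance weight);
`LT50 = -intercept/slope` (the day the logit crosses zero) and the SE
follows by the delta method. The covariance feeding the delta method is
*not* the GLM's: cumulative counts of one cohort are strongly dependent
across days, and the independence-assuming GLM covariance understates
the LT50 SE by ~30% (≈83% rather than 95% empirical 2-SE coverage in
seeded 20-insect simulations; Pearson-scaled quasi-binomial covariance
is worse still, because near-smooth cumulative curves look
underdispersed). Instead the (intercept, slope) covariance is the
inverse observed information of the exact death-day likelihood — a
multinomial over the logistic increments plus the surviving fraction —
evaluated at the fitted values by central finite differences
(relative step 1e-5). This restores ≈93-95% coverage while leaving the
point estimate (and its exact recovery of noiseless logistic data)
untouched. A replicate whose cumulative mortality never reaches 50%, or
with fewer than two days of interior mortality, yields no estimate and
is reported with a dash, and excluded (but counted) in the
mean ± SE summaries.

**Mass production.** Six arithmetic indices per production bag: conidia
powder g per kg substrate, conidia per g and per kg of powder, water
content % (wet minus oven-dry mass of a 1 g sample), viability %
(germinated/counted), and consumed substrate %.

## Spatial projection

Inputs are 12 monthly minimum plus 12 monthly maximum temperature grids
(WorldClim-style) sharing one geotransform, read and written as ESRI
ASCII grids (.asc) — a plain-text format with a
`ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value` header,
row 0 at the northern edge, cell-center registration. Values round-trip
through write/read to 1e-6. GeoTIFF is not supported; the CRS is carried
as an opaque label (WGS84 assumed) and never reprojected.

How monthly minima and maxima combine into a prediction is genuinely
open (means, extremes and degree-day schemes are all defensible); the
package evaluates the fitted expression at each month's midpoint
`(t_min + t_max)/2`, clips to [0, 1], and averages the 12 monthly
predictions into an annual surface — symmetric, total and
order-invariant in the months — while retaining the per-month
predictions so users can inspect sensitivity. Nodata propagates: a cell
missing in any month is nodata in the annual map.

The annual surface is classified into five mortality bands anchored to
the belts used when interpreting such maps: very-low [0, 0.16), low
[0.16, 0.34), low-moderate [0.34, 0.45), moderate [0.45, 0.63) and high
[0.63, 1] (half-open intervals, top band closed; edges configurable).
Occurrence points are looked up by nearest cell via the floor of the
geotransform offsets; points on a cell edge fall to the higher index and
points outside the extent are flagged, not dropped.

## Synthetic study designs

The generators are pure functions of (design, truth parameters, seed)
and mirror the laboratory layout: growth at {15, 20, 25, 30, 33, 35}
degC x 4 replicate plates; end-point mortality at {10, 15, 20, 25, 30}
degC x 4 cohorts of 20 insects; 12 days of daily death records; 5%
background control mortality so the Abbott correction is exercised
non-trivially. Default truth curves sit at the scale of the study
system: growth peaking near 2.3 mm/day around 29 degC with Gaussian
replicate noise of 0.1 mm/day, mortality following the published
Logan-1 parameter set (y0 = 0.14, p = 0.07, v = 1.66, T_max = 33.27).
Time-mortality cohorts draw each insect's death day once from the
discrete distribution implied by the logistic curve, so cumulative
counts are monotone by construction. The raster generator composes a
latitudinal gradient, a sinusoidal seasonal term and a fixed diurnal
range (so t_min <= t_max cellwise by construction) plus a nodata block
for mask testing.

What the generators do *not* emulate: between-replicate heterogeneity
beyond binomial/Gaussian noise, humidity or VPD effects, spatially
correlated weather, delayed germination at cold temperatures, or
isolate x temperature interactions. Passing recovery tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to real-data pathologies.

## Numerical choices and limitations

* Brière-1 evaluation is clamped to 0 outside its thermal window;
  Logan models are not clamped (they extrapolate), which is why the
  spatial layer clips.
* Multi-start count 32 and all random draws flow from explicit integer
  seeds; identical seeds reproduce byte-identical outputs.
* Problem sizes in the test and analysis runs (50-run growth recovery,
  200-run LT50 coverage, 20 x 20 rasters, 20^3 brute-force grids) were
  chosen to characterise the estimators at the study's own design scale.
* The LT50 regression assumes a logit-linear hazard in days; log-day
  predictors are not implemented.
* Fits are unweighted least squares on proportions; binomial-likelihood
  fitting of the temperature-virulence curve is out of scope.
* Only the four models above are implemented, not the wider battery of
  candidate thermal-response equations found in dedicated fitting
  suites, and no humidity covariates.
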