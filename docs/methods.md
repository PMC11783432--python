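# Methods

## Thermal time

Daily degree-days use the single-sine method: the day's temperature course
is idealized as one full sine period between Tmin and Tmax, and the area
above the lower developmental threshold (LDT) is integrated in closed form.
With Tm = (Tmax+Tmin)/2 and A = (Tmax−Tmin)/2 there are three cases —
whole day below threshold (0 DD), whole day above (Tm − LDT), and the
intercepted case (1/π)[(Tm−LDT)(π/2−θ) + A·cos θ], θ = arcsin((LDT−Tm)/A).
The boundary conventions are: Tmax = LDT yields exactly 0, and Tmin = LDT
is handled by the whole-day-above branch (the two formulas coincide there;
verified to 1e−9 in the tests). No upper developmental threshold is
applied, and no day-to-day interpolation is done between consecutive days
(single-sine, not double-sine). The closed form is property-tested against
brute-force quadrature of the truncated sine wave to ≤1e−6 °C·day.

Accumulation is calendar-aware with real leap years. The default biofix is
October 1 of the year before the flight season: *S. bicingulata* larvae
overwinter without obligatory diapause and accrue development whenever
temperatures exceed the LDT (4 °C, transferred from the allied dogwood
borer). The biofix day's own degree-days are included, so the CDD series
starts at that day's daily value. "Julian day" is reported as 1-based
day-of-year. Missing days inside the accumulation window are a hard error
naming the missing range; setting `fill_gaps` interpolates Tmin/Tmax
linearly and logs the fill. The error default is deliberate — silent gap
skipping biases CDD low and shifts every downstream date late.

## Emergence curve

Cumulative adult catch proportion is modelled as a two-component mixture on
the CDD axis: a Weibull-type sigmoid (50 % point β₁, shape γ₁ < 0) for the
first flight plus a logistic (centre β₁+Δβ, scale γ₂) for the second, with
weights α₁ + α₂ = 1. γ₁ is stored with its negative sign and validated as
such rather than silently absolute-valued. At DD = 0 the first term takes
its analytic limit 0, so a zero base is never raised to a negative power.
Proportions are fractions internally; percentages appear only at I/O
boundaries.

Within-peak percentiles are defined on the isolated component
(component_k = p·α_k), giving closed forms

- peak 1: β₁·((1−p)/p)^(1/γ₁)
- peak 2: β₁ + Δβ + γ₂·ln(p/(1−p))

rather than on the total mixture, because per-generation percentile tables
require per-generation quantiles. At the reference parameters the
cross-component contamination at the 50 % points is below 1e−4; note,
however, that the first component's polynomial tail is heavy (see
"Limitations"). Total-mixture inversion uses bisection with a geometrically
grown bracket, converging on interval width (relative 1e−12) because
function-value criteria stall on the near-flat inter-peak plateau and
saturation tails.

## Fitting

Trap catches per site-year are transformed to cumulative proportions of the
season total (zero-catch dates retained — they pin the curve), indexed on
CDD, and pooled across site-years with equal per-observation weight into a
single least-squares problem; per-observation weights are available as an
option. The constraint α₂ = 1−α₁ is substituted, leaving five free
parameters. Validity bounds are enforced by a smooth reparameterization
(logit α₁, log β₁, log(−γ₁), log Δβ, log γ₂) rather than penalties or
clipped bounds, keeping the objective differentiable; optimization is
trust-region least squares (ftol/xtol 1e−12, ≤3000 evaluations).
Non-convergence sets a flag instead of raising.

Starting values are data-driven: α₁ from the cumulative curve's level at
its mid-season slope minimum (the inter-peak lull, located on a smoothed
uniform-CDD grid), β₁ and β₁+Δβ from the α₁/2 and (1+α₁)/2 crossings, and
fixed shape defaults (γ₁ = −5, γ₂ = Δβ/10).

Standard errors come from a central-difference Jacobian in natural
parameter units, scaled by the residual mean square. Because software
conventions differ for the nonlinear-model F statistic, both the
mean-corrected (df p−1, n−p) and uncorrected (df p, n−p) versions are
computed and labelled; the corrected one is the headline `f_stat`.

## Validation

Observed series are split into the two flight periods at the date of
minimum raw catch in the trough between the two dominant local maxima of a
3-point moving average; dominance is ranked by peak prominence, since raw
height happily picks two noise spikes inside one flight on realistic count
data. Ties go to the earliest trough date, and an explicit split date can
override the rule. Within-peak observed percentiles renormalize by the
peak's own total; each target percent is read off the straight line
through the two sampling points bracketing it (a regression through two
points passes through both), with fractional days rounded half-up to whole
days-of-year. Deviation summaries are the mean and sample SD (n−1) of
absolute observed−predicted day differences per peak × percent, symmetric
in the two columns. The RDA benchmark (350 / 1895 DD at LDT 8.1 °C, same-
year January 1 biofix) runs through the identical single-sine engine.

## Mapping

Station Tmin/Tmax series are interpolated per day with inverse-distance
weighting: weights d^(−power) (default power 2) over the k nearest
stations by great-circle distance on the WGS84 mean sphere (default: all
stations); a cell within 1 m of a station copies it exactly. The elevation
corrections of topo-climatological downscaling are deliberately out of
scope — plain IDW is a documented simplification. Grids are xarray objects
whose georeference (north-west origin, cell size, CRS label) travels as
metadata and is never reprojected.

Peak-timing maps record, per cell, the day-of-year at which CDD from the
biofix first reaches β₁ and β₁+Δβ — the model's 50 % occurrence points.
Cells that never reach a threshold are missing (logged count). For
30-year climatological normals, the single synthetic year is preceded by a
copy of itself so the previous-autumn biofix has data. Timing rasters are
written as ESRI ASCII grids (.asc), a plain-text raster format standard
GIS software reads directly; gridded input is accepted as long-format
delimited text (`row,col,date,tmin,tmax`).

## Synthetic data

The weather generator emulates a temperate station series: daily mean
temperature is a sinusoid with a 365.25-day period (avoiding phase drift
over multi-year series) plus i.i.d. Gaussian noise, split into Tmin/Tmax
by a fixed diurnal range. Defaults — annual mean 13 °C, amplitude 12 °C,
warmest day-of-year 210, diurnal range 9 °C, noise SD 2.5 °C — describe a
southern-Korea-like climate accumulating roughly 3400–3600 DD (LDT 4 °C)
per year, enough for both flight peaks to fall within a season. What the
generator does **not** emulate: autocorrelated weather spells, spatially
correlated noise across stations, asymmetric seasonal shape, or
inversion-prone winter Tmin behaviour. Passing tests therefore demonstrate
correctness of the pipeline's mathematics under the assumed structure, not
robustness to every pathology of real station records.

Trap catches are generated by inverting the cumulative-proportion
transform: the expected catch per sampling interval is total·ΔP under the
true parameters, with Poisson noise per interval (count data; the
default), a multinomial conditioned on the season total, or no noise
(rounded expected cumulative counts). Station networks place stations
uniformly in a bounding box with an optional linear latitudinal lapse on
the annual mean. All generators are pure functions of (config, seed).

## Design choices on open points

- Missing station days: hard error by default (the original analyses do
  not document gap handling; erroring is the conservative choice).
- Scale of the fitted proportions: 0–1 (affects SSE magnitude only, not
  the estimates).
- Degrees of freedom for the model F: both conventions reported, labelled.
- Observed per-peak percentile denominators: per-peak totals (the
  two-sided percentile framing of per-peak validation tables implies it).
- The second peak's CDD is taken as β₁+Δβ = 3293.26 (→ 3293.3), the value
  consistent with the parameter estimates.

## Limitations

- The first component's tail decays polynomially (γ₁ ≈ −4.9 gives roughly
  20 % of first-flight mass beyond the inter-peak trough at the reference
  parameters). Trough-splitting with within-peak renormalization therefore
  biases *observed* first-peak medians a few days early relative to the
  model's within-peak percentile — a structural property of the mixture,
  quantified in the tests, not a numerical defect.
- IDW has no elevation or coastal corrections; mapped timings in complex
  terrain inherit that smoothing.
- The acceptance simulation uses 24 site-years of 300 moths at weekly
  sampling (≈1600 observations), matching the scale of a multi-site
  trapping study; recovery tolerances (2 % on β₁ and Δβ, 0.05 on α₁) were
  chosen for that scale.
- Fitting assumes pooled site-years share one parameter set; site-level
  heterogeneity appears only through the per-site weighting option.
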