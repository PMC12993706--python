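# Methods

This note documents the models, filters, parameter choices and numerical
conventions behind `ecoforcing`, and what validation on synthetic data
does and does not demonstrate.

## Data model and conventions

Half-hourly records are period-end timestamps in local standard time
(flux-community convention; no daylight-saving shifts). A half-hour is
attributed to the calendar day and clock time of its interval midpoint,
so the record ending at midnight belongs to the day it covers, and the
midday window 11:00–14:30 selects the seven half-hours whose midpoints
fall inside it. Missing values are `-9999` or empty on disk and NaN in
memory; the reader is exact (IEEE round-trip float parsing) so a
write–read cycle is lossless, including null patterns.

Phenological seasons (autumn, winter, spring, drydown, summer) are
supplied as ordered per-site transition dates; a transition date opens
the season it names (closed start, open end) — a deterministic tie-break
for a convention the season definitions leave open.

## Quality filters

* **Midday albedo.** α = SWUR/SWDR averaged over midday half-hours with
  clear-sky index above 0.7, SWDR > 50 W m⁻², on rain-free days. The
  clear-sky index is defined as measured SWDR over transmissivity-scaled
  potential radiation (τ = 0.75 by default), with a 20 W m⁻² low-sun
  guard; the index itself has no universal formula, so this definition
  is configurable. The 50 W m⁻² floor avoids low-sun ratio blow-ups
  (standard practice, not part of the filter set the analysis inherits).
  Ratios outside (0, 1) are discarded and counted.
* **Soil heat flux.** The ecosystem-scale G is the canopy-fraction
  weighted mean of below-canopy and open-land plates,
  G = f·G_canopy + (1−f)·G_open with f = 0.2 by default, kept as an
  explicit operation so the weighting is auditable.
* **Day flags.** A day enters the temperature decomposition only if it
  is rain-free and neither its nighttime nor its daytime missing
  fraction exceeds 66%. Day/night is split by potential radiation > 0.
  Missingness is assessed jointly over the variables the decomposition
  actually consumes (LE, H, G and the four radiation streams) rather
  than every column — the rule exists to protect the decomposition.
* **Agreement filter.** Decomposed days are kept only when the observed
  and reconstructed ΔTs have the same sign and differ by less than 2 °C.
  An exact zero agrees with either sign, so noise-free synthetic cases
  with a zero component are not discarded arbitrarily.
* **Energy-balance closure** is the through-origin OLS slope of
  (LE + H) on (Rn − G) over ≥ 30 daily means (the ratio of sums is also
  reported). This is the standard turbulent-flux closure definition,
  and it is also the sense in which the synthetic generator's closure
  parameter is defined, so the diagnostic recovers the parameter
  exactly in the noise-free limit.

## Radiative forcing

Monthly albedo differences (mean of daily midday Δα, requiring ≥ 3
qualifying days per month) are propagated to the top of the atmosphere
with a four-member ensemble of monthly albedo-kernel climatologies;
kernels are normalized to per-unit-albedo on ingestion (per-0.01 files
are scaled by 100) and read from 12-row CSVs. The across-kernel standard
deviation is carried as the forcing's kernel-spread uncertainty. The
packaged `synthetic_kernel_ensemble` is a synthetic construction with a
mid-latitude annual cycle of order 100 W m⁻² per unit albedo — it stands
in for site-extracted kernel climatologies in tests and examples and is
labelled as such.

The CO₂ term accumulates monthly NEE differences (mean daily difference
scaled by month length, which is robust to gaps) from treatment start,
converts them to a global mole-fraction perturbation weighted by the
airborne fraction β = 0.44, and applies the linearized 5.35·Δχ/χ₀
forcing expression with χ₀ fixed at 399.4 ppm for the whole record (no
annual update). The exact logarithmic form is exposed alongside the
linear one; their relative difference is bounded by |Δχ|/(2χ₀), and a
warning fires beyond |Δχ|/χ₀ = 0.01. Total forcing is the current
month's albedo term plus the cumulative CO₂ term; additivity is an
invariant of the output table. All values are reported in 10⁻¹⁴ W m⁻²
(global) m⁻² (treated surface).

**GWP of the albedo term.** The CO₂-equivalent of an annual-mean albedo
forcing is defined by inverting the package's own emission→forcing
chain: the sustained emission rate whose cumulative airborne burden at
the 100-yr horizon produces the same forcing. End-of-horizon matching
(rather than the time-mean of the growing burden, which would double the
magnitude) was chosen as the plainest reading of a sustained-emission
equivalence; the forward chain is exposed so the inversion is testable
to machine precision. The conversion is deliberately internal — no
external absolute-GWP constant is introduced — and should be read as an
order-of-magnitude bridge to the fertilization literature.

## Surface-temperature decomposition

Ts is retrieved from outgoing longwave via LWUR = σ ε Ts⁴ with
ε = −0.16 α + 0.99; no reflected-downwelling correction is applied, so
the inversion is the exact inverse of the retrieval convention. On each
qualifying day, treated-minus-control differences of daily means are
linearized around the **control site's daily state** (Ts, ε, α, SWDR):
the Δ-terms are defined against control, so control is the natural
reference; the alternative pair-mean reference changes components by
second order only. Division by 4 σ ε Ts³ converts each term to °C; the
emissivity term simplifies to −Ts·Δε/(4ε). The residual imbalance
I = Rn − LE − H − G enters as its own component, which makes the stored
components sum to the reconstructed ΔTs_cal *exactly* (machine
precision) — closure is by construction, and is asserted, not fitted.

Decomposition is daily-mean-first: daily means are formed from
quality-passing half-hours and decomposed once per day. Days without a
valid midday albedo use the site's month-mean albedo (logged). On
synthetic pairs with closed budgets the linear reconstruction tracks the
observed difference to well under 0.05 °C for |ΔTs| ≤ 2 °C; the residual
is genuine linearization error.

## Ecophysiology

Daily diagnostics use daytime means (potential radiation > 0), except ET
(and hence WUE), which integrates the 24-h mean LE through the
temperature-dependent latent heat of vaporization
λ = (2.501 − 0.00237·T) MJ kg⁻¹. Penman–Monteith inversion of Gs is
restricted to days with Rn − G > 20 W m⁻² — including nighttime would
make the inversion ill-posed — and inversions that come out negative or
above 0.1 m s⁻¹ are nulled as artifacts (counted). Psychrometrics are
Magnus-type saturation vapor pressure, γ = Cp·P/(0.622·λ), and ideal-gas
air density; they agree with standard tabulated values at 0, 20 and
40 °C within 1%. The master oracle of this module is the round trip:
inverted Gs fed through the forward Penman–Monteith equation reproduces
the input LE to machine precision. Ω = (ϵ+1)/(ϵ+1+Ga/Gs) with ϵ = s/γ
lies in (0, 1) for all valid inputs (0 = fully coupled).

## DTW attribution and statistics

Components and ΔTs_cal are compared per (site pair, layer, season) —
concatenated across years — with classic dynamic time warping:
absolute-difference local cost, symmetric steps, no window, no
z-normalization (the whole point of the °C conversion is a common
unit). Gaps split a series into aligned segments; segments shorter than
3 days are skipped, and distances and warping-path lengths add across
segments, which length-weights the recombination. Raw distances are
divided by the optimal path length (ties in backtracking break
diagonal-first, deterministically) and min–max scaled across the eight
components to [0, 1] within each group; groups need ≥ 10 kept days.
The normalization scheme is a package choice — the comparability goal
fixes the intent but not the formula — and is pluggable.

Seasonal between-site tests branch on Shapiro–Wilk normality (per site)
and Levene homoscedasticity at α = 0.05: ANOVA + Tukey HSD on the
parametric branch, Kruskal–Wallis + Dunn's test with Holm adjustment
otherwise. A compact letter display covers the maximal cliques of the
"not significantly different" graph. Degenerate zero-spread groups
short-circuit to a trivial result. The type-I error of the combined
branching procedure stays near nominal (measured ≤ 0.07 at α = 0.05
over 1000 null simulations with 30 days per site).

## Synthetic generator

The generator emulates the study conditions: three co-located sites × two
layers, two hydrological years at half-hourly resolution, latitude
39.94° N, five Mediterranean seasons. Daily weather (clouds, rain days,
synoptic temperature anomalies) is drawn once and shared across sites, so
between-site contrasts carry only the injected effects plus site-level
noise. Default injected effects mirror the reported treatment responses:
albedo offsets +0.015/+0.013 (ecosystem NT/NPT) and +0.017/+0.015
(understory), extra CO₂ uptake of 0.1–0.2 g C m⁻² d⁻¹, evaporative-
fraction shifts toward LE at NT (ecosystem) and NPT (understory), and
surface-temperature offsets of −0.41/+0.03 °C (ecosystem) and
+0.63/+0.80 °C (understory). Closure fractions are 0.88 (ecosystem) and
0.60 (understory); understory wind and friction velocity are half the
ecosystem values and its CO₂ fluxes 0.6 of ecosystem magnitude. Noise
standard deviations (e.g. 6 W m⁻² on LE/H, 0.006 on albedo), a 5% gap
fraction, 8% rain-day frequency and 15% cloudy-day frequency were chosen
once as representative of post-processed tower data of this kind.

What the generator does **not** emulate: footprint mismatch and spatial
heterogeneity, advection and storage terms, dew/fog conditions that
degrade eddy-covariance fluxes, instrument drift, realistic gap
clustering (instrument outages), or interannual phenological variability
beyond a shared synoptic wiggle. Passing parameter-recovery tests
therefore demonstrates that the estimators are unbiased and the
equations correctly implemented under the stated noise model — not that
the field-data uncertainties are this small.

## Problem sizes and numerics

Default validation runs use two synthetic years (three for the
linearization check) — about 210,000 half-hourly records — which resolve
every monthly and seasonal product while keeping the full suite and the
acceptance script in the minutes range on one CPU. DTW is exact dynamic
programming (no windowing); for the daily seasonal series involved
(≲ 200 days per group) this is unproblematic. Degenerate inputs (zero
denominators, out-of-range albedo, non-positive LWUR or conductances,
low-sun radiation) consistently yield NaN with logged counters rather
than exceptions; hard errors are reserved for structural problems
(non-monotonic timestamps, uncovered calendar dates, misaligned monthly
indices, missing kernel months).

## Known limitations

* The forcing is a first-order, kernel-based snapshot estimate; no
  longwave feedbacks or circulation response are represented.
* The big-leaf Penman–Monteith inversion aggregates stomatal and soil
  resistance and cannot separate layers of a tree–grass mosaic; Gs and Ω
  for the ecosystem layer inherit that single-surface assumption.
* The GWP conversion convention is internal (see above) and intended
  for order-of-magnitude comparison.
* The control-site reference state in the decomposition is a convention;
  antisymmetry under swapping treated and control holds to linearization
  order, not exactly.
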