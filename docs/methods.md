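# Methods

## Scope and model structure

`nearroad` implements a reduced-form (response-surface) surrogate of a
vehicle fleet emission model chained to a Gaussian line-source
dispersion model.  The surrogate replaces the parent models' internals
with a small set of fitted multiplicative submodels, so that hourly
concentrations at thousands of receptors over a year can be computed in
seconds.  It is designed for straight road segments at grade, flat
terrain, receptor distances of 15–300 m from the centreline, traffic of
1,000–15,000 vehicles h⁻¹ and winds of at least 0.5 m s⁻¹.  Mixing
height, atmospheric stability class, road grade/elevation and
mixing-zone widths other than 30 m are deliberately excluded: over the
surrogate's calibration range these inputs changed predictions far less
than wind angle, wind speed, distance and volume, and they are rarely
available for network-scale work.  NO₂ chemistry, particle
deposition/coagulation, curved roads and street-canyon effects are out
of scope.

## Geometry conventions

Coordinates are planar projected metres (UTM-like); angles are compass
bearings.  A road's alignment R lies in [0°, 180°) measured from north
(90° = east–west).  Receptor distance X is measured normal to the
*infinite* centreline — the model represents a long straight element,
and receptors beyond the finite endpoints are still evaluated.

The wind angle for a receptor is

θ = MOD₃₆₀(W − R − 90° + 180°·(I_W + I_R)),

where W is the meteorological wind direction (blowing *from*), I_W = 1
if the receptor is west of the road and I_R = 1 if R > 90°.  θ = 0°
means the wind is road-perpendicular with the receptor upwind, θ = 180°
the receptor downwind, θ = 90°/270° road-parallel winds.  "West" is
decided by the sign of the cross product of the road direction vector
pointing toward the larger-northing endpoint (larger easting for exact
east–west roads) with the road-to-receptor vector; the source geometry
only illustrates one alignment, so this deterministic rule extends the
indicator to every alignment, and the I_R term keeps the downwind
condition physically correct on both sides of R = 90°.  Receptors
exactly on the centreline take I_W = 0.  The dispersion table is
indexed by the folded angle min(θ, 360° − θ), since the problem is
mirror-symmetric about the road-normal plane.

## Emission submodel

* **Speed.**  S = S_FF / (1 + α(V/C)^β) (BPR volume-delay).  Fitted
  case-study coefficients: α = 0.1226 (freeway), α = 1.00 (arterial),
  β = 4.688; capacities 2000 veh h⁻¹ lane⁻¹ (freeway) and 825
  (arterial).  At capacity these drop 60 → 53.4 mph and 35 → 17.5 mph.
* **Day types.**  Weekday hourly volumes are the reference;
  Saturday/Sunday/holiday volumes are V·F1[d, h].  Class volumes use
  the two-stage rule: V*_K = V·F2_K·F3_K, then a common hourly rescale
  so classes sum exactly to the adjusted total.  F3 distinguishes light
  and heavy duty only (heavy = HDDV and heavy-duty bus).  The holiday
  calendar is a user-supplied date list (six observed U.S. holidays by
  default in the synthetic scenario).
* **Factors.**  Emission factors are g mi⁻¹ veh⁻¹ lookup tables by
  pollutant × season (winter / spring-fall / summer, by month) ×
  eight vehicle classes × 5-mph speed bins from 5 to 65 mph.  The
  lookup takes the nearest bin (half-bin ties round up; out-of-range
  speeds clamp to the end bins).
* **Units.**  Q = 0.625·Σ_K V·M_K·q_K(S) in g h⁻¹ km⁻¹.  The printed
  0.625 mi→km factor is used by default for fidelity with the source
  parameterisation; `strict_units=True` substitutes 1/1.609344.  The
  dispersion model consumes the fleet-average per-vehicle rate
  E = Q/V (g km⁻¹ veh⁻¹).

## Dispersion submodel

The hourly ppm concentration is

C = E · (V/10 000) · B(V, X) · U^k8 · P(X; sector),

with

* **Distance profile** P(X) = k1*·e^(−k3(X−k2)) + k4*·e^(−k6(X−k5)) —
  two exponential decays (fast and slow components, each with a scale,
  an offset and a decay rate) fitted per 10° wind sector; the 0–20°
  sectors are identically zero (receptor upwind).  The starred scales
  absorb k7, so the profile is calibrated at the nominal 4 m s⁻¹ wind.
  The 19-row coefficient table ships as packaged CSV data and is
  verified on load (all-zero upwind rows, non-negative scales/decays).
  With the 180° row the annual-mean field declines by roughly 50% at
  60 m, 75% at 100 m and 90% at 300 m relative to 15 m — the steep
  near-road gradient that motivates dispersion-based exposure metrics.
* **Wind factor** k7·U^k8 with k7 = 2.81, k8 = −0.739, relative to the
  4 m s⁻¹ calibration point (k7·4^k8 ≈ 1.01); concentrations fall ~82%
  from 1 to 10 m s⁻¹.
* **Volume bracket** B(V, X) = k9 + (e^{k10(V−k11)} − 1)(1 − e^{k12(X−k13)})
  with k9 = 0.99898, k10 = −2.6515·10⁻⁵, k11 = 10 749, k12 = −0.027061,
  k13 = 5.2826 m: vehicle-induced turbulence enhances dilution at high
  flows and reduces it at low flows, growing with distance and
  vanishing at the curb (X = k13).  B ≡ k9 at V = k11 for every X and
  spans 0.89–1.29 (2 dp) over the validity grid.  B is independent of
  wind angle by construction.
* **Emission scaling.**  The V/10 000 factor scales the total segment
  emission rate relative to the 10 000 veh h⁻¹ calibration condition;
  together with E it makes the model linear in total emissions, so
  multi-road superposition and a scalar background term are exact.
* **Units.**  Multiplying the ppm output by 1322 gives µg m⁻³; the same
  factor is applied to any pollutant run through the table, since the
  sector coefficients express dispersion per unit emission.

## Missing-data semantics

Calm hours (calm flag set, or reported speed 0) produce *missing*
predictions, never zero — Gaussian models are undefined in calms, and
coding them as zero would bias means low in exactly the conditions that
produce peak concentrations.  Wind speeds in (0, 0.5) m s⁻¹ clamp to
the 0.5 m s⁻¹ floor.  Daily means require ≥ 12 of 24 valid hours.
Percentiles (linear interpolation between order statistics) and
correlations use the non-missing support only (pairwise-complete), and
running means (5-, 30-day trailing windows) require at least half the
window — conventions chosen to mirror the daily completeness rule,
since none is prescribed for them.  The number of excluded days is
logged.

## Range policies (numerical choices)

* X < 15 m clamps to 15 m with a warning — the profile fit starts at
  15 m and errors grow rapidly below ~30 m.
* X > 300 m extrapolates the double exponential with a warning by
  default (`x_policy="missing"` masks instead, `"clamp"` holds the
  300-m value) — grids inevitably contain far receptors and the decay
  tails are well-behaved.
* V outside [1000, 15 000] clamps *only inside the bracket B*; the
  emission terms keep the true volume, so concentrations still scale
  with actual traffic.
* Folded θ maps to the nearest 10° row (ties round up).  Optional
  linear interpolation between adjacent rows (`sector_interpolation`)
  yields smoother fields and matches the row values exactly at grid
  angles; it is off by default because the parameterisation was
  estimated per-sector.

## Synthetic study conditions

The generator (`nearroad.synth`) defines the default test-bed rather
than fitting any real data set:

* **Meteorology:** 16-sector wind rose weighted toward SW–WNW (Great
  Lakes-like), uniform jitter within sectors; truncated-normal speeds
  (mean 4.4, sd 2.1 m s⁻¹, floor 0.5) giving a non-calm annual mean
  near 4.3–4.5 m s⁻¹; Bernoulli calms by hour of day averaging ~8% of
  hours and concentrated pre-dawn.
* **Traffic:** double-peaked weekday profile (peaks 7–8 am and 4–6 pm,
  high plateau to 8 pm) scaled to 144 600 veh day⁻¹; Saturday/Sunday/
  holiday totals at 77/68/74% of weekday with the morning peak erased
  and livelier nights (F1 ≈ 0.2–1.4); heavy-duty volumes at 38/27/51%;
  a fleet with 12% HDDV whose hourly share moves opposite to total
  volume (peaking pre-dawn).
* **Emission factors:** CO and NOx convex in speed with an interior
  minimum near 40 mph; PM2.5 flat in speed with heavy-duty factors
  ~17× light-duty so heavy-duty diesels carry ~72% of fleet PM2.5;
  winter CO 1.5× summer.

All draws come from a seeded PCG64 generator; identical seeds give
identical files, and generated CSVs round-trip bit-identically through
the package readers.  What the generator does *not* emulate: synoptic
persistence (hourly draws are independent, so multi-day stagnation
episodes and strongly autocorrelated daily series are rarer than in
real meteorology — cross-road daily anti-correlations are therefore
weaker than observed ones), seasonal wind shifts, temperature-driven
emission variability within a season, and high-emitting vehicles.
Passing tests on this test-bed demonstrate the model's internal
contracts (linearity, symmetry, missing-data handling, gradient
structure), not predictive skill against monitored data.

## Analytics

* **Extreme days:** argmax/argmin of the daily concentration averaged
  across receptors; ties break to the earliest date.
* **Campaign error:** for 1–2-week campaigns, every feasible start day
  is enumerated; the error is |campaign mean − annual mean| / annual
  mean, reported as mean and range.  The two-season strategy pools two
  equal windows 26 weeks apart, which cancels much of the seasonal
  cycle — on an annual sinusoid its mean error is provably below the
  single-window error, matching the general advice to sample opposite
  seasons rather than lengthen one campaign.
* **Evaluation utilities:** fraction of paired predictions within a
  factor of two of observations (0.5 ≤ pred/obs ≤ 2), Pearson r and
  relative mean bias, for use where monitoring data exist.  No
  monitoring data are packaged; the tests exercise these utilities on
  synthetic prediction/observation pairs.

## Problem sizes

The test suite runs a full synthetic year (8760 h) over a 169-receptor
grid with two roads in well under a minute; the vectorised kernel
scales linearly in receptors × roads, so the ~2000-receptor grids used
in urban case studies remain a seconds-scale computation.

## Known limitations

* The surrogate inherits every limitation of its Gaussian parent:
  no calms, no street canyons, no complex terrain, approximate at
  < 30 m and at wind speeds > 8 m s⁻¹ near the road.
* PM2.5 emission factors from fleet models of this vintage are known to
  underestimate heavy-duty emissions substantially; PM2.5 outputs are
  best treated as relative spatial patterns.
* Excluding calm hours biases daily means downward on stagnation days —
  exactly the high-concentration days — which matters for
  epidemiological designs that drop incomplete days.
* The side indicator and wind-angle conventions are self-consistent and
  reproduce the published worked geometry, but any external tool
  supplying I_W directly must follow the same cross-product rule.
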