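# Methods

`agroens` simulates rain-fed wheat and maize cropping in tropical-highland
environments with a *factorial* multi-model ensemble: four structural
variants of the crop growth submodel, two of the soil water submodel, two of
the soil organic matter (SOM) submodel and three of the soil heat submodel
are combined in every possible way (4 × 2 × 2 × 3 = 48 members).  The
ensemble is driven by daily weather — observed series or the package's
stochastic generator — and by emulated climate-model projections, and the
downstream statistics attribute the spread of projected impacts to the
individual model components.

The four crop variants are structural stand-ins built from the published
contrasts between the CERES/SUCROS/SPASS/GECROS model families (canopy
radiation scheme, leaf-internal CO₂ treatment, assimilate partitioning,
leaf-area and senescence drivers, root distribution).  They are one shared
daily core with a switch set, **not** ports of those models' code; the same
holds for the SOILN-like and DAISY-like SOM pool structures and the
LEACHN/DAISY/SHAW-like heat schemes.  The point of the ensemble is the
structural diversity signal, not source-level fidelity.

## Process models

### Phenology
Thermal time `TT = Σ max(0, Tmean − Tbase)` (°C d) accumulated from
planting; stages flip at `TT_flowering` and `TT_maturity`.  Vernalization
and photoperiod are off by default (tropical highlands; they were not part
of the calibration data either).  Defaults: wheat Tbase 0 °C, 1000/1800 °C d
(≈ 110 days at a 16–17 °C season); maize Tbase 8 °C, 700/1350 °C d (≈ 175
days at the cool maize site, matching the intermediate maturity group's
160–200-day range).

### Assimilation and the variant switches
Gross growth is radiation-use efficiency times intercepted radiation for the
ceres-like variant (RUE 1.45/1.85 g DM MJ⁻¹ for wheat/maize), and a
light-response (asymptotic-exponential) leaf photosynthesis integral over
the variant's canopy layers for the other three (Amax 36/48 g CH₂O m⁻² d⁻¹,
initial slope 4 g CH₂O MJ⁻¹ PAR, a 0.7 CH₂O→DM conversion).  Canopy
interception follows Beer's law with k = 0.6; the 3- and 5-layer schemes
telescope exactly to the big-leaf total, and the two-leaf scheme splits that
total into sunlit/shaded fractions.  Temperature response is trapezoidal:
wheat (0, 11, 20, 32) °C — a cool-season C3 crop that suffers above ~20 °C —
and maize (8, 18, 33, 44) °C.  CO₂ response is normalized to 1 at 360 ppm;
C3 follows a Michaelis form calibrated to a +25 % assimilation boost at
720 ppm, C4 rises linearly to +4 % at 450 ppm and saturates there.  The
gecros-like variant couples leaf-internal CO₂ to assimilation by a short
fixed-point iteration; sucros/spass use a constant Ci/Ca; ceres applies the
pathway response directly.

Partitioning: *priority* (ceres-like; roots and leaves served first, root
share rising under stress), *fixed* stage-indexed fractions (sucros/spass),
and *optimized* root:shoot (gecros-like; the root share grows toward the
more limiting resource).  During grain filling the grain fraction ramps to a
ceiling of 0.75–0.78.  Senescence drivers per variant: age/drought/N
(ceres), age/self-shading/temperature (sucros), + N (spass), and N
translocation to grain (gecros).  A seedling-reserve term keeps early growth
near-exponential while LAI < 0.3 (only when radiation is non-zero).

Carbon and nitrogen are book-kept exactly: Δ(live biomass) = assimilation −
senesced losses, and Δ(crop N) = soil uptake − N lost in senesced tissue, to
machine precision; the tests assert this daily and per season.

### Water and nitrogen stress
`f = min(1, supply/demand)`.  Water supply integrates plant-available water
over the variant's root distribution (dynamic-triangular, exponential or
uniform) with a daily extraction coefficient 0.09; the gecros-like variant
applies no reduction until wilting point.  N supply is 50 % of rooted-zone
mineral N per day; uptake equals min(demand, supply) and is debited from the
soil exactly.

### Evapotranspiration
Daily FAO-56 Penman–Monteith reference ET₀ (full chain: vapour pressures,
psychrometric constant from elevation, extraterrestrial/clear-sky radiation,
net shortwave with albedo 0.23, net longwave with the cloudiness factor
clipped at zero so longwave is never a gain, G = 0).  A single crop
coefficient Kc (default 1.05 wheat, 1.10 maize) scales ET₀ to crop demand,
which is split into soil evaporation `ET₀ (1 − f_int)` and transpiration
demand `Kc ET₀ f_int` by canopy cover.  When humidity is missing the
dewpoint falls back to Tmin (with a warning).

### Soil water
Shared grid: profile horizons subdivided into ≤ 15 cm cells.

*Tipping bucket*: each cell holds water up to field capacity; excess
cascades instantly; bottom excess is drainage; no upward flow by
construction.  *Richards*: implicit finite differences with
modified-Picard (mass-conservative) iteration, van Genuchten–Mualem
relations, adaptive sub-daily stepping (halving on non-convergence down to a
10⁻⁵ d floor, then an exception with diagnostics), free-drainage bottom by
default and an optional fixed water table for capillary-rise experiments.
The head-change tolerance is 0.05 cm; the conservation error of the scheme
is second order in that tolerance and the audited season residuals are
≤ 10⁻⁵ % of cumulative input.  The inner solve is a plain-loop kernel JIT
compiled with numba when available (identical code runs without it).

Hydraulic parameters are pedotransfer stand-ins anchored on the measured
data: porosity `θs = 1 − BD/2.65`, `θr = 0.5 θpwp`, van Genuchten (α, n)
fitted through (−33 kPa, FC) and (−1500 kPa, PWP), Ksat from the Cosby
sand/clay regression.  For the study sites' clayey, high-FC profiles this
yields flat retention curves and low near-saturation conductivity, so
Richards members shed wet-season surplus largely as saturation-excess runoff
where bucket members drain it — a deliberate, documented structural
contrast.  Soil evaporation extracts from the top 15 cm with a two-stage
(demand- then supply-limited) reduction and never passes the air-dry water
content (matric head −2 × 10⁵ cm); transpiration extraction is capped at
plant-available water above wilting point per layer.  Runoff is
saturation-excess only (the sites are flat plains).

### Soil heat
Implicit 1-D conduction on the water grid extended to 2 m, thermal
conductivity 0.25 + 1.2 θ W m⁻¹ K⁻¹ and volumetric heat capacity of solids +
water.  leachn-like: smoothed weekly-mean air temperature as the upper
boundary, zero flux at 2 m, no convection.  daisy-like and shaw-like:
surface temperature equals daily air temperature, an analytic damped
annual sinusoid at the bottom, and convective transport with the downward
water flux; shaw-like additionally cools the surface by 0.25 °C per mm of
soil evaporation.  With zero evaporation and zero water flux the daisy and
shaw schemes coincide exactly, and a homogeneous column under annual
sinusoidal forcing reproduces the analytic `exp(−z/d)` amplitude decay
within 10 % at 50 cm.

### Soil organic matter and mineral N
Total C per layer is OC % × BD × thickness (the only measured C input),
partitioned by documented default fractions: soiln3 = humus 0.95 / litter
0.04 / manure 0.01 (k = 7 × 10⁻⁵, 0.035, 0.012 d⁻¹; C:N 10, 25, 15;
humification 0.20–0.25); daisy6 = AOM fast/slow, microbial biomass
fast/slow, native SOM fast/slow (k from 0.05 down to 2.7 × 10⁻⁶ d⁻¹, C:N
25/6.7/11, utilization efficiencies 0.4–0.6).  Decay is exact first-order
per step with modifiers `f_T` (Q₁₀ = 2 about 25 °C, capped at 1.2) and
`f_θ` (piecewise linear, 1 at field capacity, reduced when dry or
saturated); decayed C is routed by a transfer matrix whose rows plus the
respired fraction sum to 1; N follows C through the fixed C:N ratios and net
mineralization may be negative.  Senesced leaves enter the variant's litter
pool at 0.45 kg C per kg dry matter; because the litter pool's C:N is fixed,
the residue's N bookkeeping is carried per subsystem (crop, SOM, mineral N),
each of which closes exactly.  Mineral N: fertilizer to the surface layer,
first-order nitrification (0.2 d⁻¹), uptake capped at stock, and
downward-only convective NO₃ leaching with full mixing per layer
(`leached = NO₃ · min(1, q/W)`).  Denitrification and volatilization are
omitted to keep the balance auditable.  Initial mineral N is 10 kg NO₃-N/ha
over the profile, reset annually (the study re-initializes every year).

## Management
Planting window = mean ± 2 SD of historical planting days (rounded
outward).  Within the window the first day with ≥ 20 mm rain in a forward
3-day sum and no dry spell longer than 10 days in the following 30 days is
planted; otherwise the window's last day.  "Dry" is < 1 mm/day (exposed in
config); the 3-day sum must lie fully inside the data.  Fertilizer is split
50/50 at planting and +30 days; the scenario's N rate scales the splits.
Initial soil water is 80 % of plant-available capacity, reset annually.
Seasons are simulated from 15 days before the window to maturity (or
year-end, flagged).

## Scenarios, impact and uncertainty statistics
Sensitivity perturbations: additive ΔT on Tmax/Tmin, multiplicative (1+ΔP)
on precipitation, [CO₂] to the crop, N rate to the fertilizer events.
Quantile–quantile bias correction is empirical, fitted per calendar month
(≥ 20 values required), linear between sample quantiles with constant-offset
extrapolation; precipitation is corrected on wet days (> 0.1 mm) after a
frequency-matching step and floored at zero; temperature is corrected in
value space.  Impact is the percent change of *medians* between future and
baseline simulations.  Uncertainty attribution: for one target factor, the
sample SD (ddof = 1; the variance reading is available behind a flag) of the
median changes over that factor's levels within every fixed combination of
the other factors, normalized by |overall mean change| (with a configurable
floor) × 100.  When the overall mean change is near zero this normalization
inflates the CVs arbitrarily — an intrinsic instability of the statistic —
so every decomposition carries the mean it was normalized by and the CVs
should be read together with it.  The per-factor CVs are not a variance
partition and do not sum to 100 %.

## Synthetic data
The weather generator is a minimal standard structure: two-state first-order
Markov rainfall occurrence per calendar month (wet-day persistence 0.65),
gamma wet-day amounts (shape 0.85) whose mean reproduces the monthly
climatological totals, monthly-mean temperatures plus AR(1) noise (SD
1.6 °C, autocorrelation 0.6, wet days 1 °C cooler in Tmax), solar radiation
as extraterrestrial radiation times a clear-sky factor reduced on wet
(cloudy) days, wind ≈ 2 m/s and relative humidity from a Tmin-dewpoint
proxy.  Leap days are generated.  The three site climatologies emulate the
study region: unimodal summer rains (~1300 mm/yr) at the first wheat site,
a May–October season (~900 mm/yr) at the maize site, bimodal rains at the
second wheat site.  What the generator does **not** emulate: multi-site
spatial correlation, trends, extreme-event clustering beyond Markov
persistence, or observed-station idiosyncrasies — so passing tests show the
pipeline's internal consistency and directional behaviour, not agreement
with any real station record.

GCM emulation: a "historical" run is the baseline plus fixed monthly
distortions (temperature offsets, lognormal precipitation factors) scaled by
a noise parameter, and the "future" run adds prescribed monthly deltas on
top, exactly invertible for the deterministic part.  The default ensemble
draws annual warming of 1.0–1.7 °C (mean ≈ 1.3 °C, Tmin slightly above
Tmax) with site-specific precipitation-change signs.  Crop observations are
simulated season outcomes with rounded Gaussian date noise and truncated
Gaussian yield noise, re-drawn when ordering would break.

## Calibration
Two-step sum-of-squared-errors, as a Model/Results pair
(`CropSystemModel.fit()` → `CalibrationResult`).  Step 1 estimates the
thermal-time thresholds from flowering/maturity dates by bounded
Nelder–Mead with seeded multistarts; the objective uses continuous
threshold-crossing times (linear interpolation within the crossing day,
observed dates taken at their half-day), which removes the integer-day
plateaus of the naive objective and recovers noise-free parameters to well
under 1 %.  Step 2 fixes the phenology parameters bit-for-bit and estimates
a single multiplicative scale on the variant's efficiency currency
(RUE/Amax) against observed yields.

## Numerical and scale choices
Grids: soil cells ≤ 15 cm, heat column to 2 m (padded below the profile).
Richards tolerance 0.05 cm on heads, Picard cap 15 per sub-step, sub-step
growth ×1.5 after success.  The test suite runs the full 48-member ensemble
over 30 synthetic seasons for the conservation audit; the acceptance script
uses 10-year baseline/future windows and 5 emulated GCMs per crop — a
deliberately scaled-down study (the original design is 30 years × 10 GCMs)
chosen to keep a desk-scale run practical while leaving every structural
contrast intact.

## Known limitations
* The four crop variants share one daily core; their spread understates the
  true inter-model spread of the parent families.
* Grain N concentration rarely departs from its target on the organic-rich
  site profiles (N supply is ample), so grain-quality impacts are muted
  relative to N-limited systems.
* On the clayey site profiles the fitted retention curves make the Richards
  members runoff-dominated; measured hydraulic data would change that
  partition.
* At a cool highland site, warming moves maize up the rising limb of its
  temperature response, so simulated maize can *gain* yield under moderate
  warming while its season shortens strongly (relative development-rate
  change is large when Tmean is near Tbase); wheat, already near its
  optimum, loses.  These are properties of this synthetic system, not
  predictions for any real site.
* No pests, diseases, lodging, frost, denitrification, volatilization, or
  soil freezing.
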