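# Methods

`ntheat` implements a dual-index heatwave exposure engine and a
space-time-stratified case-crossover analysis of daily emergency-department
(ED) presentation counts, with a synthetic-data generator that reproduces the
statistical structure of the restricted Northern Territory (NT) health and
climate inputs so the whole pipeline is testable offline.

## Exposure model

### Excess Heat Factor

For a daily driver series x (°C) the package computes, per region:

- significance index: `EHI_sig(i) = mean(x[i..i+2]) − T95`
- acclimatization index: `EHI_accl(i) = mean(x[i..i+2]) − mean(x[i−30..i−1])`
- Excess Heat Factor: `EHF(i) = EHI_sig(i) × max(1, EHI_accl(i))` (°C²)

`T95` is the 95th percentile (linear-interpolation definition) of the driver
over all calendar days of a fixed reference period, with 1960–2011 as the
default reference window. A day with positive EHF is a heatwave day; because
the significance index averages a three-day block, positivity embeds the
"three or more unusually hot days" persistence requirement. Severity compares
EHF with `EHF85`, the 85th percentile of the strictly positive reference-period
EHF values: low-intensity (`0 < EHF < EHF85`), severe (`EHF ≥ EHF85`), extreme
(`EHF ≥ 3 × EHF85`). Thresholds are closed below (a value exactly at the
threshold takes the higher tier). Severe and extreme days are collapsed into
one `severe_extreme` exposure level for regression, because extreme days are
rare.

Two deliberately open formulation choices are exposed as configuration rather
than hard-coded, since the index is used in the field with both conventions:

- **Window orientation** (`sig_orientation`): the default is a forward
  three-day window at day i (days i..i+2) with the 30 acclimatization days
  strictly before i; a trailing window (days i−2..i) is available. With the
  forward default the first 30 and last 2 days of a series are undefined.
- **Day labelling** (`label_window_days`): by default day i is labelled by
  EHF(i) alone, which gives each stratum-day an unambiguous exposure; an
  option paints all days covered by a positive window with the most severe
  covering value.

### Drivers: temperature-only (T) and heat-index (TH)

Variant T drives the EHF with daily mean temperature. Variant TH drives the
identical code path with an apparent-temperature heat index computed from
daily mean temperature and daily mean relative humidity via the Rothfusz
(1990) regression in °F, with the standard National Weather Service branch
logic: the heat index equals the temperature below 40 °F; the simple formula
`0.5 × (T + 61 + 1.2(T−68) + 0.094·RH)` applies until it reaches 80 °F; above
that the full nine-term polynomial applies with the low-humidity (RH < 13%,
80–112 °F) and high-humidity (RH > 85%, 80–87 °F) adjustments. The TH
thresholds (T95, EHF85) are computed on the heat-index scale, so the two
variants are never mixed numerically.

Because the heat index is computed from daily means (not hourly values
averaged afterwards), humid days weight into the driver through the daily
mean RH; this is the documented default and the only formulation offered.

### Climate ingestion

Relative humidity is derived from temperature and dewpoint with the
Magnus/Alduchov–Eskridge saturation vapor pressure
`e_s(T) = 6.1094 · exp(17.625·T / (T + 243.04))` hPa, as
`RH = 100 · e_s(Td)/e_s(T)` clamped to [0, 100]; dewpoints above the
temperature are clamped with a counted warning. Hourly fields are averaged to
local calendar days (NT civil time, UTC+9:30, no daylight saving); by default
a day is valid only if all 24 hours are present, configurable through
`max_missing_hours`. Regional series are area-weighted means over grid cells
with precomputed weights (weights sum to 1 per region; polygon processing is
out of scope); weights are renormalized per day over non-masked cells, and RH
is derived per cell before regional averaging so it stays within [0, 100].
NetCDF input/output uses the NetCDF3 classic format via xarray's scipy
backend; a per-region CSV is the fallback input.

## Outcome processing

ED line-list records carry date, hospital, residential region, age, sex,
Indigenous status and an ICD-10-AM shortlist code. Diagnoses map to eleven
condition groups by ordered range lookup, where a 3-character range (e.g.
S00–S99) matches all decimal children and a decimal-specific entry (e.g.
R19.0, U07.1–U07.2) matches only the listed codes; anything else falls into
`other_unclassified`. Age bands are <5, 5–18, 19–49, 50–64, ≥65. Two
socioeconomic (IRSD decile) banding presets circulate for the same NT
analysis — deciles 4–7 vs 4–6 as the middle band — so both are provided as
named schemes (`methods`, `table`) and the choice is an explicit argument.

Exposure region assignment: NT residents keep their residential region;
visitors (non-NT address) and unknown/missing addresses take the region of
the hospital attended. Counts are aggregated to one row per region-day over
the full calendar span, zero-filled, because the case-crossover contrast
needs every day of the risk set, and joined with exposure level, a
public-holiday flag and daily PM2.5.

## Case-crossover regression

Strata are (region, year, month, ISO day-of-week): a stratum collects e.g.
all Fridays of January 2005 in one region. Conditioning on the stratum event
total eliminates the stratum intercept and leaves the conditional
log-likelihood

    l(β) = Σ_s [ Σ_{i∈s} y_i x_i'β − (Σ_{i∈s} y_i) log Σ_{i∈s} exp(x_i'β) ]

which the package maximizes by Newton iterations from β = 0 with step
halving, converging when the largest score component falls below 1e-8 or the
step below 1e-10. Covariates are indicators for low and severe/extreme
heatwave exposure (reference: no heatwave), a public-holiday indicator and
continuous PM2.5 (µg/m³); `use_pm25=False` reproduces the sensitivity
analysis without air-quality adjustment, and rows with missing PM2.5 are
excluded from their stratum (not imputed), with a count reported.

Strata with zero total count or no within-stratum covariate variation carry
no information and are dropped (counted); a covariate with no within-stratum
variation anywhere (e.g. no holidays in a short span) is dropped from the
design with a log note, since it is unidentifiable under conditioning.
Estimates that drift beyond |β| > 15 raise a separation error naming the
column.

Overdispersion is handled quasi-likelihood style: the Pearson statistic
`Σ (y−μ̂)²/μ̂` over used rows is divided by `n − p − n_strata` — degrees of
freedom are charged for the implicitly estimated stratum intercepts as well
as the p regression parameters — and the resulting φ scales the inverse
observed information. No floor at 1 is applied; a saturated design yields
φ = NaN with an unscaled covariance and a warning. Confidence intervals are
Wald on the log scale with z = 1.96, with no multiplicity adjustment. Rate
ratios are `exp(β)`; percent change is `(RR − 1) × 100`.

## Descriptive surfaces

- **Index agreement**: a 2×2 cross-tabulation of location-days by heatwave
  status under the T and TH calendars over an identical span, with
  discordance percentages taken against each variant's margin.
- **Trends**: annual heatwave location-day counts per climate zone, fitted by
  a Gamma GLM with log link (statsmodels IRLS) on the year index. Zero-count
  years lie outside the Gamma support and are excluded with a logged note; a
  perfectly flat series is returned exactly (slope 0) without IRLS. At least
  three positive years are required.
- **Period comparison**: percentage of location-days meeting heatwave
  criteria in two non-overlapping year ranges, and the change in percentage
  points computed from the rounded percentages, as printed tables are read.
- **Characteristics tables**: counts and column percentages of presentations
  on heatwave days by characteristic × intensity × variant.

All percentages round half-up at one decimal. Location-day denominators count
365 (or 366) days per calendar year times the number of regions. The
published NT 2001–2023 summary record (heatwave-day totals, the agreement
table cells, selected presentation counts) ships as package data so its
internal arithmetic can be recomputed with the same reporting helpers.

## Synthetic data

The generator emulates the four restricted inputs:

- **Weather**: per region, daily mean temperature = annual sinusoid (default
  mean 27 °C, amplitude 3.5 °C, peak at day-of-year 330, the NT build-up) +
  AR(1) noise (ρ = 0.7, innovation SD 1.1 °C) + injected heat episodes.
  Episodes arrive Poisson (default 3/year) in the warm season (Oct–Mar), last
  at least 3 days (3 + geometric extra, mean ≈ 2), and lift the run to the
  seasonal peak plus an anomaly (default ≈ 6 °C, jittered ±25%), so injected
  heat exceeds local climatology in any season and a ≥ +8 °C run is always
  detected by the EHF engine at onset. Dewpoint couples as temperature minus
  a non-negative, seasonally varying depression (drier mid dry-season).
- **ED counts**: daily counts are Poisson with
  `log μ = log(baseline) + log(DOW multiplier) + log(RR_level) + log(RR_holiday)·1(holiday) + c·PM2.5`;
  defaults RR_low = 1.015 and RR_severe/extreme = 1.06 mirror the all-cause
  effect sizes reported for the NT, holiday RR 1.08, PM2.5 coefficient 0.003
  per µg/m³. Line-list records are expanded from fixed demographic and
  condition mixtures; each region hosts one hospital, so visitor records
  (non-NT address) map back to the generating region through the hospital.
- **PM2.5**: log-normal with mild dry-season (burning-season) elevation,
  independent of heat episodes by default; a confounded variant elevates
  PM2.5 on heatwave days to exercise the sensitivity machinery.
- **Holidays**: six fixed territory-wide dates per year.

Random streams are split per component (weather, PM2.5, counts, demographics)
from one master seed, so reconfiguring one component never perturbs another;
identical seeds give byte-identical fixture files.

Named fixtures: `tiny` (2 regions, reference 1996–1997, analysis 1998–1999,
baseline 5/day), `null` (as tiny with all effects null) and `powered`
(40 regions, reference 1990–2000, analysis 2001–2004, baseline 20/day,
true RR 1.06/1.015). Fixture reference periods sit inside the simulated span
rather than at 1960–2011, keeping simulations small; the engine itself
defaults to the 1960–2011 reference for real inputs.

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: spatial correlation of weather across regions
beyond shared seasonality, real NT geography and population sizes,
presentation time-of-day, lagged/delayed presentations after heatwaves, and
any calibration to the actual restricted records.

### Parameter recovery design

The recovery study generates the powered exposure design once (weather →
calendars → covariates) and redraws Poisson counts 200 times from the truth
means, refitting each replicate. Coverage of the 95% Wald intervals is
therefore evaluated conditional on the realized exposure design — the design
under which the model is specified — which keeps the study inside a few
seconds of compute. Observed behavior: mean bias of the severe/extreme
log-rate-ratio near zero (well under 0.005), coverage near 95%, Pearson
dispersion near 1 for the Poisson generator and near 2 when counts are drawn
with variance 2μ.

## Numerical choices and degenerate inputs

- Percentiles: linear interpolation between order statistics throughout.
- Newton iterations use a per-stratum log-sum-exp shift for stability.
- Conditional-likelihood equivalence with the stratum-dummy Poisson MLE holds
  to ~1e-9 on identified instances; unidentified (within-stratum collinear)
  designs raise rather than returning an arbitrary solution.
- A constant driver series has no positive EHF and is rejected when severity
  thresholds are requested, with an explicit message.
- Series shorter than the acclimatization + significance windows yield
  all-undefined EHF with a logged warning.
- Analyses at tiny scale (two regions, two years) produce wide intervals and
  visibly noisy point estimates; the powered configuration is the scale at
  which calibration claims are made.

## Known limitations

- The conditional fitter assumes counts are independent across days given the
  stratum; serial correlation within strata is not modelled.
- The heat index is computed from daily mean temperature and RH; hourly heat
  index averaged to days would differ on days with strong diurnal humidity
  cycles.
- Exposure misclassification from residential-address assignment is inherited
  from the design and not simulated.
- Trend confidence ribbons, distributed-lag models and separate severe vs
  extreme regression terms are out of scope.
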