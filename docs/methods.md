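# Methods

## Problem setting

A dense network of low-cost electrochemical NO/NO₂ sensors inside a
container port records concentrations at 1-minute resolution. Two questions
drive the analysis: (i) can the cheap sensors be trusted after field
calibration against reference-grade analyzers, and (ii) how much of the
measured concentration at each site is produced *locally* (trucks, cargo
handling, ships nearby) versus carried in with the *regional background*?

`portair` implements the full chain — synthetic campaign generation,
calibration, validation metrics, lowest-percentile baseline separation, and
spatiotemporal summaries — as a reusable, tested library plus CLI.

## Baseline separation (the core computation)

The measured series is modeled as `C(t) = B(t) + L(t)`: a regional
background `B` that varies slowly (hours to days, driven by meteorology and
mixed transported pollution) and a local signal `L` of short-lived plume
spikes. The lowest-percentile method estimates `B`:

1. **Segment** the series into consecutive 8-h windows anchored at local
   midnight (00–08, 08–16, 16–24). Eight hours tiles the day evenly,
   matches work-shift rhythms, and is long enough that every window almost
   surely contains plume-free moments. Windows with less than
   `min_window_coverage` (default 50%) valid data yield no anchor.
2. **Anchor** each window at its low empirical quantile
   (`anchor_quantile`, default 0.01; quantiles interpolate linearly between
   order statistics). With 480 one-minute samples the 1st percentile sits
   on roughly the 5th-lowest reading — effectively the window minimum but
   robust to isolated negative glitches. Setting the quantile to 0 gives
   the literal minimum. The anchor is placed at the window's center time.
3. **Smooth** the anchors into a continuous curve with a penalized
   regression spline evaluated on the full minute grid, clipped at zero.
   The default smoother is a one-dimensional thin-plate regression spline
   (radial basis `|r|³` plus a linear null space, natural side conditions
   `Σd = 0`, `Σd·x = 0`); a penalized cubic smoothing spline
   (`scipy.interpolate.make_smoothing_spline`) is available behind
   `smoother="penalized_cubic"` — in one dimension the two families have
   the same character. The smoothing parameter is chosen by generalized
   cross-validation, `GCV(λ) = n·RSS(λ)/(n − tr A(λ))²`, over a logarithmic
   grid `λ ∈ 10^[−9, 1]` on the `[0, 1]`-rescaled time axis; a fixed λ can
   be supplied instead (`smoothing_selection="fixed"`), which also makes
   the smoother exactly linear in the anchor values.
4. **Remainder**: `L = C − B`, clipped at zero by default (negative local
   emission is physically meaningless); the unclipped remainder is retained
   (`local_raw`) so that `B + L = C` can be audited exactly.

Contribution fractions are ratios of time means over non-missing samples,
`local% = 100·mean(L)/mean(C)`, because a single percentage per
site/pollutant is the quantity of interest; the alternative mean of
per-minute ratios is available via `fraction_mode="mean_of_ratios"`.

**Assumptions and failure modes.** The method assumes `B` is approximately
constant within one window and that every window contains near-background
moments. At very plume-dense sites the second assumption degrades: events
arrive so often at night that even the window's lowest percentile rides on
overlapping plume tails, inflating night anchors and biasing the local
fraction low by a few percentage points (measured: ≈ −3 to −7 points at the
busiest synthetic sites, well inside the ±10-point recovery band the tests
enforce). The same effect makes the smoothed curve sit above low day-time
anchors; every decomposition therefore reports
`max_anchor_violation_rel` — the largest relative excess of the baseline
over an anchor — as a diagnostic. For background-dominated series it is a
few percent; at busy sites it can reach order one and should be read as a
plume-density warning, not a smoothing failure.

## Calibration and validation metrics

Field calibration is ordinary least squares of the reference concentration
on the raw signal plus temperature and relative humidity,
`ref ~ 1 + raw + T + RH` (statsmodels), fitted per sensor and per pollutant
over a colocation window of at least 48 h of paired data. Calibrated values
clip at zero; missing values propagate. Rank-deficient designs (a constant
covariate) raise a named error. A screening helper warns — never fails —
when a window violates deployment practice (max concentration ≤ 50 ppb,
sustained RH > 80%, temperature outside 5–35 °C). Calibration defaults to
1-h means, the resolution at which sensors are compared to reference
analyzers; minute-level fits are possible but correlate residuals.

Two agreement metrics are implemented exactly in the deployed form:

* `RMSE = sqrt( Σₜ(Sensorₜ − Refₜ)² / (N − 1) )` — note the N−1
  denominator; the difference from the N form vanishes for large N.
* `R² = 1 − Σₜ(Sensorₜ − Refₜ)² / Σₜ(Sensorₜ − R̄ef)²` — the denominator
  centers the *sensor* readings on the mean *reference* reading. This is
  not the textbook coefficient of determination: it can be negative for
  poor fits, and it is undefined (raises) when the sensor is constant at
  the reference mean. The conventional squared Pearson correlation is
  available via `convention="pearson"` as a sanity check.

## The synthetic campaign generator

No public campaign data exist, so `portair.synth` generates networks with
known ground truth; it is first-class, tested code and defines the study
conditions for every recovery test. Per site and pollutant:

* **Background** `max(0, level + A·cos(2π(t − φ)/24h) + AR(1) drift)`.
  Defaults (NO): level 20 μg/m³, diurnal amplitude 0.6 μg/m³ peaking at
  05:30, per-minute AR(1) coefficient 0.99977 (drift correlation time
  ≈ 3 days, stationary SD ≈ 2 μg/m³). The background is deliberately slow
  relative to the 8-h window — the regime the lowest-percentile method is
  built for; its diurnal modulation is small and day-low/night-high.
  NO₂ background: level 32 μg/m³, amplitude 1 μg/m³ peaking at 17:00.
* **Plumes**: an inhomogeneous Poisson process of events, each contributing
  `amp·exp(−Δt/τ)` with τ = 12 min and lognormal amplitudes
  (median ≈ 89 μg/m³, σ_log = 0.8, mean ≈ 123 μg/m³) — sparse, large events,
  so minute NO readings spike to roughly 700–1000 μg/m³ at quiet sites and
  2500–3500 μg/m³ network-wide over three weeks while hourly means stay
  near 1000. Base (daytime) rates fix the zone ordering:
  OA 5.5, SR 4.0, BA 2.2, OR 0.7 events/h.
* **Night ramp**: heavy trucks are restricted to night hours, so event
  intensity climbs linearly from 1× at 22:00 to `night_multiplier`× (default
  5) just before 06:00 and drops back at 06:00. The ramp — rather than a
  flat night window — is what places the diurnal concentration maximum in
  hour 5 by construction: with short-lived plumes a flat window would leave
  all night hours statistically tied and the peak hour would be a seed
  lottery. `night_shape="flat"` restores the uniform window.
* **NO₂ local signal**: the NO plume signal passed through a unit-gain
  first-order lag (default 30 min) and scaled by `oxidation_fraction`
  (default 0.2). This is a modeling stand-in for gradual NO oxidation
  during dispersion, not a chemistry model.
* **Sensor model**: `raw = 0.85·C − 10 + 0.8·T + 0.12·RH + N(0, 2)`.
  Truth channels are clipped at zero; the raw channel is not (real
  electrochemical sensors can read negative).
* **Met**: diurnal temperature sinusoid (18 ± 5 °C, warmest 14:00, clipped
  to 5–35 °C) and anti-phase RH (65 ± 18%, clipped to 20–95%).

The default scenario is 17 sites across the four functional zones of two
terminals (3 OR, 5 SR, 4 OA, 5 BA; sites 7 and 16 colocated with the
reference analyzers) over 21 days. Everything derives from one seed via
spawned per-site streams, so output is bitwise reproducible and independent
of site ordering.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: spatial transport between sites (each
site's background and plumes are independent), wind and sea-breeze effects,
ozone-limited NO₂ chemistry, sensor drift over time, cross-gas
interference, and data gaps from telemetry outages (missingness enters only
through tests that mask values explicitly).

## Other numerical choices

* Timestamps are tz-aware local time (default `Asia/Shanghai`); hour labels
  are interval starts, half-open `[t, t+1h)`.
* Hourly aggregation marks an hour missing when fewer than
  `completeness × 60` minutes are valid (default 0.75, a common regulatory
  convention; the rule is a config knob because deployments differ).
* Missing values are explicit NaN / empty CSV fields, never sentinels.
* Quantiles everywhere interpolate linearly between order statistics; SDs
  use the N−1 denominator.
* Zone statistics pool the member sites' samples by default (a mean of site
  means is available), and NO/NOx ratios are reported at one decimal, the
  granularity at which they are meaningful for such data.
* ppb→μg/m³ conversion uses the ideal-gas molar volume with
  MW(NO) = 30.006, MW(NO₂) = 46.0055 g/mol and
  R = 0.082057 L·atm/(mol·K); at 20 °C and 1 atm the factors round to 1.25
  and 1.91.
* The bundled 17-site campaign statistics table is used as printed input
  for site NOx sums and NO/NOx ratios. Two of its published site-level
  ratios (sites 7 and 1) are not consistent with the table's own means
  (likely produced by a different aggregation); the package computes ratios
  from the means and does not force agreement.

## Problem sizes used in tests

Recovery tests run 20 single-site scenarios of 6 days across plume rates
0.5–6 events/h plus a 7-day plume-free scenario; calibration coverage uses
500 replicates of a 72-h colocation fit; qualitative structure checks run
the full 17-site, 21-day default campaign. These sizes give Monte-Carlo
error comfortably below every asserted tolerance while keeping the whole
suite fast.
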