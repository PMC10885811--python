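# Methods

## Scope and model

`vinegc` computes vineyard canopy conductance to water vapor two ways
and quantifies their agreement.

**Big-leaf estimator.** The canopy is treated as a single leaf whose
conductance is the leaf stomatal conductance g_sw scaled by LAI and
modulated by the energy supply and the evaporative demand:
g_c = LAI·√(g_sw·R_n/VPD). The square-root form keeps the output in
[L·T⁻¹] when g_sw is in m·s⁻¹, and encodes the two dominant controls on
stomatal behavior in a dry summer canopy: opening with available
radiation, closing with atmospheric dryness. The expression is evaluated
verbatim with R_n in MJ·m⁻²·h⁻¹ and VPD in Pa. This unit dialect is part
of the model definition: it is what produces conductances of order
10⁻³ m·s⁻¹ over a vineyard, and an SI-converted variant (differing by
√(10⁶/3600)) is intentionally not provided, to prevent silent
mixed-dialect use.

**Penman–Monteith reference.** The inversion
g_c = γλE_c·g_a / (ΔR_n + k_t·ρ·c_p·VPD·g_a − λ(Δ+γ)E_c) assumes the
measured evapotranspiration is pure canopy transpiration — valid only
when soil evaporation is negligible (drip-irrigated row crops measured
several days after irrigation). Soil heat flux is omitted on the same
grounds. VPD enters here in kPa: the denominator sums ΔR_n
(kPa·°C⁻¹·MJ·m⁻²·h⁻¹-scale) with k_t·ρ·c_p·VPD·g_a, which is only
dimensionally consistent with Δ and γ both in kPa·°C⁻¹. The kPa↔Pa
conversion is always explicit at call boundaries. When the supplied E_c
exceeds the energy/advection bound the denominator turns non-positive
and the inversion raises a "non-invertible regime" error (scalar calls)
or flags the record (batch pipeline) rather than returning a negative
conductance.

**Aerodynamic conductance** uses the neutral-stability logarithmic
profile with d = 2h/3, z_om = 0.123h, z_ov = 0.1z_om. No stability
correction is applied; g_a is strictly linear in wind speed. The
zero-plane displacement is named `d_disp` in code to avoid collision
with Cohen's d.

## Micrometeorological conventions

All FAO-56 primitives treat vapor pressures in kPa. The period
saturation pressure es averages e0 at the period's temperature extremes;
for hourly records without logged extremes the degenerate reduction
t_min = t_max = t_air is used (the only well-defined choice at that
resolution — whether within-hour extremes or instantaneous temperature
should be used is not standardized, so both are supported and the
degenerate form is the default). A negative VPD is passed through with a
logged warning, never clamped; the estimator then flags the record. Air
density is evaluated with pressure in Pa because R = 287 J·kg⁻¹·K⁻¹
yields kg·m⁻³ only on that scale. The molar density of air used for the
porometer unit conversion comes from the ideal-gas law at ambient T and
P rather than a fixed standard value; a fixed value can be supplied
where reproducing a legacy workflow requires it.

## Preprocessing

* Porometer readings in mol·m⁻²·s⁻¹ are divided by the molar density of
  air; readings already in m·s⁻¹ pass through.
* The two canopy sides (east/west ≙ sunlit/shaded depending on hour) are
  averaged unweighted per timestamp; a two-leaf sun/shade weighting is a
  non-goal. Timestamps with one side only are flagged, not dropped.
* The exclusion rule couples a clock window and a radiation floor; both
  are enforced independently (drop if outside [10:00, 18:00], inclusive,
  OR R_n < 0.60 MJ·m⁻²·h⁻¹), the conservative union that guarantees every
  retained record satisfies both conditions. The filter is idempotent and
  every dropped record carries its reason(s).
* Outlier screening flags values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR],
  with quartiles by linear interpolation of the order statistics (the
  most common convention; configurable via any numpy quantile method).
* Alignment floors timestamps to the working cadence (hourly by
  default), averaging minute-cadence meteorology into each bin, then
  inner-joins the three tables; unmatched timestamps are counted in the
  log and an empty join raises.

## Agreement statistics

* |E| is implemented exactly as the aggregate signed-bias percentage
  |Σ(est−obs)|/Σobs·100 — opposite errors cancel. It is not a MAPE, and
  a conventional MAPE is deliberately not substituted.
* The OLS intercept test is two-sided, t-distributed with n−2 df (backed
  by statsmodels). An exact fit has zero residual variance; its p-value
  is reported as NaN with a `perfect_fit` flag, never 0.
* Regression through origin: slope = Σ(obs·est)/Σobs². The companion r
  is, by default, the Pearson correlation between est and the fitted
  values; the uncentered-R² convention is available as an option since
  the no-intercept r convention differs between software packages.
* Cohen's d uses the pooled SD with N−1 sample variances; variances use
  N−1 denominators throughout (CVs included) for consistency.
* U1 non-overlap defaults to linear interpolation of Cohen's published
  table, which is the convention practitioners quote (at d = 0.217 it
  gives 15.8 %, while the exact-normal closed form gives 15.9 %); the
  exact mode (2Φ(|d|/2)−1)/Φ(|d|/2) is available, the two agree within
  0.5 percentage points for |d| ≤ 1, and table mode falls back to the
  exact form with a warning beyond |d| = 4.
* Batch evaluation drops obs/est pairs jointly when either is flagged
  missing, records the surviving n, and reports component statistics
  that are undefined for the data (zero mean, constant series, zero
  pooled variance) as NaN plus a flag instead of aborting.

## Synthetic campaigns

The generator emulates a hot, dry Mediterranean summer measurement day
on a drip-irrigated vineyard, hourly 09:00–19:00:

| parameter | default | meaning |
|---|---|---|
| `rn_peak` | 2.2 MJ·m⁻²·h⁻¹ | half-sine net-radiation peak at the window centre |
| `t_dawn`/`t_peak` | 18 / 36 °C | temperature sinusoid endpoints, peak lagging R_n by `temp_lag_h` = 2 h |
| `rh_dawn`/`rh_min` | 70 / 25 % | humidity mirror of the temperature curve |
| `u_mean` | 2.0 m·s⁻¹ | mean of an hourly lognormal wind draw (σ_log 0.3) |
| `gsw_max` | 0.25 mol·m⁻²·s⁻¹ | unstressed stomatal ceiling |
| `k_r` | 0.5 MJ·m⁻²·h⁻¹ | radiation half-saturation of the stomatal response |
| `d0` | 1.5 kPa | VPD sensitivity of stomatal closure |
| `side_asymmetry` | ±10 % | east boost before solar noon, west after |
| `noise_sd_rel` | 0 | relative SD of mean-one lognormal noise on E_c |
| `model_mismatch_rel` | 0 | relative offset between true g_c and the big-leaf value |

These defaults produce midday VPD near 3.5–4 kPa, stomatal conductance
peaking mid-morning (~0.002 m·s⁻¹) before declining with VPD, canopy
conductance in the 0.5–2.5 ×10⁻³ m·s⁻¹ band and transpiration of a few
tenths of mm·h⁻¹ — the magnitudes of a moderately water-stressed
vineyard. Temperature and humidity share one stretched half-sine so that
VPD rises strictly monotonically from mid-morning to the temperature
peak.

Transpiration is synthesized *from* the big-leaf conductance through the
forward Penman–Monteith relation, so on a noiseless campaign the
estimator and the inverted reference agree identically — an algebraic
round trip that pins down both implementations at once. Because of this
construction, passing tests demonstrate internal consistency, unit
correctness and statistical calibration; they cannot demonstrate that
the big-leaf model fits real vineyard data (the field disagreement is
not replicable without field measurements). `model_mismatch_rel` and
`noise_sd_rel` exist precisely to move the evaluation statistics off the
degenerate perfect fit in a controlled way. Noise is multiplicative
lognormal with mean one (flux errors scale with flux magnitude), driven
by a single seeded `numpy` generator stream; every output is bit-for-bit
reproducible given the seed.

Hours where the generated radiation is exactly zero (the window
endpoints of the half-sine) carry zero stomatal conductance, zero true
canopy conductance and zero flux; they are excluded by the default
daylight filter and, in unfiltered runs, surface as flagged records
rather than errors.

## Numerical and design choices

* Scalar API calls raise typed exceptions on precondition violations;
  the batch pipeline instead marks the record missing with a reason code
  (`vpd_nonpositive`, `rn_negative`, `gsw_negative`, `ga_nonpositive`,
  `ec_negative`, `non_invertible`) — a field pipeline must survive bad
  hours without losing row alignment.
* Round-trip identity forward→invert holds to ~4×10⁻¹⁵ relative in
  practice (tolerance asserted: 1×10⁻¹⁰) over g_c ∈ [10⁻⁴, 10⁻²] m·s⁻¹,
  T ∈ [15, 40] °C, RH ∈ [20, 80] %, R_n ∈ [0.6, 3] MJ·m⁻²·h⁻¹,
  U ∈ [0.5, 5] m·s⁻¹.
* The perfect-fit detector in OLS triggers when the residual sum of
  squares is below 10⁻²⁴ of the response sum of squares.
* CSV numerics are written with 12 significant digits (`%.12g`); the
  write→read round trip is lossless at that precision.
* Problem sizes in the test suite and acceptance script — 5-day
  campaigns (45 analysis records), a 10⁴-point round-trip grid, 1000
  oracle draws per statistic, 2000 intercept-test replicates at n = 30 —
  were chosen so the whole suite completes in seconds while leaving the
  Monte-Carlo assertions comfortable margins (e.g. the type-I rate check
  at 0.05 ± 0.02 has a binomial SE of ~0.005 at 2000 replicates).

## Known limitations

* The big-leaf estimator has no aerodynamic term; it is designed for
  well-coupled, stressed canopies where stomata dominate, and has not
  been exercised under non-stressed or humid conditions.
* No stability correction in g_a; strongly unstable/stable hours are
  outside the intended regime.
* The generator does not model radiation interception, energy-balance
  closure error, or soil evaporation; its side asymmetry is a fixed
  ±10 % contrast, not a radiative-transfer result.
* The inversion is record-wise at whatever cadence is supplied; whether
  sub-hourly inversion then averaging, or averaging then inversion, is
  preferable is left to the user (the two differ under nonlinearity).
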