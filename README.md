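# vinegc — vineyard canopy conductance estimation and validation

Canopy conductance to water vapor (g_c, m·s⁻¹) controls how a grapevine
canopy partitions net radiation into latent and sensible heat, and it is
one of the most water-stress-responsive quantities in a vineyard. The
gold-standard way to obtain it — inverting the Penman–Monteith equation
against eddy-covariance transpiration — needs instrumentation few
growers have. `vinegc` implements a simple big-leaf alternative that
needs only a porometer and a basic weather station, together with the
Penman–Monteith reference it is validated against and the full
model-agreement statistics used for that validation.

The package is aimed at plant ecophysiologists and irrigation scientists
working on row crops in hot, water-limited climates.

## The model

The big-leaf estimator scales leaf stomatal conductance g_sw to the
canopy through the leaf area index and modulates it by the available
energy and the atmospheric demand:

    g_c,est = LAI · ( g_sw · R_n / VPD )^0.5        [m·s⁻¹]

with g_sw in m·s⁻¹ (porometer readings in mol·m⁻²·s⁻¹ are converted via
the molar density of air), R_n the net radiation above the canopy in
MJ·m⁻²·h⁻¹, and VPD the air vapor pressure deficit in **Pa**. The
formula is evaluated in exactly these units; converting R_n and VPD to
SI would rescale the result by √(10⁶/3600) ≈ 16.7 and is deliberately
not offered.

The reference is the inverted Penman–Monteith equation,

    g_c,obs = γ λ E_c g_a / ( Δ R_n + k_t ρ c_p VPD g_a − λ (Δ + γ) E_c )

with E_c the canopy transpiration (mm·h⁻¹, an eddy-covariance flux under
conditions of negligible soil evaporation), g_a the aerodynamic
conductance from the logarithmic wind profile, and Δ, γ, ρ the standard
FAO-56 micrometeorological quantities (VPD in kPa here). The exact
forward relation E_c(g_c) is also provided, which is what makes fully
synthetic, ground-truthed test campaigns possible.

Agreement between the two routes is quantified with RMSE, MAE, an
aggregate relative error |E| = |Σ(est−obs)| / Σobs × 100, Pearson r,
OLS with a t-test on the intercept, regression through the origin,
Cohen's d with pooled SD, the U1 distribution non-overlap, and
coefficients of variation.

## Worked example

Generate a five-day synthetic Mediterranean-summer campaign with 5 %
multiplicative flux noise and a 5 % deliberate model mismatch, run the
full pipeline (unit conversion, canopy-side aggregation, daylight and
radiation exclusion, IQR screen, both conductance computations), and
print the agreement report:

```python
import vinegc
from vinegc import io as vio

params = vinegc.ScenarioParams(seed=7, noise_sd_rel=0.05, model_mismatch_rel=0.05)
camp = vinegc.generate_campaign(params, n_days=5)
bundle = vio.RawDatasetBundle(camp.meteo, camp.leaf, camp.flux, camp.site)
result = vinegc.run_pipeline(bundle)
print(result.report.to_text())
```

```
n = 45
rmse = 0.00014941649491676854
mae = 0.00010090865798269175
rel_err_pct = 4.376920580466455
pearson_r = 0.9828713686058851
ols_intercept = 0.00014551522840557514
ols_slope = 0.8786892600943083
intercept_p = 0.005334801628327104
rto_slope = 0.9488198366268936
rto_r = 0.9828713686058852
cohens_d = 0.14037046071351186
pooled_sd = 0.0005851497144521906
u1_pct = 10.525932249945829
cv_obs = 32.87481953111706
cv_est = 30.73542947588229
flags =
```

Reading it: of the 55 generated hours, 45 survive the 10:00–18:00 /
R_n ≥ 0.60 MJ·m⁻²·h⁻¹ exclusion. The per-record error (RMSE ≈
1.5×10⁻⁴ m·s⁻¹) is an order of magnitude below the conductances
themselves (mean ≈ 1.8×10⁻³ m·s⁻¹), the regression-through-origin slope
0.949 ≈ 1/1.05 recovers the injected 5 % mismatch, and Cohen's
d = 0.14 is a "very small" effect — about 10.5 % of the two conductance
distributions do not overlap. With `noise_sd_rel=0` and
`model_mismatch_rel=0` the report collapses to the exact round trip
(r = 1, slope = 1, RMSE ≈ 1e-19).

The same flow is available from the shell:

```sh
vinegc simulate --seed 7 --days 5 -o campaign/
vinegc pipeline -i campaign/ -o report.csv
```

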