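"""Seeded generator of Mediterranean-summer diurnal vineyard campaigns.

Every other module is testable without field data because this one
produces a physically coherent day: a half-sine net-radiation curve
peaking at the window's centre, an air-temperature sinusoid lagging the
radiation peak, relative humidity mirroring temperature (so VPD rises
monotonically through the afternoon), lognormal wind speed around a mean,
a multiplicative light x VPD stomatal response (conductance peaks
mid-morning, then declines as the air dries), and canopy transpiration
computed from the forward Penman-Monteith relation at a known ("true")
canopy conductance.

Because transpiration is synthesized *from* the big-leaf conductance via
the forward Penman-Monteith equation, the estimator and the inverted
reference agree exactly on a noiseless campaign — a round trip that pins
down both computations. ``model_mismatch_rel`` injects a controlled
relative disagreement between the true conductance and the big-leaf
value, and ``noise_sd_rel`` applies mean-one multiplicative lognormal
noise to the flux, so the evaluation statistics can be exercised away
from the degenerate perfect fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canopy_flux import (
    STUDY_SITE,
    SiteParams,
    aerodynamic_conductance,
    estimate_canopy_conductance,
    forward_penman_monteith,
)
from .exceptions import ConfigurationError
from .micromet import (
    DEFAULT_CONSTANTS,
    PhysicalConstants,
    molar_density_air,
    vapor_pressure_deficit,
)

__all__ = ["ScenarioParams", "Campaign", "diurnal_meteo", "jarvis_gsw", "generate_campaign"]


@dataclass(frozen=True)
class ScenarioParams:
    """Shape parameters of one synthetic campaign day.

    Defaults emulate a hot, dry mid-summer vineyard day: measurements
    from 09:00 to 19:00 hourly, net radiation peaking at 2.2 MJ m-2 h-1,
    temperature climbing from 18 to 36 degC with a 2 h lag behind the
    radiation peak, humidity falling from 70 to 25 %, 2 m s-1 mean wind,
    a maximal stomatal conductance of 0.25 mol m-2 s-1 with radiation
    half-saturation at 0.5 MJ m-2 h-1 and VPD sensitivity 1.5 kPa.
    """

    window_start: int = 9
    window_end: int = 19
    rn_peak: float = 2.2
    t_dawn: float = 18.0
    t_peak: float = 36.0
    rh_dawn: float = 70.0
    rh_min: float = 25.0
    u_mean: float = 2.0
    u_sigma_log: float = 0.3
    gsw_max: float = 0.25
    k_r: float = 0.5
    d0: float = 1.5
    temp_lag_h: float = 2.0
    side_asymmetry: float = 0.10
    noise_sd_rel: float = 0.0
    model_mismatch_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.window_start < self.window_end <= 23:
            raise ConfigurationError("need 0 <= window_start < window_end <= 23")
        for name in ("rn_peak", "u_mean", "gsw_max", "k_r", "d0"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0 < self.rh_min < self.rh_dawn <= 100):
            raise ConfigurationError("need 0 < rh_min < rh_dawn <= 100")
        if self.t_dawn >= self.t_peak:
            raise ConfigurationError("t_dawn must be below t_peak")
        if self.noise_sd_rel < 0 or not -0.9 <= self.model_mismatch_rel:
            raise ConfigurationError("noise_sd_rel >= 0 and model_mismatch_rel > -0.9 required")


def diurnal_meteo(
    params: ScenarioParams,
    date: str = "2021-07-08",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One day of hourly above-canopy weather for the scenario window.

    Net radiation follows a half-sine vanishing at the window ends and
    peaking at its centre (solar noon for this window); air temperature
    follows a stretched sinusoid whose maximum lags the radiation peak by
    ``temp_lag_h`` hours; relative humidity mirrors temperature between
    ``rh_dawn`` and ``rh_min``; wind speed is drawn hourly from a
    mean-``u_mean`` lognormal. Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    hours = np.arange(params.window_start, params.window_end + 1)
    span = params.window_end - params.window_start

    rn = params.rn_peak * np.sin(np.pi * (hours - params.window_start) / span)
    rn = np.clip(rn, 0.0, None)

    # same half-sine family, period stretched so the peak trails by the lag
    frac = np.sin(np.pi * (hours - params.window_start) / (span + 2 * params.temp_lag_h))
    frac = np.clip(frac, 0.0, 1.0)
    t_air = params.t_dawn + (params.t_peak - params.t_dawn) * frac
    rh = params.rh_dawn - (params.rh_dawn - params.rh_min) * frac

    mu = np.log(params.u_mean) - params.u_sigma_log**2 / 2.0
    u = rng.lognormal(mu, params.u_sigma_log, size=hours.size)

    ts = pd.Timestamp(date) + pd.to_timedelta(hours, unit="h")
    return pd.DataFrame(
        {
            "timestamp": ts,
            "t_air_c": t_air,
            "rh_pct": rh,
            "rn_mj_m2_h": rn,
            "u_m_s": u,
        }
    )


def jarvis_gsw(rn, vpd_kpa, params: ScenarioParams) -> float | np.ndarray:
    """Multiplicative light x VPD stomatal response, mol m-2 s-1.

    ``gsw_max * rn/(rn + k_r) * 1/(1 + vpd/d0)`` — saturating in
    radiation, declining hyperbolically with atmospheric demand, bounded
    by ``gsw_max``. Both factors equal one half at their half-saturation
    constants.
    """
    rn_arr = np.asarray(rn, dtype=float)
    vpd_arr = np.asarray(vpd_kpa, dtype=float)
    out = (
        params.gsw_max
        * (rn_arr / (rn_arr + params.k_r))
        * (1.0 / (1.0 + vpd_arr / params.d0))
    )
    if np.ndim(rn) == 0 and np.ndim(vpd_kpa) == 0:
        return float(out)
    return out


@dataclass
class Campaign:
    """Raw synthetic dataset: the three input tables plus the ground truth."""

    meteo: pd.DataFrame
    leaf: pd.DataFrame
    flux: pd.DataFrame
    truth: pd.DataFrame
    params: ScenarioParams
    site: SiteParams


def generate_campaign(
    params: ScenarioParams = ScenarioParams(),
    n_days: int = 1,
    site: SiteParams = STUDY_SITE,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    start_date: str = "2021-07-08",
) -> Campaign:
    """Generate an ``n_days`` campaign with known true canopy conductance.

    Per hour: the stomatal conductance from :func:`jarvis_gsw` is split
    into an east and a west sample with a fixed +/-``side_asymmetry``
    contrast (east boosted before solar noon, west after — the
    sun-exposure pattern of north-south rows) whose mean preserves the
    canopy value; the true conductance is ``(1 + model_mismatch_rel)``
    times the big-leaf estimate; transpiration is the forward
    Penman-Monteith flux at that true conductance, optionally degraded
    by mean-one lognormal noise of relative sd ``noise_sd_rel``.

    Leaf samples are emitted in mol m-2 s-1 so the preprocessing unit
    conversion is exercised end-to-end.
    """
    if n_days < 1:
        raise ConfigurationError(f"n_days must be >= 1, got {n_days}")
    rng = np.random.default_rng(params.seed)
    noon = (params.window_start + params.window_end) / 2.0
    sigma = float(np.sqrt(np.log1p(params.noise_sd_rel**2)))

    met_frames = []
    leaf_rows = []
    flux_rows = []
    truth_rows = []
    for day in range(n_days):
        date = (pd.Timestamp(start_date) + pd.Timedelta(days=day)).strftime("%Y-%m-%d")
        met = diurnal_meteo(params, date=date, rng=rng)
        met_frames.append(met)
        for row in met.itertuples(index=False):
            t, rh, rn, u = row.t_air_c, row.rh_pct, row.rn_mj_m2_h, row.u_m_s
            vpd_kpa = vapor_pressure_deficit(t, t, t, rh)
            gsw_mol = jarvis_gsw(rn, vpd_kpa, params)
            boost = params.side_asymmetry if row.timestamp.hour < noon else -params.side_asymmetry
            leaf_rows.append((row.timestamp, "east", gsw_mol * (1 + boost), "mol_m2_s"))
            leaf_rows.append((row.timestamp, "west", gsw_mol * (1 - boost), "mol_m2_s"))

            gsw_ms = gsw_mol / molar_density_air(t, site.pressure, constants)
            if vpd_kpa > 0 and rn > 0 and gsw_ms > 0:
                gc_true = (1.0 + params.model_mismatch_rel) * estimate_canopy_conductance(
                    site.lai, gsw_ms, rn, vpd_kpa * 1000.0
                )
            else:
                gc_true = 0.0
            if gc_true > 0 and u > 0:
                ga = aerodynamic_conductance(u, site, constants)
                ec = forward_penman_monteith(gc_true, rn, vpd_kpa, t, site, ga, constants)
            else:
                ec = 0.0
            if params.noise_sd_rel > 0:
                ec *= rng.lognormal(-sigma**2 / 2.0, sigma)
            flux_rows.append((row.timestamp, ec))
            truth_rows.append((row.timestamp, gc_true))

    return Campaign(
        meteo=pd.concat(met_frames, ignore_index=True),
        leaf=pd.DataFrame(leaf_rows, columns=["timestamp", "side", "gsw_value", "gsw_unit"]),
        flux=pd.DataFrame(flux_rows, columns=["timestamp", "ec_mm_h"]),
        truth=pd.DataFrame(truth_rows, columns=["timestamp", "gc_true_m_s"]),
        params=params,
        site=site,
    )
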