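"""Canopy-scale conductance and transpiration computations.

Two routes to canopy conductance (g_c, m s-1) live here:

* the **big-leaf estimator** — leaf stomatal conductance scaled to the
  canopy by LAI and modulated by the available energy and the atmospheric
  demand, ``g_c = LAI * sqrt(g_sw * R_n / VPD)``, with g_sw in m s-1,
  R_n in MJ m-2 h-1 and VPD in **Pa**;
* the **inverted Penman-Monteith** reference, which recovers g_c from
  measured canopy transpiration E_c (mm h-1), net radiation, VPD (in
  **kPa** here — dimensional consistency with Delta and gamma requires
  it), air temperature and the aerodynamic conductance g_a.

The forward Penman-Monteith transpiration (the exact algebraic inverse of
the reference) is provided for synthesis and round-trip testing.

A note on the estimator's unit dialect: it is evaluated verbatim with
R_n in MJ m-2 h-1 and VPD in Pa because that recipe reproduces the
observed g_c magnitudes (order 1e-3 m s-1 over a vineyard); converting
R_n and VPD to SI (W m-2, kPa) would rescale the output by
sqrt(1e6/3600) ~ 16.7 and is deliberately NOT offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from . import micromet
from .exceptions import (
    ConfigurationError,
    EmptySeriesError,
    InvalidInputError,
    NonInvertibleError,
)
from .micromet import DEFAULT_CONSTANTS, PhysicalConstants, _asarray, _scalar_or_array

__all__ = [
    "SiteParams",
    "STUDY_SITE",
    "ConductanceSeries",
    "aerodynamic_conductance",
    "estimate_canopy_conductance",
    "invert_penman_monteith",
    "forward_penman_monteith",
    "conductance_pipeline",
]

Provenance = Literal["estimated", "observed", "true_synthetic"]


@dataclass(frozen=True)
class SiteParams:
    """Site and canopy geometry.

    Defaults are the study configuration of a vertically shoot-positioned
    vineyard: sensors at ``z_m`` = 3.0 m, canopy height ``h`` = 1.7 m,
    mean LAI 1.96 m2 m-2, elevation 220 m. Atmospheric pressure defaults
    to the barometric value at the site elevation.

    Roughness parameters derive from canopy height: zero-plane
    displacement ``d_disp = 2h/3``, momentum roughness length
    ``z_om = 0.123 h`` and vapor roughness length ``z_ov = 0.1 z_om``.
    The measurement height must sit above ``d_disp + z_om``.
    """

    elevation: float = 220.0
    z_m: float = 3.0
    h: float = 1.7
    lai: float = 1.96
    pressure: float | None = None

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ConfigurationError(f"canopy height must be > 0 m, got {self.h}")
        if self.lai <= 0:
            raise ConfigurationError(f"LAI must be > 0, got {self.lai}")
        if self.pressure is None:
            object.__setattr__(
                self, "pressure", micromet.pressure_from_elevation(self.elevation)
            )
        if self.pressure <= 0:
            raise ConfigurationError(f"pressure must be > 0 kPa, got {self.pressure}")
        if self.z_m <= self.d_disp + self.z_om:
            raise ConfigurationError(
                "sensor below roughness sublayer: "
                f"z_m={self.z_m} m must exceed d + z_om = {self.d_disp + self.z_om:.4g} m"
            )

    @property
    def d_disp(self) -> float:
        """Zero-plane displacement height, m (2h/3)."""
        return 2.0 * self.h / 3.0

    @property
    def z_om(self) -> float:
        """Roughness length for momentum transfer, m (0.123 h)."""
        return 0.123 * self.h

    @property
    def z_ov(self) -> float:
        """Roughness length for water-vapor transfer, m (0.1 z_om)."""
        return 0.1 * self.z_om


STUDY_SITE = SiteParams()


@dataclass
class ConductanceSeries:
    """A timestamped canopy-conductance series with provenance.

    ``values`` are in m s-1; records that failed a precondition carry NaN
    and a reason code in ``qc`` (valid records carry ``"ok"``).
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    provenance: Provenance
    qc: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if self.qc is None:
            self.qc = np.full(len(self.values), "ok", dtype=object)
        self.qc = np.asarray(self.qc, dtype=object)
        if not (len(self.timestamps) == len(self.values) == len(self.qc)):
            raise InvalidInputError("timestamps, values and qc must share one length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "gc_m_s": self.values,
                "provenance": self.provenance,
                "qc_flag": self.qc,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: Provenance | None = None):
        prov = provenance or (df["provenance"].iloc[0] if len(df) else "observed")
        qc = df["qc_flag"].to_numpy(dtype=object) if "qc_flag" in df else None
        return cls(df["timestamp"], df["gc_m_s"].to_numpy(dtype=float), prov, qc)


def aerodynamic_conductance(
    u,
    site: SiteParams = STUDY_SITE,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Aerodynamic conductance g_a (m s-1) from the logarithmic wind profile.

    ``g_a = k^2 u / ( ln((z_m - d)/z_om) * ln((z_m - d)/z_ov) )`` —
    linear in wind speed ``u``; zero wind gives zero conductance (calm
    air transfers no momentum in this neutral-stability form).
    """
    u_arr = _asarray(u, "u")
    if np.any(u_arr < 0):
        raise InvalidInputError(f"wind speed must be >= 0, got {u!r}")
    zd = site.z_m - site.d_disp
    denom = np.log(zd / site.z_om) * np.log(zd / site.z_ov)
    ga = constants.k_vonkarman**2 * u_arr / denom
    return _scalar_or_array(ga, u)


def estimate_canopy_conductance(lai, g_sw, rn, vpd_pa):
    """Big-leaf canopy conductance estimate, m s-1.

    ``g_c = LAI * sqrt(g_sw * R_n / VPD)`` with g_sw in m s-1, R_n in
    MJ m-2 h-1 and VPD in Pa (see the module docstring on this unit
    dialect). Strictly increasing in LAI, g_sw and R_n; strictly
    decreasing in VPD; homogeneous of degree 1/2 in g_sw.
    """
    lai_arr = _asarray(lai, "lai")
    gsw_arr = _asarray(g_sw, "g_sw")
    rn_arr = _asarray(rn, "rn")
    vpd_arr = _asarray(vpd_pa, "vpd_pa")
    if np.any(lai_arr <= 0):
        raise InvalidInputError(f"lai must be > 0, got {lai!r}")
    if np.any(vpd_arr <= 0):
        raise InvalidInputError(f"vpd_pa must be > 0 Pa, got {vpd_pa!r}")
    if np.any(gsw_arr < 0):
        raise InvalidInputError(f"g_sw must be >= 0, got {g_sw!r}")
    if np.any(rn_arr < 0):
        raise InvalidInputError(f"rn must be >= 0, got {rn!r}")
    gc = lai_arr * np.sqrt(gsw_arr * rn_arr / vpd_arr)
    return _scalar_or_array(gc, lai, g_sw, rn, vpd_pa)


def _pm_terms(t_air, vpd_kpa, site, constants):
    delta = micromet.slope_vapor_pressure_curve(t_air)
    gamma = micromet.psychrometric_constant(site.pressure, constants)
    rho = micromet.air_density(t_air, site.pressure, constants)
    return np.asarray(delta), np.asarray(gamma), np.asarray(rho)


def invert_penman_monteith(
    e_c,
    rn,
    vpd_kpa,
    t_air,
    site: SiteParams = STUDY_SITE,
    g_a=None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Canopy conductance (m s-1) by inverting the Penman-Monteith equation.

    ``g_c = gamma lambda E_c g_a / (Delta R_n + kt rho cp VPD g_a
    - lambda (Delta + gamma) E_c)`` with E_c in mm h-1, R_n in
    MJ m-2 h-1 and VPD in kPa. Soil heat flux is omitted: the method is
    meant for conditions with negligible soil evaporation, where measured
    evapotranspiration proxies canopy transpiration.

    Raises :class:`NonInvertibleError` when the denominator is
    non-positive, i.e. the supplied transpiration exceeds what the
    available energy and advection can sustain at these inputs.
    """
    ec_arr = _asarray(e_c, "e_c")
    rn_arr = _asarray(rn, "rn")
    vpd_arr = _asarray(vpd_kpa, "vpd_kpa")
    if np.any(ec_arr < 0):
        raise InvalidInputError(f"e_c must be >= 0 mm h-1, got {e_c!r}")
    if g_a is None:
        raise InvalidInputError("g_a is required")
    ga_arr = _asarray(g_a, "g_a")
    if np.any(ga_arr <= 0):
        raise InvalidInputError(f"g_a must be > 0 m s-1, got {g_a!r}")
    delta, gamma, rho = _pm_terms(t_air, vpd_arr, site, constants)
    lam, cp, kt = constants.lambda_vap, constants.cp, constants.kt
    denom = delta * rn_arr + kt * rho * cp * vpd_arr * ga_arr - lam * (delta + gamma) * ec_arr
    if np.any(denom <= 0):
        raise NonInvertibleError(
            "non-invertible regime: transpiration exceeds the energy/advection "
            "bound for these inputs (denominator <= 0)"
        )
    gc = gamma * lam * ec_arr * ga_arr / denom
    return _scalar_or_array(gc, e_c, rn, vpd_kpa, t_air, g_a)


def forward_penman_monteith(
    g_c,
    rn,
    vpd_kpa,
    t_air,
    site: SiteParams = STUDY_SITE,
    g_a=None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Canopy transpiration E_c (mm h-1) from the Penman-Monteith equation.

    ``E_c = (Delta R_n + kt rho cp VPD g_a) /
    (lambda (Delta + gamma (1 + g_a/g_c)))`` — the exact algebraic
    inverse of :func:`invert_penman_monteith`, strictly increasing in
    g_c at fixed meteorology. Used to synthesize transpiration consistent
    with a known canopy conductance.
    """
    gc_arr = _asarray(g_c, "g_c")
    rn_arr = _asarray(rn, "rn")
    vpd_arr = _asarray(vpd_kpa, "vpd_kpa")
    if np.any(gc_arr <= 0):
        raise InvalidInputError(f"g_c must be > 0 m s-1, got {g_c!r}")
    if g_a is None:
        raise InvalidInputError("g_a is required")
    ga_arr = _asarray(g_a, "g_a")
    if np.any(ga_arr <= 0):
        raise InvalidInputError(f"g_a must be > 0 m s-1, got {g_a!r}")
    delta, gamma, rho = _pm_terms(t_air, vpd_arr, site, constants)
    lam, cp, kt = constants.lambda_vap, constants.cp, constants.kt
    num = delta * rn_arr + kt * rho * cp * vpd_arr * ga_arr
    den = lam * (delta + gamma * (1.0 + ga_arr / gc_arr))
    return _scalar_or_array(num / den, g_c, rn, vpd_kpa, t_air, g_a)


#: qc reason codes emitted by the batch pipeline, in check order.
QC_REASONS = (
    "vpd_nonpositive",
    "rn_negative",
    "gsw_negative",
    "ga_nonpositive",
    "ec_negative",
    "non_invertible",
)


def conductance_pipeline(
    aligned: pd.DataFrame,
    site: SiteParams = STUDY_SITE,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    which: Literal["both", "estimated", "observed"] = "both",
) -> tuple[ConductanceSeries, ConductanceSeries]:
    """Apply both conductance computations record-wise to an aligned table.

    ``aligned`` must carry ``timestamp, t_air_c, rh_pct, rn_mj_m2_h,
    u_m_s`` plus ``gsw_m_s`` (for the estimate) and ``ec_mm_h`` (for the
    reference). Records violating any precondition are marked missing
    (NaN) with a reason code, never dropped, so the two outputs stay
    aligned with the input. Single-value calls to the underlying
    operations raise instead; batch mode must survive bad hours.
    """
    if len(aligned) == 0:
        raise EmptySeriesError("aligned input table is empty")
    need = {"timestamp", "t_air_c", "rh_pct", "rn_mj_m2_h", "u_m_s"}
    if which in ("both", "estimated"):
        need.add("gsw_m_s")
    if which in ("both", "observed"):
        need.add("ec_mm_h")
    missing = need - set(aligned.columns)
    if missing:
        raise InvalidInputError(f"aligned table missing column(s): {sorted(missing)}")

    n = len(aligned)
    est = np.full(n, np.nan)
    obs = np.full(n, np.nan)
    qc = np.full(n, "ok", dtype=object)

    for i, row in enumerate(aligned.itertuples(index=False)):
        t = row.t_air_c
        rn = row.rn_mj_m2_h
        vpd_kpa = micromet.vapor_pressure_deficit(t, t, t, row.rh_pct)
        ga = aerodynamic_conductance(row.u_m_s, site, constants)
        gsw = getattr(row, "gsw_m_s", np.nan)
        ec = getattr(row, "ec_mm_h", np.nan)

        if vpd_kpa <= 0:
            qc[i] = "vpd_nonpositive"
            continue
        if rn < 0:
            qc[i] = "rn_negative"
            continue
        if which in ("both", "estimated"):
            if gsw < 0:
                qc[i] = "gsw_negative"
                continue
            est[i] = estimate_canopy_conductance(site.lai, gsw, rn, vpd_kpa * 1000.0)
        if which in ("both", "observed"):
            if ga <= 0:
                qc[i] = "ga_nonpositive"
                continue
            if ec < 0:
                qc[i] = "ec_negative"
                continue
            try:
                obs[i] = invert_penman_monteith(
                    ec, rn, vpd_kpa, t, site, ga, constants
                )
            except NonInvertibleError:
                qc[i] = "non_invertible"

    ts = pd.DatetimeIndex(aligned["timestamp"])
    return (
        ConductanceSeries(ts, est, "estimated", qc.copy()),
        ConductanceSeries(ts, obs, "observed", qc.copy()),
    )
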