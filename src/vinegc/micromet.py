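"""Closed-form atmospheric primitives (FAO-56 conventions).

These are the standard micrometeorological building blocks used throughout
the package: saturation and actual vapor pressure, vapor pressure deficit
(VPD), the slope of the saturation curve, the psychrometric constant, air
density, barometric pressure from elevation, and the molar density of air.

Unit conventions
----------------
All vapor pressures are handled in **kPa** internally; the big-leaf canopy
conductance estimator consumes VPD in **Pa**, produced by the explicit
:func:`vapor_pressure_deficit_pa` converter (x1000), never implicitly.
Air density is evaluated with pressure in Pa because the specific gas
constant of dry air (287 J kg-1 K-1) yields kg m-3 only on that scale.

All functions accept scalars or numpy arrays and are pure; invalid inputs
raise :class:`~vinegc.exceptions.InvalidInputError`. A negative VPD
(supersaturation artifact, possible when ``t_air < t_max`` at high RH) is
returned as-is with a logged warning, never clamped: silent clamping would
hide data problems upstream of the conductance estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "PhysicalConstants",
    "DEFAULT_CONSTANTS",
    "saturation_vapor_pressure",
    "actual_vapor_pressure",
    "mean_saturation_vapor_pressure",
    "vapor_pressure_deficit",
    "vapor_pressure_deficit_pa",
    "slope_vapor_pressure_curve",
    "psychrometric_constant",
    "air_density",
    "pressure_from_elevation",
    "molar_density_air",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the conductance computations.

    Attributes
    ----------
    k_vonkarman :
        von Karman constant (dimensionless).
    lambda_vap :
        Latent heat of vaporization of water, MJ kg-1.
    cp :
        Specific heat of dry air at constant pressure, MJ kg-1 degC-1.
    epsilon :
        Ratio of molecular weights, water vapor over dry air.
    r_gas :
        Specific gas constant of dry air, J kg-1 K-1.
    kt :
        Time unit conversion, s h-1.
    r_universal :
        Universal gas constant, J mol-1 K-1 (used for the molar density
        of air in the stomatal-conductance unit conversion).
    """

    k_vonkarman: float = 0.41
    lambda_vap: float = 2.45
    cp: float = 0.001013
    epsilon: float = 0.622
    r_gas: float = 287.0
    kt: float = 3600.0
    r_universal: float = 8.314

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidInputError(
                    f"physical constant {f.name!r} must be finite and > 0, got {value!r}"
                )


DEFAULT_CONSTANTS = PhysicalConstants()


def _asarray(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite, got {x!r}")
    return arr


def _scalar_or_array(result: np.ndarray, *inputs) -> float | np.ndarray:
    if np.ndim(result) == 0 and all(np.ndim(i) == 0 for i in inputs):
        return float(result)
    return result


def saturation_vapor_pressure(t_air):
    """Saturation vapor pressure e0(T) in kPa at air temperature ``t_air`` (degC).

    Tetens-form exponential: ``0.6108 * exp(17.27 T / (T + 237.3))``.
    Strictly positive and strictly increasing in temperature.
    """
    t = _asarray(t_air, "t_air")
    if np.any(t <= -237.3):
        raise InvalidInputError("t_air must exceed -237.3 degC")
    e0 = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return _scalar_or_array(e0, t_air)


def actual_vapor_pressure(t_air, rh):
    """Actual vapor pressure ea in kPa from temperature (degC) and RH (%)."""
    rh_arr = _asarray(rh, "rh")
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise InvalidInputError(f"rh must lie in [0, 100] %, got {rh!r}")
    ea = saturation_vapor_pressure(t_air) * rh_arr / 100.0
    return _scalar_or_array(np.asarray(ea), t_air, rh)


def mean_saturation_vapor_pressure(t_min, t_max):
    """Mean saturation vapor pressure es in kPa over a period.

    Average of e0 at the period's minimum and maximum temperature; for
    hourly records without logged extremes pass ``t_min = t_max = t_air``,
    which reduces es to e0(t_air).
    """
    tmin = _asarray(t_min, "t_min")
    tmax = _asarray(t_max, "t_max")
    if np.any(tmin > tmax):
        raise InvalidInputError("t_min must not exceed t_max")
    es = (saturation_vapor_pressure(tmin) + saturation_vapor_pressure(tmax)) / 2.0
    return _scalar_or_array(np.asarray(es), t_min, t_max)


def vapor_pressure_deficit(t_min, t_max, t_air, rh):
    """Vapor pressure deficit VPD = es - ea in kPa.

    ``es`` comes from the period extremes, ``ea`` from the instantaneous
    temperature and relative humidity. A negative result is possible when
    ``t_air < t_max`` under humid air; it is returned unmodified with a
    warning so that downstream consumers (which require VPD > 0) can flag
    the record explicitly.
    """
    es = mean_saturation_vapor_pressure(t_min, t_max)
    ea = actual_vapor_pressure(t_air, rh)
    vpd = np.asarray(es) - np.asarray(ea)
    if np.any(vpd < 0):
        logger.warning(
            "negative VPD encountered (min %.4g kPa): supersaturation artifact, not clamped",
            float(np.min(vpd)),
        )
    return _scalar_or_array(vpd, t_min, t_max, t_air, rh)


def vapor_pressure_deficit_pa(t_min, t_max, t_air, rh):
    """Companion of :func:`vapor_pressure_deficit` returning Pa (x1000)."""
    vpd = vapor_pressure_deficit(t_min, t_max, t_air, rh)
    return _scalar_or_array(np.asarray(vpd) * 1000.0, t_min, t_max, t_air, rh)


def slope_vapor_pressure_curve(t_air):
    """Slope Delta of the saturation vapor pressure curve, kPa degC-1.

    ``4098 e0(T) / (T + 237.3)^2``; strictly positive.
    """
    t = _asarray(t_air, "t_air")
    if np.any(t <= -237.3):
        raise InvalidInputError("t_air must exceed -237.3 degC")
    delta = 4098.0 * 0.6108 * np.exp(17.27 * t / (t + 237.3)) / (t + 237.3) ** 2
    return _scalar_or_array(delta, t_air)


def psychrometric_constant(p, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Psychrometric constant gamma = cp P / (epsilon lambda), kPa degC-1.

    ``p`` is atmospheric pressure in kPa; gamma is exactly linear in p.
    """
    p_arr = _asarray(p, "p")
    if np.any(p_arr <= 0):
        raise InvalidInputError(f"pressure must be > 0 kPa, got {p!r}")
    gamma = constants.cp * p_arr / (constants.epsilon * constants.lambda_vap)
    return _scalar_or_array(gamma, p)


def air_density(t_air, p, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Moist air density rho in kg m-3 at temperature (degC) and pressure (kPa).

    ``rho = P / (1.01 (T + 273.3) R)`` with P in Pa; decreasing in
    temperature, linear in pressure.
    """
    t = _asarray(t_air, "t_air")
    p_arr = _asarray(p, "p")
    if np.any(p_arr <= 0):
        raise InvalidInputError(f"pressure must be > 0 kPa, got {p!r}")
    if np.any(t <= -273.3):
        raise InvalidInputError("t_air must exceed -273.3 degC")
    rho = (p_arr * 1000.0) / (1.01 * (t + 273.3) * constants.r_gas)
    return _scalar_or_array(rho, t_air, p)


def pressure_from_elevation(z):
    """Barometric pressure in kPa from elevation ``z`` (m above sea level).

    ``101.3 ((293 - 0.0065 z) / 293)^5.26`` — the standard-atmosphere
    profile; 101.3 kPa at sea level, monotone decreasing with elevation.
    """
    z_arr = _asarray(z, "z")
    if np.any((z_arr < 0) | (z_arr >= 11000)):
        raise InvalidInputError(f"elevation must lie in [0, 11000) m, got {z!r}")
    p = 101.3 * ((293.0 - 0.0065 * z_arr) / 293.0) ** 5.26
    return _scalar_or_array(p, z)


def molar_density_air(t_air, p, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Molar density of air in mol m-3 by the ideal-gas law.

    ``n/V = P / (R_u (T + 273.15))`` with P in Pa. Evaluated at ambient
    temperature and pressure rather than a fixed standard value (about
    41.6 mol m-3 at 0 degC, 39.8 mol m-3 at 25 degC and 98.7 kPa); callers
    that prefer a fixed molar density can pass one directly to the
    stomatal-conductance unit converter.
    """
    t = _asarray(t_air, "t_air")
    p_arr = _asarray(p, "p")
    if np.any(p_arr <= 0):
        raise InvalidInputError(f"pressure must be > 0 kPa, got {p!r}")
    if np.any(t <= -273.15):
        raise InvalidInputError("t_air must exceed -273.15 degC")
    n = (p_arr * 1000.0) / (constants.r_universal * (t + 273.15))
    return _scalar_or_array(n, t_air, p)
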