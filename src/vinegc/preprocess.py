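"""Data conditioning ahead of the conductance computations.

Covers the campaign's quality rules: stomatal-conductance unit conversion
(mol m-2 s-1 -> m s-1 via the molar density of air), aggregation of the
two canopy sides to one leaf-level series, the daylight/radiation
exclusion window (records before 10:00 or after 18:00, or with net
radiation below 0.60 MJ m-2 h-1, are dropped), the 1.5 x IQR outlier
screen, and timestamp alignment of the meteorological, leaf and flux
tables.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    EmptySeriesError,
    InsufficientDataError,
    InvalidInputError,
)
from .micromet import DEFAULT_CONSTANTS, PhysicalConstants, molar_density_air

__all__ = [
    "FilterConfig",
    "gsw_to_ms",
    "aggregate_leaf_conductance",
    "daylight_radiation_filter",
    "iqr_outlier_mask",
    "align",
]

logger = logging.getLogger(__name__)

LEAF_UNITS = ("mol_m2_s", "m_s")


@dataclass(frozen=True)
class FilterConfig:
    """Record-exclusion rules.

    The clock window and the radiation floor are enforced independently
    (drop if outside [window_start, window_end] OR R_n < rn_min), the
    conservative union of the two stated exclusion conditions; window
    bounds are inclusive.
    """

    window_start: dt.time = dt.time(10, 0)
    window_end: dt.time = dt.time(18, 0)
    rn_min: float = 0.60
    iqr_k: float = 1.5

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ConfigurationError("window_start must precede window_end")
        if self.rn_min < 0:
            raise ConfigurationError(f"rn_min must be >= 0, got {self.rn_min}")
        if self.iqr_k <= 0:
            raise ConfigurationError(f"iqr_k must be > 0, got {self.iqr_k}")


def gsw_to_ms(
    value,
    unit: str,
    t_air,
    p,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    molar_density: float | None = None,
):
    """Convert a stomatal-conductance reading to m s-1.

    Readings already in ``m_s`` pass through unchanged; ``mol_m2_s``
    readings are divided by the molar density of air at the record's
    temperature and pressure (or by ``molar_density`` if a fixed value
    is preferred). Homogeneous of degree 1 in the reading.
    """
    if unit not in LEAF_UNITS:
        raise InvalidInputError(f"unknown g_sw unit {unit!r}; expected one of {LEAF_UNITS}")
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError(f"g_sw value must be finite and >= 0, got {value!r}")
    if unit == "m_s":
        return value if np.ndim(value) else float(arr)
    n_mol = molar_density if molar_density is not None else molar_density_air(t_air, p, constants)
    out = arr / n_mol
    return float(out) if np.ndim(out) == 0 else out


def aggregate_leaf_conductance(
    leaf: pd.DataFrame,
    meteo: pd.DataFrame,
    pressure: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    cadence: str = "h",
    molar_density: float | None = None,
) -> pd.DataFrame:
    """Mean leaf conductance per timestamp, in m s-1.

    Samples are converted with :func:`gsw_to_ms` (air temperature looked
    up from ``meteo`` at the same cadence) and averaged arithmetically
    across all samples sharing a timestamp — the canopy sides enter
    unweighted. Returns ``timestamp, gsw_m_s, n_samples, qc_flag`` where
    ``qc_flag`` is ``one_side_only`` when a single side contributed and
    ``no_meteo`` rows are excluded with a log entry.
    """
    if len(leaf) == 0:
        raise EmptySeriesError("leaf table is empty")
    lf = leaf.copy()
    lf["timestamp"] = pd.DatetimeIndex(lf["timestamp"]).floor(cadence)
    met = meteo[["timestamp", "t_air_c"]].copy()
    met["timestamp"] = pd.DatetimeIndex(met["timestamp"]).floor(cadence)
    met = met.groupby("timestamp", as_index=False)["t_air_c"].mean()
    lf = lf.merge(met, on="timestamp", how="left")

    no_met = lf["t_air_c"].isna() & (lf["gsw_unit"] == "mol_m2_s")
    if no_met.any():
        logger.warning(
            "%d leaf sample(s) lack a meteo record for unit conversion; excluded",
            int(no_met.sum()),
        )
        lf = lf[~no_met]
    if len(lf) == 0:
        raise EmptySeriesError("no leaf samples left after meteo matching")

    lf["gsw_m_s"] = [
        gsw_to_ms(v, u, t, pressure, constants, molar_density)
        for v, u, t in zip(lf["gsw_value"], lf["gsw_unit"], lf["t_air_c"])
    ]
    grouped = lf.groupby("timestamp")
    out = grouped.agg(
        gsw_m_s=("gsw_m_s", "mean"),
        n_samples=("gsw_m_s", "size"),
        n_sides=("side", "nunique"),
    ).reset_index()
    out["qc_flag"] = np.where(out["n_sides"] < 2, "one_side_only", "ok")
    return out.drop(columns="n_sides")


def daylight_radiation_filter(
    records: pd.DataFrame,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the clock-window and radiation-floor exclusion.

    Returns ``(kept, dropped)``; ``dropped`` carries a ``qc_flag`` column
    with the reason(s), semicolon-joined when both apply. Idempotent.
    """
    ts = pd.DatetimeIndex(records["timestamp"])
    clock = pd.Series([t.time() for t in ts], index=records.index)
    outside = (clock < cfg.window_start) | (clock > cfg.window_end)
    low_rn = records["rn_mj_m2_h"] < cfg.rn_min
    drop = outside | low_rn

    reasons = []
    for o, r in zip(outside, low_rn):
        parts = (["outside_window"] if o else []) + (["rn_below_min"] if r else [])
        reasons.append(";".join(parts))
    dropped = records[drop].copy()
    dropped["qc_flag"] = [x for x, d in zip(reasons, drop) if d]
    kept = records[~drop].copy()
    if len(kept) == 0:
        logger.warning("daylight/radiation filter removed every record")
    return kept, dropped


def iqr_outlier_mask(values, k: float = 1.5, interpolation: str = "linear") -> np.ndarray:
    """Boolean mask, True where a value lies outside [Q1 - k IQR, Q3 + k IQR].

    Quartiles use linear interpolation between order statistics by
    default (``interpolation`` accepts any numpy quantile method). Needs
    at least four finite values to give the quartiles meaning.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 4:
        raise InsufficientDataError(
            f"IQR screen needs >= 4 finite values, got {int(finite.sum())}"
        )
    q1, q3 = np.percentile(arr[finite], [25, 75], method=interpolation)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    mask = np.zeros(arr.shape, dtype=bool)
    mask[finite] = (arr[finite] < lo) | (arr[finite] > hi)
    return mask


def align(
    meteo: pd.DataFrame,
    leaf_aggregated: pd.DataFrame,
    flux: pd.DataFrame | None = None,
    cadence: str = "h",
) -> pd.DataFrame:
    """Inner-join the three tables on timestamps binned to ``cadence``.

    Minute-cadence meteorology is averaged (R_n, T, RH, U) into each bin
    before merging; unmatched timestamps are counted in the log. Raises
    :class:`EmptySeriesError` when the join is empty (disjoint ranges).
    """
    met = meteo.copy()
    met["timestamp"] = pd.DatetimeIndex(met["timestamp"]).floor(cadence)
    met = met.groupby("timestamp", as_index=False).mean(numeric_only=True)

    lf = leaf_aggregated.copy()
    lf["timestamp"] = pd.DatetimeIndex(lf["timestamp"]).floor(cadence)

    joined = met.merge(lf, on="timestamp", how="inner", suffixes=("", "_leaf"))
    if flux is not None and len(flux):
        fx = flux.copy()
        fx["timestamp"] = pd.DatetimeIndex(fx["timestamp"]).floor(cadence)
        fx = fx.groupby("timestamp", as_index=False).mean(numeric_only=True)
        joined = joined.merge(fx, on="timestamp", how="inner")
        n_sets = 3
        stamps = [set(met["timestamp"]), set(lf["timestamp"]), set(fx["timestamp"])]
    else:
        n_sets = 2
        stamps = [set(met["timestamp"]), set(lf["timestamp"])]
    matched = set(joined["timestamp"])
    unmatched = sum(len(s - matched) for s in stamps)
    if unmatched:
        logger.info(
            "align: %d timestamp(s) across %d table(s) had no counterpart",
            unmatched,
            n_sets,
        )
    if len(joined) == 0:
        raise EmptySeriesError("alignment produced an empty join (disjoint time ranges)")
    return joined.sort_values("timestamp").reset_index(drop=True)
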