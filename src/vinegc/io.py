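"""CSV readers/writers with a fixed column schema, plus key-value config.

Schema (exact lowercase column names, one header row, ISO-8601 local
timestamps without timezone):

* meteo.csv  — ``timestamp, t_air_c, rh_pct, rn_mj_m2_h, u_m_s``
* leaf.csv   — ``timestamp, side, gsw_value, gsw_unit``
* flux.csv   — ``timestamp, ec_mm_h``
* truth.csv  — ``timestamp, gc_true_m_s`` (synthetic campaigns only)
* conductance output — ``timestamp, gc_m_s, provenance, qc_flag``

Malformed rows (unparseable timestamp, relative humidity outside
[0, 100] %, non-finite numbers) are rejected row-wise with a reason and
the 1-based file line number; a missing column is a schema error naming
the column. Numeric fields are written with 12 significant digits so a
write -> read round trip is lossless at that precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .canopy_flux import ConductanceSeries, SiteParams
from .exceptions import SchemaError
from .preprocess import LEAF_UNITS
from .synthetic import Campaign

__all__ = [
    "METEO_COLUMNS",
    "LEAF_COLUMNS",
    "FLUX_COLUMNS",
    "TRUTH_COLUMNS",
    "CONDUCTANCE_COLUMNS",
    "RawDatasetBundle",
    "read_table",
    "read_meteo",
    "read_leaf",
    "read_flux",
    "read_conductance",
    "read_raw",
    "write_table",
    "write_campaign",
    "write_conductance",
    "read_config",
]

METEO_COLUMNS = ["timestamp", "t_air_c", "rh_pct", "rn_mj_m2_h", "u_m_s"]
LEAF_COLUMNS = ["timestamp", "side", "gsw_value", "gsw_unit"]
FLUX_COLUMNS = ["timestamp", "ec_mm_h"]
TRUTH_COLUMNS = ["timestamp", "gc_true_m_s"]
CONDUCTANCE_COLUMNS = ["timestamp", "gc_m_s", "provenance", "qc_flag"]

FLOAT_FORMAT = "%.12g"


@dataclass
class RawDatasetBundle:
    """Validated raw inputs: the three tables plus the site parameters."""

    meteo: pd.DataFrame
    leaf: pd.DataFrame
    flux: pd.DataFrame | None
    site: SiteParams
    qc: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "line", "reason"])
    )


def read_table(path, columns: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} file {path} missing column(s): {', '.join(missing)}")
    return df[columns]


def _validate(df: pd.DataFrame, name: str, checks) -> tuple[pd.DataFrame, list]:
    """Run row-level checks; returns (clean rows, qc records).

    ``checks`` maps a reason string to a boolean Series marking bad rows.
    Line numbers are 1-based file lines (header is line 1).
    """
    qc = []
    bad = pd.Series(False, index=df.index)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    for idx in df.index[ts.isna()]:
        qc.append((name, int(idx) + 2, "unparseable_timestamp"))
    bad |= ts.isna()
    for reason, mask in checks.items():
        mask = mask & ~bad
        for idx in df.index[mask]:
            qc.append((name, int(idx) + 2, reason))
        bad |= mask
    out = df[~bad].copy()
    out["timestamp"] = ts[~bad]
    return out, qc


def read_meteo(path) -> tuple[pd.DataFrame, list]:
    df = read_table(path, METEO_COLUMNS, "meteo")
    num = df[["t_air_c", "rh_pct", "rn_mj_m2_h", "u_m_s"]].apply(
        pd.to_numeric, errors="coerce"
    )
    df[num.columns] = num
    checks = {
        "rh_out_of_range": (num["rh_pct"] < 0) | (num["rh_pct"] > 100) | num["rh_pct"].isna(),
        "nonfinite_value": ~np.isfinite(num["t_air_c"].fillna(np.nan))
        | ~np.isfinite(num["rn_mj_m2_h"].fillna(np.nan))
        | ~np.isfinite(num["u_m_s"].fillna(np.nan)),
        "u_negative": num["u_m_s"] < 0,
    }
    return _validate(df, "meteo", checks)


def read_leaf(path) -> tuple[pd.DataFrame, list]:
    df = read_table(path, LEAF_COLUMNS, "leaf")
    df["gsw_value"] = pd.to_numeric(df["gsw_value"], errors="coerce")
    checks = {
        "gsw_negative_or_missing": df["gsw_value"].isna() | (df["gsw_value"] < 0),
        "unknown_unit": ~df["gsw_unit"].isin(LEAF_UNITS),
    }
    return _validate(df, "leaf", checks)


def read_flux(path) -> tuple[pd.DataFrame, list]:
    df = read_table(path, FLUX_COLUMNS, "flux")
    df["ec_mm_h"] = pd.to_numeric(df["ec_mm_h"], errors="coerce")
    checks = {"ec_negative_or_missing": df["ec_mm_h"].isna() | (df["ec_mm_h"] < 0)}
    return _validate(df, "flux", checks)


def read_conductance(path) -> ConductanceSeries:
    df = read_table(path, CONDUCTANCE_COLUMNS, "conductance")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["gc_m_s"] = pd.to_numeric(df["gc_m_s"], errors="coerce")
    return ConductanceSeries.from_frame(df)


def read_raw(directory, site: SiteParams | None = None) -> RawDatasetBundle:
    """Load ``meteo.csv``, ``leaf.csv`` and (if present) ``flux.csv``.

    Row-level rejections from all tables are collected into the bundle's
    ``qc`` frame rather than raised.
    """
    directory = Path(directory)
    meteo, qc_m = read_meteo(directory / "meteo.csv")
    leaf, qc_l = read_leaf(directory / "leaf.csv")
    flux_path = directory / "flux.csv"
    if flux_path.exists():
        flux, qc_f = read_flux(flux_path)
    else:
        flux, qc_f = None, []
    qc = pd.DataFrame(qc_m + qc_l + qc_f, columns=["table", "line", "reason"])
    return RawDatasetBundle(meteo=meteo, leaf=leaf, flux=flux, site=site or SiteParams(), qc=qc)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if "timestamp" in out.columns:
        out["timestamp"] = pd.DatetimeIndex(out["timestamp"]).strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_campaign(campaign: Campaign, directory) -> None:
    directory = Path(directory)
    write_table(campaign.meteo, directory / "meteo.csv")
    write_table(campaign.leaf, directory / "leaf.csv")
    write_table(campaign.flux, directory / "flux.csv")
    write_table(campaign.truth, directory / "truth.csv")


def write_conductance(series: ConductanceSeries, path) -> None:
    write_table(series.to_frame(), path)


def read_config(path) -> dict:
    """Parse a plain-text ``key = value`` config file.

    Nested keys are dotted (``scenario.rn_peak``); ``#`` starts a
    comment; values are coerced to int, then float, then left as strings.
    """
    cfg: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise SchemaError(f"config line not of the form 'key = value': {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        for caster in (int, float):
            try:
                cfg[key] = caster(value)
                break
            except ValueError:
                continue
        else:
            cfg[key] = value
    return cfg
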