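"""Model-agreement statistics for paired conductance series.

Bundles the validation suite used to compare the big-leaf estimate with
the Penman-Monteith reference: RMSE, MAE, the aggregate relative error
|E|, Pearson correlation, ordinary least squares with a t-test on the
intercept, regression through the origin, Cohen's d with pooled standard
deviation, the U1 distribution non-overlap percentage, and coefficients
of variation.

Two conventions worth knowing:

* |E| is the absolute value of the *summed signed* errors over the summed
  observations, times 100 — an aggregate bias percentage in which
  opposite-signed errors cancel. It is deliberately not a mean absolute
  percentage error.
* U1 defaults to linear interpolation of Cohen's published table (which
  is the tabulated form practitioners quote); an exact-normal mode
  ``(2 Phi(|d|/2) - 1) / Phi(|d|/2)`` is available and agrees with the
  table to within half a percentage point for |d| <= 1.

Sample statistics use N-1 denominators throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import ndtr

from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedMetricError,
)

__all__ = [
    "EvaluationReport",
    "error_metrics",
    "pearson_r",
    "ols_with_intercept",
    "OLSFit",
    "regression_through_origin",
    "cohens_d",
    "u1_nonoverlap",
    "coefficient_of_variation",
    "evaluate_model",
]

logger = logging.getLogger(__name__)


def _paired(obs, est) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(getattr(obs, "values", obs), dtype=float)
    e = np.asarray(getattr(est, "values", est), dtype=float)
    if o.shape != e.shape:
        raise InvalidInputError(
            f"series length mismatch: obs has {o.size}, est has {e.size}"
        )
    return o, e


def error_metrics(obs, est) -> tuple[float, float, float]:
    """(RMSE, MAE, |E| %) between observed and estimated series.

    RMSE and MAE are the usual per-record deviations; |E| is the
    aggregate signed-bias percentage |sum(est - obs)| / sum(obs) * 100,
    so opposite errors cancel (obs=(1,3) vs est=(2,2) gives |E| = 0 with
    MAE = 1).
    """
    o, e = _paired(obs, est)
    if o.size == 0:
        raise InvalidInputError("need at least one record")
    diff = e - o
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    denom = float(np.sum(o))
    if denom == 0:
        raise UndefinedMetricError("|E| undefined: observations sum to zero")
    rel = float(abs(np.sum(diff)) / denom * 100.0)
    return rmse, mae, rel


def pearson_r(obs, est) -> float:
    """Product-moment correlation between the two series."""
    o, e = _paired(obs, est)
    if o.size < 2:
        raise InsufficientDataError("correlation needs n >= 2")
    if np.ptp(o) == 0 or np.ptp(e) == 0:
        raise UndefinedMetricError("correlation undefined for a constant series")
    return float(scipy.stats.pearsonr(o, e).statistic)


class OLSFit(NamedTuple):
    intercept: float
    slope: float
    intercept_p: float
    perfect_fit: bool


def ols_with_intercept(obs, est) -> OLSFit:
    """Least-squares fit est = b0 + b1 obs with a two-sided t-test on b0.

    The p-value uses the t distribution with n - 2 degrees of freedom.
    On an exact fit the residual variance is zero and the p-value is
    reported as NaN with ``perfect_fit=True`` rather than 0.
    """
    o, e = _paired(obs, est)
    if o.size < 3:
        raise InsufficientDataError("OLS with intercept needs n >= 3")
    if np.ptp(o) == 0:
        raise UndefinedMetricError("OLS undefined: observations are constant")
    res = sm.OLS(e, sm.add_constant(o)).fit()
    b0, b1 = float(res.params[0]), float(res.params[1])
    scale = float(np.sum(e**2)) or 1.0
    if res.ssr <= 1e-24 * scale:
        return OLSFit(b0, b1, float("nan"), True)
    return OLSFit(b0, b1, float(res.pvalues[0]), False)


def regression_through_origin(
    obs, est, r_convention: str = "fitted"
) -> tuple[float, float]:
    """No-intercept regression est = slope * obs.

    ``slope = sum(obs * est) / sum(obs^2)``. The companion correlation
    ``r`` follows the chosen convention: ``"fitted"`` (default) is the
    Pearson correlation between est and the fitted values slope * obs;
    ``"uncentered"`` is the square root of the uncentered R^2,
    ``sqrt(1 - sum(residual^2)/sum(est^2))``.
    """
    o, e = _paired(obs, est)
    sxx = float(np.sum(o**2))
    if sxx == 0:
        raise InvalidInputError("regression through origin undefined: all-zero obs")
    slope = float(np.sum(o * e) / sxx)
    if r_convention == "fitted":
        fitted = slope * o
        if np.ptp(fitted) == 0 or np.ptp(e) == 0:
            r = float("nan")
        else:
            r = float(scipy.stats.pearsonr(e, fitted).statistic)
    elif r_convention == "uncentered":
        see = float(np.sum(e**2))
        if see == 0:
            raise UndefinedMetricError("uncentered R^2 undefined: all-zero est")
        r = float(np.sqrt(max(0.0, 1.0 - np.sum((e - slope * o) ** 2) / see)))
    else:
        raise InvalidInputError(f"unknown r_convention {r_convention!r}")
    return slope, r


def cohens_d(obs, est) -> tuple[float, float]:
    """Standardized mean difference (obs - est) / s_p and the pooled SD.

    ``s_p`` pools the two sample variances (N-1 denominators) weighted by
    their degrees of freedom. Antisymmetric under swapping the samples
    and invariant under a common rescaling.
    """
    o = np.asarray(getattr(obs, "values", obs), dtype=float)
    e = np.asarray(getattr(est, "values", est), dtype=float)
    if o.size < 2 or e.size < 2:
        raise InsufficientDataError("Cohen's d needs >= 2 values per sample")
    v_o = float(np.var(o, ddof=1))
    v_e = float(np.var(e, ddof=1))
    sp2 = ((o.size - 1) * v_o + (e.size - 1) * v_e) / (o.size + e.size - 2)
    if sp2 <= 0:
        raise UndefinedMetricError("Cohen's d undefined: zero pooled variance")
    sp = float(np.sqrt(sp2))
    return float((np.mean(o) - np.mean(e)) / sp), sp


# Cohen's tabulated non-overlap percentages U1 as a function of d.
_U1_D = np.array(
    [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
     1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2.0,
     2.2, 2.4, 2.6, 2.8, 3.0, 3.2, 3.4, 3.6, 3.8, 4.0]
)
_U1_PCT = np.array(
    [0.0, 7.7, 14.7, 21.3, 27.4, 33.0, 38.2, 43.0, 47.4, 51.6, 55.4,
     58.9, 62.2, 65.3, 68.1, 70.7, 73.1, 75.4, 77.4, 79.4, 81.1,
     84.3, 87.0, 89.3, 91.2, 92.8, 94.2, 95.3, 96.3, 97.0, 97.7]
)


def u1_nonoverlap(d: float, mode: str = "table_interpolation") -> float:
    """Percentage of the two distributions that does not overlap, from |d|.

    ``table_interpolation`` (default) interpolates Cohen's published U1
    values linearly in |d|; ``exact_normal`` evaluates the closed form
    ``(2 Phi(|d|/2) - 1) / Phi(|d|/2)`` for two equal-variance normal
    distributions. Beyond the table's range (|d| > 4) table mode falls
    back to the exact form with a warning.
    """
    if not np.isfinite(d):
        raise InvalidInputError(f"d must be finite, got {d!r}")
    a = abs(float(d))
    if mode == "exact_normal" or (mode == "table_interpolation" and a > _U1_D[-1]):
        if mode == "table_interpolation":
            logger.warning("|d|=%.3g beyond Cohen's table; using exact-normal U1", a)
        phi = float(ndtr(a / 2.0))
        return (2.0 * phi - 1.0) / phi * 100.0
    if mode != "table_interpolation":
        raise InvalidInputError(f"unknown U1 mode {mode!r}")
    return float(np.interp(a, _U1_D, _U1_PCT))


def coefficient_of_variation(series) -> float:
    """Sample standard deviation over the mean, as a percentage."""
    x = np.asarray(getattr(series, "values", series), dtype=float)
    if x.size < 2:
        raise InsufficientDataError("CV needs n >= 2")
    m = float(np.mean(x))
    if m == 0:
        raise UndefinedMetricError("CV undefined: zero mean")
    return float(np.std(x, ddof=1) / m * 100.0)


@dataclass
class EvaluationReport:
    """Full agreement-statistics bundle for one obs/est comparison.

    Metrics that were undefined for the given data carry NaN and an
    explanatory entry in ``flags``.
    """

    n: int
    rmse: float
    mae: float
    rel_err_pct: float
    pearson_r: float
    ols_intercept: float
    ols_slope: float
    intercept_p: float
    rto_slope: float
    rto_r: float
    cohens_d: float
    pooled_sd: float
    u1_pct: float
    cv_obs: float
    cv_est: float
    flags: dict[str, str] = field(default_factory=dict)

    _NUMERIC_FIELDS = (
        "n", "rmse", "mae", "rel_err_pct", "pearson_r", "ols_intercept",
        "ols_slope", "intercept_p", "rto_slope", "rto_r", "cohens_d",
        "pooled_sd", "u1_pct", "cv_obs", "cv_est",
    )

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self._NUMERIC_FIELDS}
        out["flags"] = ";".join(f"{k}:{v}" for k, v in sorted(self.flags.items()))
        return out

    def to_text(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in self.to_dict().items()) + "\n"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        flags = {}
        raw = d.get("flags", "")
        if isinstance(raw, str) and raw:
            flags = dict(item.split(":", 1) for item in raw.split(";"))
        kwargs = {k: d[k] for k in cls._NUMERIC_FIELDS}
        kwargs["n"] = int(kwargs["n"])
        return cls(flags=flags, **kwargs)


def evaluate_model(
    obs,
    est,
    u1_mode: str = "table_interpolation",
    rto_r_convention: str = "fitted",
) -> EvaluationReport:
    """Compose the full agreement report for an obs/est conductance pair.

    Accepts :class:`~vinegc.canopy_flux.ConductanceSeries` or plain
    arrays; record pairs where either side is missing (NaN) are excluded
    jointly before computing any statistic. Component metrics that fail
    their own preconditions are reported as NaN with a flag rather than
    aborting the report; only a length mismatch (or fewer than 3 valid
    pairs) raises.
    """
    o, e = _paired(obs, est)
    keep = np.isfinite(o) & np.isfinite(e)
    o, e = o[keep], e[keep]
    if o.size < 3:
        raise InsufficientDataError(
            f"model evaluation needs >= 3 valid paired records, got {o.size}"
        )

    flags: dict[str, str] = {}
    nan = float("nan")

    def attempt(name, fn, default):
        try:
            return fn()
        except (UndefinedMetricError, InsufficientDataError, InvalidInputError) as exc:
            flags[name] = str(exc)
            return default

    rmse, mae, rel = attempt("error_metrics", lambda: error_metrics(o, e), (nan, nan, nan))
    r = attempt("pearson_r", lambda: pearson_r(o, e), nan)
    fit = attempt("ols", lambda: ols_with_intercept(o, e), OLSFit(nan, nan, nan, False))
    if fit.perfect_fit:
        flags["ols"] = "perfect_fit:intercept_p_undefined"
    rto_slope, rto_r = attempt(
        "rto", lambda: regression_through_origin(o, e, rto_r_convention), (nan, nan)
    )
    d, sp = attempt("cohens_d", lambda: cohens_d(o, e), (nan, nan))
    u1 = attempt("u1", lambda: u1_nonoverlap(d, u1_mode), nan) if np.isfinite(d) else nan
    cv_o = attempt("cv_obs", lambda: coefficient_of_variation(o), nan)
    cv_e = attempt("cv_est", lambda: coefficient_of_variation(e), nan)

    return EvaluationReport(
        n=int(o.size),
        rmse=rmse,
        mae=mae,
        rel_err_pct=rel,
        pearson_r=r,
        ols_intercept=fit.intercept,
        ols_slope=fit.slope,
        intercept_p=fit.intercept_p,
        rto_slope=rto_slope,
        rto_r=rto_r,
        cohens_d=d,
        pooled_sd=sp,
        u1_pct=u1,
        cv_obs=cv_o,
        cv_est=cv_e,
        flags=flags,
    )
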