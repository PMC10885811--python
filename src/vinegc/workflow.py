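"""End-to-end orchestration: raw tables -> filtered analysis table ->
both conductance series -> agreement report."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .canopy_flux import ConductanceSeries, conductance_pipeline
from .evaluate import EvaluationReport, evaluate_model
from .exceptions import InsufficientDataError
from .io import RawDatasetBundle
from .micromet import DEFAULT_CONSTANTS, PhysicalConstants
from .preprocess import (
    FilterConfig,
    aggregate_leaf_conductance,
    align,
    daylight_radiation_filter,
    iqr_outlier_mask,
)

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    analysis: pd.DataFrame
    estimated: ConductanceSeries
    observed: ConductanceSeries
    report: EvaluationReport | None
    qc: pd.DataFrame


def run_pipeline(
    bundle: RawDatasetBundle,
    filter_cfg: FilterConfig | None = None,
    apply_filter: bool = True,
    apply_iqr: bool = True,
    u1_mode: str = "table_interpolation",
    which: Literal["both", "estimated", "observed"] = "both",
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> PipelineResult:
    """Run the full conductance pipeline on a raw dataset bundle.

    Steps: aggregate leaf samples to one g_sw series (with unit
    conversion), align the tables on the hourly cadence, apply the
    daylight/radiation exclusion and the IQR screen on g_sw (both
    optional), compute the big-leaf estimate and the Penman-Monteith
    reference record-wise, and — when both series have at least three
    valid pairs — the agreement report. Per-record rejections land in
    ``result.qc``; nothing is silently dropped.
    """
    cfg = filter_cfg or FilterConfig()
    qc_frames = [bundle.qc] if len(bundle.qc) else []

    leaf_agg = aggregate_leaf_conductance(
        bundle.leaf, bundle.meteo, bundle.site.pressure, constants
    )
    flux = bundle.flux if which in ("both", "observed") else None
    analysis = align(bundle.meteo, leaf_agg, flux)

    if apply_filter:
        analysis, dropped = daylight_radiation_filter(analysis, cfg)
        if len(dropped):
            qc_frames.append(
                pd.DataFrame(
                    {
                        "table": "analysis",
                        "line": dropped.index + 1,
                        "reason": dropped["qc_flag"],
                    }
                )
            )

    if apply_iqr and len(analysis) >= 4:
        mask = iqr_outlier_mask(analysis["gsw_m_s"].to_numpy(), cfg.iqr_k)
        if mask.any():
            flagged = analysis[mask]
            qc_frames.append(
                pd.DataFrame(
                    {
                        "table": "analysis",
                        "line": flagged.index + 1,
                        "reason": "gsw_iqr_outlier",
                    }
                )
            )
            logger.info("IQR screen flagged %d record(s)", int(mask.sum()))
            analysis = analysis[~mask]
    analysis = analysis.reset_index(drop=True)

    estimated, observed = conductance_pipeline(analysis, bundle.site, constants, which)

    report = None
    if which == "both":
        try:
            report = evaluate_model(observed, estimated, u1_mode=u1_mode)
        except InsufficientDataError as exc:
            logger.warning("agreement report skipped: %s", exc)

    pipe_qc = estimated.to_frame().query("qc_flag != 'ok'")[["timestamp", "qc_flag"]]
    if len(pipe_qc):
        qc_frames.append(
            pd.DataFrame(
                {"table": "pipeline", "line": pipe_qc.index + 1, "reason": pipe_qc["qc_flag"]}
            )
        )
    qc = (
        pd.concat(qc_frames, ignore_index=True)
        if qc_frames
        else pd.DataFrame(columns=["table", "line", "reason"])
    )
    return PipelineResult(analysis, estimated, observed, report, qc)
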