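"""One-call orchestration: preprocess → metrics → classify → dosimetry → SUV.

Mirrors the intended clinical workflow: the dose-rate curves recorded
during the first ten minutes of administration are reduced to the
injection metrics; the session is classified; for an extravasation the
PET-segmentation statistics (when available) feed the residual-activity
and self-dose estimates and the SUV correction, while normal and
abnormal administrations keep a correction coefficient of exactly 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

from .classification import (
    AbnormalBand,
    LABEL_EXTRAVASATION,
    ThresholdModel,
    classify_session,
)
from .dosimetry import F18_HALF_LIFE_MIN, SegmentationResult, dose_chain
from .io_sessions import AdministrationSession, SphereDoseTable, write_report
from .metrics import PlateauConfig, compute_metrics
from .preprocessing import PreprocessConfig
from .suv import suv_correct

logger = logging.getLogger("extravakit.pipeline")

# CLI exit codes (0 = success, 1 = unexpected error)
EXIT_IO_ERROR = 2
EXIT_PLATEAU_NOT_REACHED = 3


@dataclass(frozen=True)
class PipelineConfig:
    """Everything :func:`run_analysis` needs besides the session itself."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    plateau: PlateauConfig = field(default_factory=PlateauConfig)
    thresholds: Mapping[str, ThresholdModel] | None = None
    abnormal_band: AbnormalBand = field(default_factory=AbnormalBand)
    dose_table: SphereDoseTable | None = None
    segmentation: SegmentationResult | None = None
    suv_in: float | None = None
    half_life_min: float = F18_HALF_LIFE_MIN
    include_series: bool = True


def run_analysis(session: AdministrationSession, config: PipelineConfig | None = None) -> dict[str, Any]:
    """Run the full workflow on one session; returns the parsed report.

    Stages run in order; classification requires fitted thresholds, and
    the dosimetry/SUV stages run only for sessions classified as
    extravasation *and* supplied with segmentation statistics and a dose
    table.  Stage errors propagate with the stage name attached.
    """
    config = config or PipelineConfig()

    logger.info("metrics: session %s", session.patient_id)
    metrics = _stage("metrics", compute_metrics, session, config.preprocess, config.plateau)

    label = None
    dose_report = None
    correction = None
    if config.thresholds is not None:
        result = _stage("classify", classify_session, metrics, config.thresholds, config.abnormal_band)
        label = result.label
        logger.info("classify: %s (%s)", label, result.reasons or "no threshold crossed")
        if label == LABEL_EXTRAVASATION and config.segmentation is not None and config.dose_table is not None:
            est, dose_report = _stage(
                "dosimetry",
                dose_chain,
                config.segmentation,
                config.dose_table,
                session.uptake_time_min,
                config.half_life_min,
            )
            if config.suv_in is not None:
                correction = _stage(
                    "suv_correction",
                    suv_correct,
                    config.suv_in,
                    session.injected_activity_mbq,
                    est.a_rs_bq / 1e6,
                )

    text = write_report(
        session,
        metrics=metrics.as_dict(include_series=config.include_series),
        label=label,
        dose_report=dose_report,
        suv_correction=correction,
        thresholds=config.thresholds,
    )
    return json.loads(text)


def _stage(name: str, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        exc.args = (f"[stage {name}] {exc}",) + exc.args[1:]
        raise
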