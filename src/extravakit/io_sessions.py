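"""Reading and writing administration sessions, dose-factor tables and reports.

An *administration session* is the unit of analysis: the two dose-rate
curves recorded on the patient's arms while the radiotracer is injected
(one detector ~5 cm proximal to the IV access, one mirrored on the
contralateral arm), together with the injected activity and the uptake
time before PET acquisition.

Curve files are plain CSV with the header ``time_s,dose_rate_usv_h,arm``;
``arm`` is ``injection`` or ``contralateral``.  Times are seconds since
acquisition start, values are ambient dose equivalent rate H*(10) in
µSv/h, sampled nominally at 1 Hz.  Session metadata (patient id, injected
activity, uptake time) travels in a side-car mapping, not in the curve
file.  Reports are a single JSON document.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import CurveValidationError, SessionFormatError

ARM_INJECTION = "injection"
ARM_CONTRALATERAL = "contralateral"

#: Minimum overlap (s) of the two arms' records for a raw monitoring
#: session; ten minutes of concurrent data are required to evaluate the
#: arm-difference metric six minutes after plateau onset.
MIN_RAW_OVERLAP_S = 600.0

CURVE_COLUMNS = ("time_s", "dose_rate_usv_h", "arm")
DOSE_TABLE_COLUMNS = ("mass_g", "dose_factor_mGy_per_MBq")


@dataclass(frozen=True)
class DoseRateCurve:
    """One arm's time-stamped dose-rate series.

    Parameters
    ----------
    times
        Sample times in seconds since acquisition start, strictly increasing.
    values
        Ambient dose equivalent rate H*(10) in µSv/h, non-negative.
    arm
        ``"injection"`` or ``"contralateral"``.
    detector_id
        Free-text identifier of the detector.
    """

    times: np.ndarray
    values: np.ndarray
    arm: str
    detector_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.arm not in (ARM_INJECTION, ARM_CONTRALATERAL):
            raise CurveValidationError(f"unknown arm {self.arm!r}")
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise CurveValidationError("times and values must be 1-D and the same length")
        if times.size < 2:
            raise CurveValidationError("a curve needs at least 2 samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise CurveValidationError("non-finite sample in curve")
        if np.any(np.diff(times) <= 0):
            raise CurveValidationError("non-increasing times")
        if np.any(values < 0):
            raise CurveValidationError("negative dose-rate value")

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def sampling_interval(self, rtol: float = 1e-6) -> float:
        """Return the uniform sampling interval, or raise if non-uniform."""
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=rtol, atol=1e-9):
            raise CurveValidationError("curve is not uniformly sampled")
        return float(dt[0])

    def restrict(self, t_lo: float, t_hi: float) -> "DoseRateCurve":
        """Sub-curve with times in ``[t_lo, t_hi]`` (inclusive)."""
        m = (self.times >= t_lo) & (self.times <= t_hi)
        if m.sum() < 2:
            raise CurveValidationError("window retains fewer than 2 samples")
        return replace(self, times=self.times[m], values=self.values[m])


@dataclass(frozen=True)
class AdministrationSession:
    """Paired dose-rate curves plus injection metadata.

    ``contralateral_curve`` may be absent (single-detector mode: only the
    peak-drop family of metrics is then available).  ``windowed`` marks a
    session whose curves were already cut to the peak-anchored analysis
    window; ``truncated`` marks a windowed session with less post-peak
    data than the nominal nine minutes.
    """

    patient_id: str
    injected_activity_mbq: float
    injection_curve: DoseRateCurve
    contralateral_curve: DoseRateCurve | None = None
    uptake_time_min: float = 60.0
    windowed: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.injected_activity_mbq > 0:
            raise SessionFormatError("injected activity must be > 0 MBq")
        if not self.uptake_time_min > 0:
            raise SessionFormatError("uptake time must be > 0 min")
        if self.injection_curve.arm != ARM_INJECTION:
            raise SessionFormatError("injection_curve must have arm='injection'")
        if self.contralateral_curve is not None:
            if self.contralateral_curve.arm != ARM_CONTRALATERAL:
                raise SessionFormatError("contralateral_curve must have arm='contralateral'")
            if self.overlap_seconds() <= 0:
                raise SessionFormatError("arm records do not overlap in time")

    @property
    def single_detector(self) -> bool:
        return self.contralateral_curve is None

    def overlap_seconds(self) -> float:
        """Duration of the time interval covered by both arms (0 if single)."""
        if self.contralateral_curve is None:
            return 0.0
        lo = max(self.injection_curve.t_start, self.contralateral_curve.t_start)
        hi = min(self.injection_curve.t_end, self.contralateral_curve.t_end)
        return hi - lo

    def validate_monitoring(self, min_overlap_s: float = MIN_RAW_OVERLAP_S) -> None:
        """Check the raw-session requirement of >= 10 min of concurrent data.

        Applied at pipeline entry; windowed or deliberately short sessions
        (e.g. toy fixtures) are representable without passing this check.
        """
        if self.contralateral_curve is not None and self.overlap_seconds() < min_overlap_s:
            raise SessionFormatError(
                f"arm records overlap for {self.overlap_seconds():.0f} s "
                f"(< {min_overlap_s:.0f} s required)"
            )


@dataclass(frozen=True)
class SphereDoseTable:
    """Sphere-model dose factors: unit-density sphere mass (g) -> mGy/MBq.

    The factors are tabulated inputs (e.g. exported from an internal-
    dosimetry code's sphere model); they are interpolated, never derived,
    here.
    """

    masses_g: np.ndarray
    dose_factors_mgy_per_mbq: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses_g, dtype=float)
        f = np.asarray(self.dose_factors_mgy_per_mbq, dtype=float)
        order = np.argsort(m)
        m, f = m[order], f[order]
        object.__setattr__(self, "masses_g", m)
        object.__setattr__(self, "dose_factors_mgy_per_mbq", f)
        if m.size != f.size or m.size < 2:
            raise SessionFormatError("dose table needs >= 2 (mass, factor) rows")
        if np.any(np.diff(m) <= 0):
            raise SessionFormatError("duplicate or unsorted masses in dose table")
        if np.any(m <= 0) or np.any(f <= 0):
            raise SessionFormatError("dose table entries must be positive")

    @property
    def mass_range(self) -> tuple[float, float]:
        return float(self.masses_g[0]), float(self.masses_g[-1])


def _meta_get(meta: Mapping[str, Any], *keys: str, default: Any = None, required: bool = False) -> Any:
    for k in keys:
        if k in meta:
            return meta[k]
    if required:
        raise SessionFormatError(f"metadata missing required key (any of {keys})")
    return default


def read_session(curve_path, meta: Mapping[str, Any]) -> AdministrationSession:
    """Read a dual-arm curve CSV plus a metadata mapping into a session.

    ``meta`` supplies ``patient_id``, the injected activity in MBq
    (``injected_activity_mbq`` or ``A_in``) and optionally
    ``uptake_time_min`` (``uptake_time``), defaulting to 60 min.

    Rows are partitioned by the ``arm`` column.  An arm with fewer than
    two samples cannot form a curve: for the injection arm this is an
    error, for the contralateral arm the session silently degrades to
    single-detector mode (with a warning).
    """
    try:
        # round_trip: parse floats to the nearest representable double so
        # write_session -> read_session is bit-exact
        df = pd.read_csv(curve_path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SessionFormatError(f"cannot parse curve file {curve_path}: {exc}") from exc
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise SessionFormatError(f"curve file missing columns {missing}")
    for col in ("time_s", "dose_rate_usv_h"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SessionFormatError(f"non-numeric values in column {col!r}")

    curves: dict[str, DoseRateCurve] = {}
    for arm in (ARM_INJECTION, ARM_CONTRALATERAL):
        part = df[df["arm"] == arm]
        if len(part) >= 2:
            curves[arm] = DoseRateCurve(
                times=part["time_s"].to_numpy(float),
                values=part["dose_rate_usv_h"].to_numpy(float),
                arm=arm,
            )
    if ARM_INJECTION not in curves:
        raise SessionFormatError("no usable injection-arm rows (need >= 2 samples)")
    if ARM_CONTRALATERAL not in curves and (df["arm"] == ARM_CONTRALATERAL).any():
        warnings.warn(
            "contralateral arm has < 2 samples; falling back to single-detector mode",
            stacklevel=2,
        )

    a_in = _meta_get(meta, "injected_activity_mbq", "A_in", "a_in", required=True)
    return AdministrationSession(
        patient_id=str(_meta_get(meta, "patient_id", default="")),
        injected_activity_mbq=float(a_in),
        uptake_time_min=float(_meta_get(meta, "uptake_time_min", "uptake_time", default=60.0)),
        injection_curve=curves[ARM_INJECTION],
        contralateral_curve=curves.get(ARM_CONTRALATERAL),
    )


def write_session(session: AdministrationSession, curve_path) -> None:
    """Write a session's curves as CSV; inverse of :func:`read_session`.

    Float formatting uses Python's shortest round-tripping repr, so
    ``read_session(write_session(x))`` reproduces times and values
    bit-identically.
    """
    with open(curve_path, "w") as fh:
        fh.write(",".join(CURVE_COLUMNS) + "\n")
        for curve in (session.injection_curve, session.contralateral_curve):
            if curve is None:
                continue
            for t, v in zip(curve.times.tolist(), curve.values.tolist()):
                fh.write(f"{t!r},{v!r},{curve.arm}\n")


def session_meta(session: AdministrationSession) -> dict[str, Any]:
    """Side-car metadata mapping for :func:`write_session` output."""
    return {
        "patient_id": session.patient_id,
        "injected_activity_mbq": session.injected_activity_mbq,
        "uptake_time_min": session.uptake_time_min,
    }


def read_dose_table(path) -> SphereDoseTable:
    """Read a two-column (mass_g, dose_factor_mGy_per_MBq) CSV table.

    A header row with those column names is preferred; a bare two-column
    numeric file is accepted as well.
    """
    df = pd.read_csv(path)
    if all(c in df.columns for c in DOSE_TABLE_COLUMNS):
        m, f = df["mass_g"], df["dose_factor_mGy_per_MBq"]
    else:
        # headerless: first row was consumed as a header; re-read positionally
        try:
            [float(c) for c in df.columns[:2]]
        except ValueError as exc:
            raise SessionFormatError(
                f"dose table must have columns {DOSE_TABLE_COLUMNS}"
            ) from exc
        df = pd.read_csv(path, header=None)
        m, f = df.iloc[:, 0], df.iloc[:, 1]
    if not (pd.api.types.is_numeric_dtype(m) and pd.api.types.is_numeric_dtype(f)):
        raise SessionFormatError("non-numeric entries in dose table")
    return SphereDoseTable(m.to_numpy(float), f.to_numpy(float))


def write_dose_table(table: SphereDoseTable, path) -> None:
    pd.DataFrame(
        {"mass_g": table.masses_g, "dose_factor_mGy_per_MBq": table.dose_factors_mgy_per_mbq}
    ).to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and dataclass-likes to JSON types."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    return obj


def write_report(
    session: AdministrationSession,
    metrics=None,
    label: str | None = None,
    dose_report=None,
    suv_correction=None,
    thresholds: Mapping[str, Any] | None = None,
    extra: Mapping[str, Any] | None = None,
    path=None,
) -> str:
    """Serialise one session's analysis into a single JSON document.

    Sections are present only when the corresponding input is given.  A
    session without a contralateral curve is flagged ``single_detector``.
    Numbers are written with round-tripping precision (>= 15 significant
    digits), so parse → compare is lossless.  Keys are sorted, making the
    report byte-identical across repeated runs on the same inputs.

    Returns the JSON text; if ``path`` is given, also writes it there.
    """
    doc: dict[str, Any] = {
        "patient_id": session.patient_id,
        "injected_activity_mbq": session.injected_activity_mbq,
        "uptake_time_min": session.uptake_time_min,
        "single_detector": session.single_detector,
    }
    if metrics is not None:
        doc["metrics"] = _jsonable(metrics)
    if label is not None:
        doc["classification"] = {"label": label}
        if thresholds is not None:
            doc["classification"]["thresholds"] = _jsonable(dict(thresholds))
    if dose_report is not None:
        doc["dosimetry"] = _jsonable(dose_report)
    if suv_correction is not None:
        doc["suv_correction"] = _jsonable(suv_correction)
    else:
        # the correction coefficient is fixed at 1 for non-extravasation cases
        if label is not None and label != "extravasation":
            doc["suv_correction"] = {"coefficient": 1.0}
    if extra:
        doc.update(_jsonable(dict(extra)))
    text = json.dumps(doc, indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
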