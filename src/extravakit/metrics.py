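"""Injection metrics from a windowed administration session.

Five quantities characterise an administration within the first ten
minutes:

* ``DR_in_max`` — maximum dose rate on the injection arm (bolus transit);
* ``DR_in_mean`` — mean injection-arm dose rate over the plateau segment;
* ``t*`` — time from the injection peak to plateau onset;
* ``Δp_in = DR_in_max − DR_in_mean`` and its normalised form
  ``Δp_in_NOR = Δp_in / DR_in_max`` (near 1 for a clean injection, low
  when activity is retained at the injection site);
* ``ΔR(t) = DR_in(t) − DR_con(t)`` — arm difference, evaluated six
  minutes after plateau onset and optionally normalised by ``DR_in_max``.

Plateau onset is the start of the first 60-s window, searched from the
injection peak onward, in which the arm-difference signal changes by no
more than 15 µSv/h between consecutive seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Any

import numpy as np

from .errors import CurveValidationError, PlateauNotReachedError
from .io_sessions import AdministrationSession, DoseRateCurve
from .preprocessing import PreprocessConfig, cut_window, find_peak, smooth


@dataclass(frozen=True)
class PlateauConfig:
    """Stability rule and evaluation point for the plateau segment.

    stability_tolerance
        Maximum allowed change of the monitored signal between
        consecutive seconds (µSv/h); default 15, an empirical device
        threshold.
    stability_duration
        How long (s) the condition must hold; default 60.
    evaluation_delay
        Delay (s) after plateau onset at which the arm difference is
        read out; default 360 (six minutes).
    """

    stability_tolerance: float = 15.0
    stability_duration: float = 60.0
    evaluation_delay: float = 360.0

    def __post_init__(self) -> None:
        if min(self.stability_tolerance, self.stability_duration, self.evaluation_delay) <= 0:
            raise ValueError("all plateau parameters must be > 0")


@dataclass(frozen=True)
class InjectionMetrics:
    """Computed injection metrics; arm-difference fields are ``None`` in
    single-detector mode."""

    dr_in_max: float
    t_peak: float
    dr_in_mean: float
    t_star: float                       # plateau onset relative to the peak, s
    delta_p: float                      # dr_in_max - dr_in_mean, µSv/h
    delta_p_nor: float                  # delta_p / dr_in_max
    delta_r_times: np.ndarray | None = None
    delta_r_values: np.ndarray | None = None
    delta_r_6min: float | None = None
    delta_r_nor: float | None = None
    single_detector: bool = False
    truncated_evaluation: bool = False

    def as_dict(self, include_series: bool = True) -> dict[str, Any]:
        d: dict[str, Any] = {
            "dr_in_max_usv_h": self.dr_in_max,
            "t_peak_s": self.t_peak,
            "dr_in_mean_usv_h": self.dr_in_mean,
            "t_star_s": self.t_star,
            "delta_p_usv_h": self.delta_p,
            "delta_p_nor": self.delta_p_nor,
            "single_detector": self.single_detector,
            "truncated_evaluation": self.truncated_evaluation,
        }
        if self.delta_r_6min is not None:
            d["delta_r_6min_usv_h"] = self.delta_r_6min
            d["delta_r_nor"] = self.delta_r_nor
        if include_series and self.delta_r_values is not None:
            d["delta_r_series"] = {
                "time_s": self.delta_r_times,
                "delta_r_usv_h": self.delta_r_values,
            }
        return d


def resample_common_grid(session: AdministrationSession) -> AdministrationSession:
    """Put both curves on a shared 1-s integer grid spanning their overlap.

    The two detectors are not synchronised, so the pointwise difference
    ΔR(t) needs a common grid; each curve is linearly interpolated onto
    integer seconds.  Curves already sharing a uniform 1-s grid are
    returned unchanged.  Raises if the overlap is shorter than 120 s.
    """
    inj, con = session.injection_curve, session.contralateral_curve
    if con is None:
        if _is_unit_grid(inj.times):
            return session
        grid = _integer_grid(inj.t_start, inj.t_end)
        return replace(session, injection_curve=_interp(inj, grid))

    lo = max(inj.t_start, con.t_start)
    hi = min(inj.t_end, con.t_end)
    if hi - lo < 120.0:
        raise CurveValidationError(
            f"arm records overlap for {max(hi - lo, 0):.0f} s (< 120 s required)"
        )
    if np.array_equal(inj.times, con.times) and _is_unit_grid(inj.times):
        return session
    grid = _integer_grid(lo, hi)
    return replace(
        session,
        injection_curve=_interp(inj, grid),
        contralateral_curve=_interp(con, grid),
    )


def _is_unit_grid(times: np.ndarray) -> bool:
    return bool(np.allclose(np.diff(times), 1.0, rtol=0, atol=1e-9))


def _integer_grid(lo: float, hi: float) -> np.ndarray:
    return np.arange(np.ceil(lo), np.floor(hi) + 0.5)


def _interp(curve: DoseRateCurve, grid: np.ndarray) -> DoseRateCurve:
    return replace(curve, times=grid, values=np.interp(grid, curve.times, curve.values))


def delta_r_series(session: AdministrationSession) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise arm difference ΔR(t) = DR_in(t) − DR_con(t).

    Requires a resampled session (identical grids); the difference may be
    negative.  Raises if the contralateral curve is missing.
    """
    if session.contralateral_curve is None:
        raise CurveValidationError("no contralateral curve: use single-detector mode")
    inj, con = session.injection_curve, session.contralateral_curve
    if not np.array_equal(inj.times, con.times):
        raise CurveValidationError("curves not on a common grid; resample first")
    return inj.times.copy(), inj.values - con.values


def detect_plateau(
    times: np.ndarray,
    values: np.ndarray,
    cfg: PlateauConfig | None = None,
    start_time: float | None = None,
) -> float:
    """First time from which the signal is stable for one minute.

    Stability: every change between consecutive samples within a window
    of ``stability_duration`` seconds has magnitude at most
    ``stability_tolerance``.  Returns the absolute time of the window
    start (the plateau onset).  ``start_time`` restricts the search to
    windows starting at or after that time (the injection peak, in the
    pipeline, since the plateau cannot precede the bolus).

    Raises :class:`PlateauNotReachedError` when no window qualifies.
    """
    cfg = cfg or PlateauConfig()
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if times.size != values.size or times.size < 2:
        raise ValueError("times and values must match and have >= 2 samples")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise CurveValidationError("plateau detection requires uniform sampling")
    step = float(dt[0])
    n_diffs = int(round(cfg.stability_duration / step))
    if n_diffs < 1:
        raise ValueError("stability_duration shorter than one sampling interval")
    ok = np.abs(np.diff(values)) <= cfg.stability_tolerance
    if ok.size < n_diffs:
        raise PlateauNotReachedError("record shorter than the stability window")

    first = 0
    if start_time is not None:
        first = int(np.searchsorted(times, start_time, side="left"))
    # window of n_diffs consecutive qualifying steps, scanned left to right
    csum = np.concatenate(([0], np.cumsum(ok.astype(np.int64))))
    window_ok = csum[n_diffs:] - csum[:-n_diffs] == n_diffs  # index i -> diffs i..i+n-1
    candidates = np.nonzero(window_ok[first:])[0]
    if candidates.size == 0:
        raise PlateauNotReachedError("plateau not reached")
    return float(times[first + int(candidates[0])])


def compute_metrics(
    session: AdministrationSession,
    pp_cfg: PreprocessConfig | None = None,
    plateau_cfg: PlateauConfig | None = None,
) -> InjectionMetrics:
    """Run the metric chain on a session.

    Steps: peak-anchored windowing (skipped if already windowed), peak
    location on the *raw* injection curve, resampling to a common 1-s
    grid, Gaussian smoothing, plateau detection on the smoothed
    arm-difference signal (or on the smoothed injection curve in
    single-detector mode), then metric assembly:

    * ``dr_in_mean``: mean of the smoothed injection-arm signal from
      plateau onset to the window end;
    * ``delta_r_6min``: smoothed ΔR at onset + ``evaluation_delay``; if
      the record ends earlier the last sample is used and the metrics
      are flagged ``truncated_evaluation`` (with a warning).

    Exact identities hold by construction:
    ``delta_p == dr_in_max - dr_in_mean``,
    ``delta_p_nor == delta_p / dr_in_max`` and
    ``delta_r_nor == delta_r_6min / dr_in_max``.
    """
    pp_cfg = pp_cfg or PreprocessConfig()
    plateau_cfg = plateau_cfg or PlateauConfig()

    if not session.windowed:
        session = cut_window(session, pp_cfg)
    session = resample_common_grid(session)

    # peak on the raw (resampled, unsmoothed) injection curve
    t_peak, dr_in_max = find_peak(session.injection_curve)
    if dr_in_max <= 0:
        raise CurveValidationError("injection curve has no positive peak")

    inj_s = smooth(session.injection_curve, pp_cfg.smoothing_sigma, pp_cfg.boundary_mode)
    single = session.contralateral_curve is None
    if single:
        stab_times, stab_values = inj_s.times, inj_s.values
        dr_t = dr_v = None
    else:
        con_s = smooth(session.contralateral_curve, pp_cfg.smoothing_sigma, pp_cfg.boundary_mode)
        dr_t, dr_v = inj_s.times.copy(), inj_s.values - con_s.values
        stab_times, stab_values = dr_t, dr_v

    t_star_abs = detect_plateau(stab_times, stab_values, plateau_cfg, start_time=t_peak)

    plateau_mask = inj_s.times >= t_star_abs
    dr_in_mean = float(inj_s.values[plateau_mask].mean())
    delta_p = dr_in_max - dr_in_mean
    delta_p_nor = delta_p / dr_in_max

    delta_r_6min = delta_r_nor = None
    truncated_eval = False
    if not single:
        t_eval = t_star_abs + plateau_cfg.evaluation_delay
        if t_eval > dr_t[-1]:
            truncated_eval = True
            warnings.warn(
                "record ends before onset + evaluation delay; using last sample",
                stacklevel=2,
            )
            t_eval = dr_t[-1]
        idx = int(np.argmin(np.abs(dr_t - t_eval)))
        delta_r_6min = float(dr_v[idx])
        delta_r_nor = delta_r_6min / dr_in_max

    return InjectionMetrics(
        dr_in_max=dr_in_max,
        t_peak=t_peak,
        dr_in_mean=dr_in_mean,
        t_star=t_star_abs - t_peak,
        delta_p=delta_p,
        delta_p_nor=delta_p_nor,
        delta_r_times=dr_t,
        delta_r_values=dr_v,
        delta_r_6min=delta_r_6min,
        delta_r_nor=delta_r_nor,
        single_detector=single,
        truncated_evaluation=truncated_eval,
    )
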