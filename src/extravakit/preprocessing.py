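"""Peak-anchored windowing and Gaussian smoothing of dose-rate curves.

The analysis window runs from one minute before to nine minutes after the
injection-arm peak, which marks the passage of the radioactive bolus.
Curves are denoised with a Gaussian kernel before plateau detection and
plateau averaging; the peak itself is always located on the raw curve so
the bolus maximum is not attenuated by the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import CurveValidationError
from .io_sessions import AdministrationSession, DoseRateCurve

#: Minimum post-peak record length (s) for a session to be analysable at
#: all: shorter records cannot contain a 60-s stability window plus any
#: meaningful evaluation point.
MIN_POST_PEAK_S = 120.0


@dataclass(frozen=True)
class PreprocessConfig:
    """Windowing and smoothing parameters.

    pre_peak_window / post_peak_window
        Seconds kept before/after the injection peak (defaults 60 / 540:
        one minute before, nine minutes after).
    smoothing_sigma
        Gaussian kernel standard deviation in seconds (0 disables
        smoothing).  The kernel is truncated at ±4σ and renormalised.
    boundary_mode
        Edge handling for the convolution: ``reflect`` or ``nearest``.
    """

    pre_peak_window: float = 60.0
    post_peak_window: float = 540.0
    smoothing_sigma: float = 3.0
    boundary_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.pre_peak_window <= 0 or self.post_peak_window <= 0:
            raise ValueError("window lengths must be > 0")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.boundary_mode not in ("reflect", "nearest"):
            raise ValueError("boundary_mode must be 'reflect' or 'nearest'")


def find_peak(curve: DoseRateCurve) -> tuple[float, float]:
    """Locate the bolus peak: ``(t_peak, dr_max)``.

    ``dr_max`` is the maximum sample value; ties are broken by the first
    occurrence.  The peak is meaningful on the *injection* arm, where the
    bolus transit produces it, but the function accepts any curve.
    """
    idx = int(np.argmax(curve.values))
    return float(curve.times[idx]), float(curve.values[idx])


def cut_window(session: AdministrationSession, cfg: PreprocessConfig | None = None) -> AdministrationSession:
    """Restrict both curves to the peak-anchored analysis window.

    The window is ``[t_peak - pre, t_peak + post]`` intersected with the
    available data; it is clamped (not an error) when the peak sits near
    the record start.  If less than :data:`MIN_POST_PEAK_S` of post-peak
    data exists the session is unanalysable and an error is raised; if
    the post-peak record is shorter than the nominal window the returned
    session carries ``truncated=True``.  Idempotent.
    """
    cfg = cfg or PreprocessConfig()
    t_peak, _ = find_peak(session.injection_curve)
    post_available = session.injection_curve.t_end - t_peak
    if post_available < MIN_POST_PEAK_S:
        raise CurveValidationError(
            f"only {post_available:.0f} s of post-peak data (< {MIN_POST_PEAK_S:.0f} s)"
        )
    lo = t_peak - cfg.pre_peak_window
    hi = t_peak + cfg.post_peak_window
    inj = session.injection_curve.restrict(lo, hi)
    con = session.contralateral_curve.restrict(lo, hi) if session.contralateral_curve else None
    return replace(
        session,
        injection_curve=inj,
        contralateral_curve=con,
        windowed=True,
        truncated=post_available < cfg.post_peak_window,
    )


def smooth(curve: DoseRateCurve, sigma: float, boundary_mode: str = "reflect") -> DoseRateCurve:
    """Gaussian-kernel smoothing of a uniformly sampled curve.

    ``sigma`` is in seconds; it is converted to samples using the curve's
    sampling interval.  The discrete kernel is truncated at ±4σ and
    renormalised to unit sum, so a constant signal is preserved exactly.
    ``sigma = 0`` returns the curve unchanged.  Non-uniform sampling is
    rejected (resample first).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return curve
    dt = curve.sampling_interval()
    smoothed = gaussian_filter1d(
        curve.values, sigma=sigma / dt, mode=boundary_mode, truncate=4.0
    )
    return replace(curve, values=smoothed)


def gaussian_kernel(sigma_samples: float, truncate: float = 4.0) -> np.ndarray:
    """The discrete smoothing kernel used by :func:`smooth` (for analysis).

    Symmetric, truncated at ``±truncate·σ`` and renormalised to sum 1.
    Exposed so noise-propagation factors (Σw²) can be computed exactly.
    """
    radius = int(truncate * sigma_samples + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma_samples) ** 2)
    return w / w.sum()
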