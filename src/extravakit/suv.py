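"""SUV correction for extravasated administrations.

The standardised uptake value assumes the whole injected activity A_in
entered circulation.  When a fraction ``f_RS = A_RS / A_in`` stays at the
injection site, the scanner-reported value ``SUV_in`` underestimates the
true uptake; correcting the denominator by subtracting the residual
activity gives

    SUV_corrected = SUV_in · A_in / (A_in − A_RS) = SUV_in / (1 − f_RS),

so the multiplicative *correction coefficient* is ``1 / (1 − f_RS) =
1 + SUV_%CR/100`` with the percentage change ``SUV_%CR = 100·f_RS /
(1 − f_RS)``.  The coefficient is 1 for normal and abnormal cases.

The trend of the coefficient against either late-curve metric (the
six-minute arm difference normalised by the peak, or the inverse of the
normalised peak drop) is summarised by the exponential fit
``coefficient = 1 + exp(−a (metric − b))``, which lets the correction be
predicted from the injection-phase curves alone, before any image is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError


@dataclass(frozen=True)
class SUVCorrection:
    """Correction of a single scanner-reported SUV."""

    suv_in: float
    f_rs: float
    suv_pct_cr: float
    coefficient: float
    suv_corrected: float

    def as_dict(self) -> dict[str, Any]:
        return {
            "suv_in": self.suv_in,
            "f_rs": self.f_rs,
            "suv_pct_cr": self.suv_pct_cr,
            "coefficient": self.coefficient,
            "suv_corrected": self.suv_corrected,
        }


@dataclass(frozen=True)
class CorrectionCurveFit:
    """Fitted metric → coefficient curve with its quality measures."""

    metric_name: str
    a: float
    b: float
    r2: float
    rmse: float
    nrmse: float

    def predict(self, metric) -> np.ndarray:
        return 1.0 + np.exp(-self.a * (np.asarray(metric, float) - self.b))

    def as_dict(self) -> dict[str, Any]:
        return {
            "metric_name": self.metric_name,
            "a": self.a,
            "b": self.b,
            "r2": self.r2,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
        }


def suv_correct(suv_in: float, a_in_mbq: float, a_rs_mbq: float) -> SUVCorrection:
    """Correct an SUV for the residual activity left at the injection site.

    Requires ``0 ≤ A_RS < A_in`` and ``SUV_in > 0``.  With ``f_RS = 0``
    the correction is the identity (coefficient exactly 1).
    """
    if suv_in <= 0:
        raise ValueError("SUV_in must be positive")
    if a_in_mbq <= 0:
        raise ValueError("A_in must be positive")
    if a_rs_mbq < 0 or a_rs_mbq >= a_in_mbq:
        raise ValueError("need 0 <= A_RS < A_in")
    f_rs = a_rs_mbq / a_in_mbq
    coefficient = 1.0 / (1.0 - f_rs)
    suv_pct_cr = 100.0 * (coefficient - 1.0)
    return SUVCorrection(
        suv_in=suv_in,
        f_rs=f_rs,
        suv_pct_cr=suv_pct_cr,
        coefficient=coefficient,
        suv_corrected=suv_in * coefficient,
    )


def fit_quality(observed: Sequence[float], predicted: Sequence[float]) -> tuple[float, float, float]:
    """(R², RMSE, NRMSE) of a fit.

    ``R² = 1 − SS_res/SS_tot``; ``RMSE = sqrt(SS_res/n)``; ``NRMSE``
    divides the RMSE by the population (n-denominator) standard
    deviation of the observed values, making the two metric fits
    comparable on one scale.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("need >= 2 matching observed/predicted values")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise FitError("degenerate observations: zero variance")
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / obs.size))
    nrmse = rmse / float(obs.std())  # population SD
    return r2, rmse, nrmse


def fit_correction_curve(
    points: Sequence[tuple[float, float]],
    anchor: tuple[float, float] | None = None,
    metric_name: str = "metric",
) -> CorrectionCurveFit:
    """Fit ``coefficient = 1 + exp(−a (metric − b))`` to (metric, coefficient) points.

    ``anchor`` optionally appends one extra point — conventionally the
    cumulative non-extravasation point at coefficient 1 — before
    fitting.  Nonlinear least squares with multi-start over the sign and
    scale of ``a``; requires at least 3 points (after the anchor) and
    non-constant coefficients.  The model form guarantees predicted
    coefficients > 1 for any finite input.
    """
    pts = list(points)
    if anchor is not None:
        pts.append((float(anchor[0]), float(anchor[1])))
    x = np.array([p[0] for p in pts], float)
    y = np.array([p[1] for p in pts], float)
    if x.size < 3:
        raise FitError("need >= 3 points (including the anchor)")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite fit input")
    if np.ptp(y) == 0:
        raise FitError("degenerate fit: all coefficients equal")
    if np.any(y <= 1.0 - 1e-12):
        # exp term is positive; coefficients below 1 cannot be represented
        y = np.maximum(y, 1.0 + 1e-12)

    span = np.ptp(x) or 1.0

    def resid(params):
        a, b = params
        z = np.clip(-a * (x - b), -500, 500)
        return 1.0 + np.exp(z) - y

    best = None
    # seed b near the abscissa of the largest coefficient, a at several scales
    b0 = float(x[np.argmax(y)])
    for a0 in (1 / span, 4 / span, 16 / span, -1 / span, -4 / span, -16 / span):
        try:
            res = least_squares(resid, [a0, b0], max_nfev=10000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError("correction-curve fit did not converge")
    a, b = (float(v) for v in best.x)
    pred = 1.0 + np.exp(np.clip(-a * (x - b), -500, 500))
    r2, rmse, nrmse = fit_quality(y, pred)
    return CorrectionCurveFit(metric_name=metric_name, a=a, b=b, r2=r2, rmse=rmse, nrmse=nrmse)
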