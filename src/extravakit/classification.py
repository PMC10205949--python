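"""Administration classification and threshold fitting.

Each administration falls into one of three classes — ``normal``,
``abnormal`` (venous retention) or ``extravasation`` — distinguished by
the normalised peak drop Δp_in_NOR (depressed under extravasation) and
the late arm difference ΔR at six minutes post-plateau (elevated under
extravasation).

Decision thresholds are obtained by least-squares fitting of a logistic

    outcome = 1 / (1 + exp(-k (metric - a)))

to dichotomous outcomes (1 = extravasation, 0 = everything else); with
the decision limit at probability 0.5 the fitted location ``a`` *is* the
threshold.  Least squares on the 0/1 outcomes — not maximum likelihood —
mirrors how such thresholds are fitted with generic curve-fitting tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

from .errors import FitError
from .metrics import InjectionMetrics

LABEL_NORMAL = "normal"
LABEL_ABNORMAL = "abnormal"
LABEL_EXTRAVASATION = "extravasation"

DIRECTION_BELOW = "extravasation_below"   # e.g. delta_p_nor: low values flag extravasation
DIRECTION_ABOVE = "extravasation_above"   # e.g. delta_r_6min: high values flag extravasation

_METRIC_DIRECTIONS = {
    "delta_p_nor": DIRECTION_BELOW,
    "delta_r_6min": DIRECTION_ABOVE,
}


@dataclass(frozen=True)
class ThresholdModel:
    """A fitted logistic decision rule on a single metric."""

    metric_name: str
    k: float
    a: float
    direction: str
    decision_limit: float = 0.5

    def __post_init__(self) -> None:
        if self.k == 0:
            raise FitError("degenerate logistic: k = 0")
        if self.direction not in (DIRECTION_BELOW, DIRECTION_ABOVE):
            raise ValueError(f"unknown direction {self.direction!r}")

    def predict_probability(self, value) -> np.ndarray:
        z = np.clip(self.k * (np.asarray(value, float) - self.a), -500, 500)
        return 1.0 / (1.0 + np.exp(-z))

    def flags_extravasation(self, value: float) -> bool:
        """Strict crossing: a value exactly at the threshold does not flag."""
        return value < self.a if self.direction == DIRECTION_BELOW else value > self.a

    def as_dict(self) -> dict[str, Any]:
        return {
            "metric_name": self.metric_name,
            "k": self.k,
            "a": self.a,
            "direction": self.direction,
            "decision_limit": self.decision_limit,
        }


@dataclass(frozen=True)
class AbnormalBand:
    """Boundary between normal and abnormal administrations.

    The three-class boundary between *normal* and *abnormal* is not part
    of the logistic threshold analysis; it is exposed as a configurable
    band defaulting to the normal-class mean ± 2 SD of each metric
    (Δp_in_NOR below 0.91 − 2·0.06 = 0.79, or ΔR above 24 + 2·11 = 46
    µSv/h, is flagged abnormal).  These defaults derive from the
    reported normal-class statistics, not from a fitted rule.
    """

    delta_p_nor_lower: float = 0.79
    delta_r_6min_upper: float = 46.0


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    used_metrics: tuple[str, ...]
    reasons: dict[str, str] = field(default_factory=dict)
    delta_p_only: bool = False

    def as_dict(self) -> dict[str, Any]:
        return {
            "label": self.label,
            "used_metrics": list(self.used_metrics),
            "reasons": dict(self.reasons),
            "delta_p_only": self.delta_p_only,
        }


def _logistic_residuals(params, x, y):
    k, a = params
    z = np.clip(k * (x - a), -500, 500)
    return 1.0 / (1.0 + np.exp(-z)) - y


def fit_threshold(
    values: Sequence[float],
    outcomes: Sequence[int],
    metric_name: str = "metric",
) -> ThresholdModel:
    """Least-squares logistic fit of dichotomous outcomes on metric values.

    Multi-start Levenberg–Marquardt/TRF over slope seeds ``±{1, 4}/SD``
    with the location seeded at the midpoint of the two class means; the
    best sum of squares wins.  The fitted ``a`` is the probability-0.5
    crossing, i.e. the decision threshold.  The rule's direction is
    taken from the sign of the class-mean difference (it is stored
    explicitly rather than inferred later from ``k``).
    """
    x = np.asarray(values, float)
    y = np.asarray(outcomes, float)
    if x.size != y.size:
        raise ValueError("values and outcomes must have the same length")
    if x.size < 4:
        raise FitError("need at least 4 points to fit a threshold")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcomes must be 0 or 1")
    if np.unique(y).size < 2:
        raise FitError("both outcome classes must be represented")

    m0, m1 = x[y == 0].mean(), x[y == 1].mean()
    sd = x.std()
    if sd == 0:
        raise FitError("degenerate metric values (zero spread)")
    a0 = 0.5 * (m0 + m1)
    best = None
    for k0 in (1 / sd, -1 / sd, 4 / sd, -4 / sd):
        try:
            res = least_squares(_logistic_residuals, [k0, a0], args=(x, y), max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise FitError("logistic fit did not converge")
    k, a = best.x
    direction = DIRECTION_BELOW if m1 < m0 else DIRECTION_ABOVE
    return ThresholdModel(metric_name=metric_name, k=float(k), a=float(a), direction=direction)


def classify_session(
    metrics: InjectionMetrics,
    models: Mapping[str, ThresholdModel],
    abnormal_band: AbnormalBand | None = None,
) -> ClassificationResult:
    """Three-class decision from the fitted thresholds.

    ``extravasation`` if any available metric crosses its threshold
    strictly (Δp_in_NOR below a, or ΔR above a) — an OR rule, favouring
    sensitivity; else ``abnormal`` if a metric falls in the abnormal
    band; else ``normal``.  Deterministic and order-independent.  When
    the arm-difference metrics are unavailable (single-detector mode)
    the decision rests on Δp_in_NOR alone and is flagged.
    """
    abnormal_band = abnormal_band or AbnormalBand()
    available: dict[str, float] = {"delta_p_nor": metrics.delta_p_nor}
    if metrics.delta_r_6min is not None:
        available["delta_r_6min"] = metrics.delta_r_6min
    used = tuple(sorted(name for name in models if name in available))
    if "delta_p_nor" not in used:
        raise ValueError("a delta_p_nor threshold model is required")

    reasons: dict[str, str] = {}
    extravasation = False
    for name in used:
        if models[name].flags_extravasation(available[name]):
            extravasation = True
            reasons[name] = "crossed extravasation threshold"
    if extravasation:
        label = LABEL_EXTRAVASATION
    else:
        abnormal = False
        if available["delta_p_nor"] < abnormal_band.delta_p_nor_lower:
            abnormal = True
            reasons["delta_p_nor"] = "inside abnormal band"
        if (
            "delta_r_6min" in available
            and available["delta_r_6min"] > abnormal_band.delta_r_6min_upper
        ):
            abnormal = True
            reasons["delta_r_6min"] = "inside abnormal band"
        label = LABEL_ABNORMAL if abnormal else LABEL_NORMAL
    return ClassificationResult(
        label=label,
        used_metrics=used,
        reasons=reasons,
        delta_p_only="delta_r_6min" not in used,
    )


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design of a one-sided AUC superiority test.

    ``auc_null`` vs ``auc_alt`` (one-sided, type I error ``alpha``),
    targeting the given ``power``, with ``prevalence`` the positive-case
    fraction of the cohort.
    """

    auc_null: float = 0.80
    auc_alt: float = 0.90
    alpha: float = 0.05
    power: float = 0.90
    prevalence: float = 0.06

    def __post_init__(self) -> None:
        if not (0.5 < self.auc_null < self.auc_alt < 1.0):
            raise ValueError("need 0.5 < auc_null < auc_alt < 1")
        for name in ("alpha", "power", "prevalence"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")


def _hanley_mcneil_var(auc: float, n_pos: float, n_neg: float) -> float:
    """AUC variance under the exponential approximation."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc) + (n_pos - 1.0) * (q1 - auc**2) + (n_neg - 1.0) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def sample_size_auc(spec: SampleSizeSpec) -> int:
    """Smallest cohort size for the one-sided AUC test to reach its power.

    Uses the Hanley–McNeil exponential-approximation variance at both the
    null and alternative AUC; positives are ``prevalence·n`` (continuous
    during the search, so the result is monotone in the design
    parameters).  Returns the total patient count, rounded up.
    """
    z_a = norm.ppf(1.0 - spec.alpha)
    z_b = norm.ppf(spec.power)
    delta = spec.auc_alt - spec.auc_null

    def deficit(n: float) -> float:
        n_pos = max(spec.prevalence * n, 2.0)
        n_neg = max((1.0 - spec.prevalence) * n, 2.0)
        v0 = _hanley_mcneil_var(spec.auc_null, n_pos, n_neg)
        v1 = _hanley_mcneil_var(spec.auc_alt, n_pos, n_neg)
        return z_a * np.sqrt(v0) + z_b * np.sqrt(v1) - delta

    lo, hi = 4.0, 8.0
    while deficit(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise FitError("required sample size diverges")
    while hi - lo > 0.5:
        mid = 0.5 * (lo + hi)
        if deficit(mid) > 0:
            lo = mid
        else:
            hi = mid
    return int(np.ceil(hi))


def save_thresholds(models: Mapping[str, ThresholdModel], path) -> None:
    doc = {name: model.as_dict() for name, model in models.items()}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def load_thresholds(path) -> dict[str, ThresholdModel]:
    with open(path) as fh:
        doc = json.load(fh)
    return {name: ThresholdModel(**params) for name, params in doc.items()}


def default_thresholds() -> dict[str, ThresholdModel]:
    """Reference thresholds from the published analysis.

    a = 0.61 on Δp_in_NOR (extravasation below) and a = 302 µSv/h on the
    six-minute arm difference (extravasation above); slopes are nominal
    (steep) since only the 0.5-crossing enters the decision.
    """
    return {
        "delta_p_nor": ThresholdModel("delta_p_nor", k=-50.0, a=0.61, direction=DIRECTION_BELOW),
        "delta_r_6min": ThresholdModel("delta_r_6min", k=0.05, a=302.0, direction=DIRECTION_ABOVE),
    }
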