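"""Residual activity and sphere-model self-dose at the injection site.

When an extravasation is confirmed on the PET image, the depot is
segmented with a relative-intensity threshold (10% and 40% of the
maximum voxel, "Th10"/"Th40"), giving a volume and a mean activity
concentration.  Residual activity at imaging time is their product; it
is decay-corrected back to injection time with the physical half-life
(¹⁸F: 109.771 min), since no patient-specific clearance curve exists.
The absorbed self-dose of the infiltrated tissue is obtained from
tabulated unit-density-sphere dose factors (mGy/MBq) at the sphere mass
matching the segmented volume (water density, 1 g/ml).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .io_sessions import SphereDoseTable

#: Physical half-life of fluorine-18, minutes.
F18_HALF_LIFE_MIN = 109.771


@dataclass(frozen=True)
class VoxelGrid:
    """3-D activity-concentration map (Bq/ml) with voxel size in mm."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        if v.ndim != 3:
            raise ValueError("voxel grid must be 3-D")
        if np.any(v < 0):
            raise ValueError("negative activity concentration")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        # mm³ -> cm³ == ml
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def total_activity_bq(self) -> float:
        return float(self.values.sum() * self.voxel_volume_ml)


@dataclass(frozen=True)
class SegmentationResult:
    """Outcome of relative-threshold segmentation of the depot."""

    threshold_fraction: float
    volume_cm3: float
    mean_concentration_bq_ml: float

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_fraction <= 1.0):
            raise ValueError("threshold fraction must lie in (0, 1]")
        if self.volume_cm3 <= 0 or self.mean_concentration_bq_ml <= 0:
            raise ValueError("volume and mean concentration must be positive")

    def as_dict(self) -> dict[str, Any]:
        return {
            "threshold_fraction": self.threshold_fraction,
            "volume_cm3": self.volume_cm3,
            "mean_concentration_bq_ml": self.mean_concentration_bq_ml,
        }


@dataclass(frozen=True)
class ResidualActivityEstimate:
    """Residual activity decay-corrected to injection time."""

    activity_at_imaging_bq: float
    decay_factor: float
    a_rs_bq: float
    uptake_time_min: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def as_dict(self) -> dict[str, Any]:
        return {
            "activity_at_imaging_bq": self.activity_at_imaging_bq,
            "decay_factor": self.decay_factor,
            "a_rs_bq": self.a_rs_bq,
            "uptake_time_min": self.uptake_time_min,
            "half_life_min": self.half_life_min,
        }


@dataclass(frozen=True)
class DoseReport:
    """Sphere-model self-dose of the infiltrated tissue."""

    sphere_mass_g: float
    dose_factor_mgy_per_mbq: float
    self_dose_gy: float
    a_rs_bq: float

    def as_dict(self) -> dict[str, Any]:
        return {
            "sphere_mass_g": self.sphere_mass_g,
            "dose_factor_mgy_per_mbq": self.dose_factor_mgy_per_mbq,
            "self_dose_gy": self.self_dose_gy,
            "a_rs_bq": self.a_rs_bq,
        }


def segment_threshold(grid: VoxelGrid, fraction: float) -> SegmentationResult:
    """Segment voxels at or above ``fraction`` of the global maximum.

    The mask is ``values >= fraction * max``; for any fraction ≤ 1 it
    contains at least the maximum voxel, so it is never empty.  Volume is
    the voxel count times the voxel volume (cm³); the mean concentration
    is averaged over the mask.  Thresholding is against the single global
    maximum (manual VOI choice is emulated upstream by cropping the
    grid), and no connected-component filtering is applied.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("threshold fraction must lie in (0, 1]")
    vmax = float(grid.values.max())
    if vmax <= 0:
        raise ValueError("grid has no positive voxel")
    mask = grid.values >= fraction * vmax
    volume = float(mask.sum()) * grid.voxel_volume_ml
    mean_conc = float(grid.values[mask].mean())
    return SegmentationResult(
        threshold_fraction=float(fraction),
        volume_cm3=volume,
        mean_concentration_bq_ml=mean_conc,
    )


def residual_activity(
    seg: SegmentationResult,
    uptake_time_min: float = 60.0,
    half_life_min: float = F18_HALF_LIFE_MIN,
) -> ResidualActivityEstimate:
    """Residual activity at injection time from segmentation statistics.

    ``A(imaging) = mean_concentration × volume``; the decay correction
    ``2^(uptake_time / half_life) ≥ 1`` reports it at injection time.
    """
    if uptake_time_min < 0:
        raise ValueError("uptake time must be >= 0 min")
    if half_life_min <= 0:
        raise ValueError("half-life must be > 0 min")
    at_imaging = seg.mean_concentration_bq_ml * seg.volume_cm3
    decay_factor = 2.0 ** (uptake_time_min / half_life_min)
    return ResidualActivityEstimate(
        activity_at_imaging_bq=at_imaging,
        decay_factor=decay_factor,
        a_rs_bq=at_imaging * decay_factor,
        uptake_time_min=uptake_time_min,
        half_life_min=half_life_min,
    )


def interpolate_dose_factor(
    table: SphereDoseTable, mass_g: float, extrapolate: bool = False
) -> float:
    """Log-log interpolation of the sphere dose factor at ``mass_g``.

    Sphere S-values are close to a power law in mass, so interpolation is
    linear in (log mass, log factor); table nodes are reproduced exactly.
    Masses outside the table range are refused unless ``extrapolate`` is
    set (then the boundary power-law segment is extended).
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    lo, hi = table.mass_range
    if not extrapolate and not (lo <= mass_g <= hi):
        raise ValueError(f"mass {mass_g} g outside table range [{lo}, {hi}] g")
    logm = np.log(table.masses_g)
    logf = np.log(table.dose_factors_mgy_per_mbq)
    x = np.log(mass_g)
    if x <= logm[0]:
        slope = (logf[1] - logf[0]) / (logm[1] - logm[0])
        return float(np.exp(logf[0] + slope * (x - logm[0])))
    if x >= logm[-1]:
        slope = (logf[-1] - logf[-2]) / (logm[-1] - logm[-2])
        return float(np.exp(logf[-1] + slope * (x - logm[-1])))
    return float(np.exp(np.interp(x, logm, logf)))


def self_dose(a_rs_bq: float, dose_factor_mgy_per_mbq: float) -> float:
    """Absorbed self-dose in Gy: ``(A_RS / 10⁶) [MBq] × factor [mGy/MBq] / 1000``."""
    if a_rs_bq < 0 or dose_factor_mgy_per_mbq < 0:
        raise ValueError("inputs must be non-negative")
    return (a_rs_bq / 1e6) * dose_factor_mgy_per_mbq / 1000.0


def dose_chain(
    seg: SegmentationResult,
    table: SphereDoseTable,
    uptake_time_min: float = 60.0,
    half_life_min: float = F18_HALF_LIFE_MIN,
    extrapolate: bool = False,
) -> tuple[ResidualActivityEstimate, DoseReport]:
    """Full dosimetry chain: segmentation stats → A_RS → self-dose.

    The sphere mass equals the segmented volume at water density
    (1 g/ml).
    """
    est = residual_activity(seg, uptake_time_min, half_life_min)
    mass_g = seg.volume_cm3 * 1.0
    factor = interpolate_dose_factor(table, mass_g, extrapolate=extrapolate)
    report = DoseReport(
        sphere_mass_g=mass_g,
        dose_factor_mgy_per_mbq=factor,
        self_dose_gy=self_dose(est.a_rs_bq, factor),
        a_rs_bq=est.a_rs_bq,
    )
    return est, report
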