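import numpy as np
import pytest

from extravakit import (
    ARM_CONTRALATERAL,
    ARM_INJECTION,
    AdministrationSession,
    CurveValidationError,
    DoseRateCurve,
    PlateauConfig,
    PlateauNotReachedError,
    compute_metrics,
    delta_r_series,
    detect_plateau,
    resample_common_grid,
)

from conftest import make_step_session


def dual_session(t_inj, v_inj, t_con, v_con, a_in=250.0):
    return AdministrationSession(
        patient_id="x",
        injected_activity_mbq=a_in,
        injection_curve=DoseRateCurve(t_inj, v_inj, ARM_INJECTION),
        contralateral_curve=DoseRateCurve(t_con, v_con, ARM_CONTRALATERAL),
    )


class TestResampleCommonGrid:
    def test_identical_unit_grids_unchanged(self):
        t = np.arange(200.0)
        s = dual_session(t, np.ones(200), t, np.ones(200))
        assert resample_common_grid(s) is s

    def test_linear_signal_interpolated_exactly(self):
        # contralateral offset by 0.5 s; a linear function is reproduced
        # exactly by linear interpolation
        t_inj = np.arange(200.0)
        t_con = t_inj + 0.5
        s = dual_session(t_inj, 2.0 * t_inj + 5.0, t_con, 3.0 * t_con + 1.0)
        r = resample_common_grid(s)
        grid = r.contralateral_curve.times
        assert np.all(grid == np.round(grid))
        assert r.contralateral_curve.values == pytest.approx(3.0 * grid + 1.0, rel=1e-12)
        assert r.injection_curve.values == pytest.approx(2.0 * grid + 5.0, rel=1e-12)

    def test_disjoint_ranges_rejected(self):
        from extravakit import SessionFormatError

        with pytest.raises(SessionFormatError, match="overlap"):
            dual_session(np.arange(0.0, 200.0), np.ones(200),
                         np.arange(300.0, 500.0), np.ones(200))

    def test_short_overlap_rejected(self):
        s = dual_session(np.arange(0.0, 200.0), np.ones(200),
                         np.arange(150.0, 350.0), np.ones(200))
        with pytest.raises(CurveValidationError, match="120 s"):
            resample_common_grid(s)


class TestDeltaRSeries:
    def test_identical_curves_give_zero(self):
        t = np.arange(150.0)
        v = np.linspace(1, 50, 150)
        _, dr = delta_r_series(dual_session(t, v, t, v))
        assert dr == pytest.approx(np.zeros(150), abs=0)

    def test_constant_offset_recovered(self):
        t = np.arange(150.0)
        v = np.linspace(1, 50, 150)
        _, dr = delta_r_series(dual_session(t, v + 390.0, t, v))
        assert dr == pytest.approx(np.full(150, 390.0), rel=1e-12)

    def test_missing_contralateral_rejected(self):
        s = AdministrationSession(
            patient_id="x",
            injected_activity_mbq=100.0,
            injection_curve=DoseRateCurve(np.arange(150.0), np.ones(150), ARM_INJECTION),
        )
        with pytest.raises(CurveValidationError, match="single-detector"):
            delta_r_series(s)


def brute_force_plateau(times, values, tol=15.0, duration=60.0, start_time=None):
    """Independent oracle: scan every window explicitly."""
    n = int(round(duration / (times[1] - times[0])))
    diffs = np.abs(np.diff(values))
    for i in range(len(diffs) - n + 1):
        if start_time is not None and times[i] < start_time:
            continue
        if all(diffs[i + j] <= tol for j in range(n)):
            return times[i]
    return None


class TestDetectPlateau:
    def test_onset_after_large_steps_subside(self):
        t = np.arange(0.0, 400.0)
        v = np.where(t < 200, 100.0 * t, 100.0 * 200 + 5.0 * (t - 200))
        assert detect_plateau(t, v) == 200.0

    def test_constant_series_onset_at_first_sample(self):
        t = np.arange(10.0, 200.0)
        assert detect_plateau(t, np.full(190, 42.0)) == 10.0

    def test_persistent_oscillation_never_stabilises(self):
        t = np.arange(0.0, 400.0)
        v = 100.0 + 20.0 * (-1.0) ** np.arange(400)
        with pytest.raises(PlateauNotReachedError):
            detect_plateau(t, v)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(123)
        cfg = PlateauConfig()
        for _ in range(40):
            n = int(rng.integers(80, 1000))
            # random walk whose step scale decays: crosses the stability
            # threshold at an unpredictable time
            scale = rng.uniform(20, 200) * np.exp(-np.arange(n) / rng.uniform(20, 200))
            v = np.cumsum(scale * rng.standard_normal(n)) + 500.0
            t = np.arange(float(n))
            expected = brute_force_plateau(t, v)
            if expected is None:
                with pytest.raises(PlateauNotReachedError):
                    detect_plateau(t, v, cfg)
            else:
                assert detect_plateau(t, v, cfg) == expected

    def test_start_time_restricts_search(self):
        t = np.arange(0.0, 300.0)
        v = np.full(300, 10.0)
        assert detect_plateau(t, v, start_time=120.0) == 120.0


class TestComputeMetrics:
    def test_constructed_session_recovers_design_values(self, step_session):
        m = compute_metrics(step_session)
        assert m.dr_in_max == 1000.0
        assert m.t_peak == 60.0
        assert m.delta_p == pytest.approx(900.0, rel=2e-3)
        assert m.delta_p_nor == pytest.approx(0.9, rel=2e-3)
        assert m.delta_r_6min == pytest.approx(20.0, rel=1e-6)

    def test_exact_identities(self, step_session):
        m = compute_metrics(step_session)
        assert m.delta_p == m.dr_in_max - m.dr_in_mean
        assert m.delta_p_nor * m.dr_in_max == m.delta_p
        assert m.delta_r_nor == m.delta_r_6min / m.dr_in_max

    def test_scaling_leaves_normalised_metrics_unchanged(self, step_session):
        c = 2.5
        scaled = make_step_session(peak=1000 * c, plateau=100 * c, contralateral=80 * c)
        m0 = compute_metrics(step_session)
        m1 = compute_metrics(scaled)
        assert m1.delta_p_nor == pytest.approx(m0.delta_p_nor, abs=1e-3)
        assert m1.delta_r_nor == pytest.approx(m0.delta_r_nor, rel=1e-6)
        assert m1.dr_in_max == pytest.approx(c * m0.dr_in_max, rel=1e-12)

    def test_constant_shift_affects_exactly_the_absolute_fields(self, step_session):
        c = 50.0
        shifted = make_step_session(peak=1050.0, plateau=150.0, contralateral=130.0)
        m0 = compute_metrics(step_session)
        m1 = compute_metrics(shifted)
        # unchanged (up to smoothing-tail leakage near the peak):
        # the differences
        assert m1.delta_p == pytest.approx(m0.delta_p, abs=0.1)
        assert m1.delta_r_6min == pytest.approx(m0.delta_r_6min, abs=1e-9)
        # changed by the shift: absolute levels, hence the normalised forms
        assert m1.dr_in_max == m0.dr_in_max + c
        assert m1.dr_in_mean == pytest.approx(m0.dr_in_mean + c, abs=0.1)
        assert m1.delta_p_nor < m0.delta_p_nor
        assert m1.delta_r_nor < m0.delta_r_nor

    def test_raising_plateau_moves_both_metrics(self):
        low = compute_metrics(make_step_session(plateau=100.0))
        high = compute_metrics(make_step_session(plateau=200.0))
        assert high.delta_p_nor < low.delta_p_nor
        assert high.delta_r_6min > low.delta_r_6min

    def test_single_detector_mode(self):
        t = np.arange(0.0, 700.0)
        inj = np.zeros_like(t)
        inj[t > 60] = 100.0
        inj[60] = 1000.0
        s = AdministrationSession(
            patient_id="single",
            injected_activity_mbq=200.0,
            injection_curve=DoseRateCurve(t, inj, ARM_INJECTION),
        )
        m = compute_metrics(s)
        assert m.single_detector
        assert m.delta_r_6min is None and m.delta_r_nor is None
        assert m.delta_p_nor == pytest.approx(0.9, rel=2e-3)

    def test_truncated_record_warns_and_flags(self):
        s = make_step_session(t_peak=120.0, duration=420.0)
        with pytest.warns(UserWarning, match="last sample"):
            m = compute_metrics(s)
        assert m.truncated_evaluation

    def test_unstable_session_raises(self):
        # slow oscillation that smoothing cannot flatten
        t = np.arange(0.0, 700.0)
        v = 500.0 + 400.0 * np.sin(2 * np.pi * t / 60.0)
        s = dual_session(t, v, t, np.full(700, 10.0))
        with pytest.raises(PlateauNotReachedError):
            compute_metrics(s)
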