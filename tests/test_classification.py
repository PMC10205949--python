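import numpy as np
import pytest

from extravakit import (
    AbnormalBand,
    FitError,
    InjectionMetrics,
    SampleSizeSpec,
    ThresholdModel,
    classify_session,
    default_thresholds,
    fit_threshold,
    load_thresholds,
    sample_size_auc,
    save_thresholds,
)


def metrics_with(delta_p_nor, delta_r_6min=None):
    dr_max = 850.0
    return InjectionMetrics(
        dr_in_max=dr_max,
        t_peak=70.0,
        dr_in_mean=dr_max * (1 - delta_p_nor),
        t_star=20.0,
        delta_p=dr_max * delta_p_nor,
        delta_p_nor=delta_p_nor,
        delta_r_6min=delta_r_6min,
        delta_r_nor=None if delta_r_6min is None else delta_r_6min / dr_max,
        single_detector=delta_r_6min is None,
    )


class TestFitThreshold:
    def test_separated_toy_threshold_in_gap_and_beats_grid_oracle(self):
        values = np.array([0.40, 0.45, 0.85, 0.90, 0.95])
        outcomes = np.array([1, 1, 0, 0, 0])
        model = fit_threshold(values, outcomes, "delta_p_nor")
        assert 0.45 < model.a < 0.85
        assert model.direction == "extravasation_below"
        # oracle: exhaustive grid over (k, a); the fit must be at least as
        # good in least squares as the best grid point
        def sse(k, a):
            p = 1 / (1 + np.exp(-np.clip(k * (values - a), -500, 500)))
            return np.sum((p - outcomes) ** 2)

        grid = min(
            sse(k, a)
            for k in (-200, -50, -20, -5, 5, 20, 50, 200)
            for a in np.arange(0.30, 1.01, 0.005)
        )
        assert sse(model.k, model.a) <= grid + 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(FitError, match="both outcome classes"):
            fit_threshold([0.1, 0.2, 0.3, 0.4], [0, 0, 0, 0])

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError, match="at least 4"):
            fit_threshold([0.1, 0.9], [1, 0])

    def test_non_binary_outcomes_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            fit_threshold([0.1, 0.2, 0.3, 0.4], [0, 1, 2, 0])

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0.9, 0.1, 30), rng.normal(0.5, 0.1, 10)])
        y = np.concatenate([np.zeros(30), np.ones(10)])
        m1 = fit_threshold(x, y)
        perm = rng.permutation(x.size)
        m2 = fit_threshold(x[perm], y[perm])
        assert m2.a == pytest.approx(m1.a, rel=1e-6)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(8)
        # overlapping classes: the least-squares optimum is well defined
        x = np.concatenate([rng.normal(0.9, 0.15, 40), rng.normal(0.5, 0.15, 12)])
        y = np.concatenate([np.zeros(40), np.ones(12)])
        alpha, beta = 37.5, -4.0
        m = fit_threshold(x, y)
        mt = fit_threshold(alpha * x + beta, y)
        assert mt.a == pytest.approx(alpha * m.a + beta, rel=1e-3)
        assert mt.k == pytest.approx(m.k / alpha, rel=1e-3)


class TestClassifySession:
    def test_reported_class_centres_classified(self):
        thresholds = default_thresholds()
        assert classify_session(metrics_with(0.44, 390.0), thresholds).label == "extravasation"
        assert classify_session(metrics_with(0.91, 24.0), thresholds).label == "normal"
        assert classify_session(metrics_with(0.77, 150.0), thresholds).label == "abnormal"

    def test_value_exactly_at_threshold_is_not_extravasation(self):
        thresholds = default_thresholds()
        res = classify_session(metrics_with(0.61, 302.0), thresholds)
        assert res.label != "extravasation"

    def test_either_metric_crossing_suffices(self):
        thresholds = default_thresholds()
        assert classify_session(metrics_with(0.90, 400.0), thresholds).label == "extravasation"
        assert classify_session(metrics_with(0.40, 24.0), thresholds).label == "extravasation"

    def test_single_detector_decision_is_flagged(self):
        res = classify_session(metrics_with(0.44, None), default_thresholds())
        assert res.label == "extravasation"
        assert res.delta_p_only

    def test_custom_abnormal_band(self):
        band = AbnormalBand(delta_p_nor_lower=0.85, delta_r_6min_upper=46.0)
        res = classify_session(metrics_with(0.80, 24.0), default_thresholds(), band)
        assert res.label == "abnormal"

    def test_threshold_persistence_roundtrip(self, tmp_path):
        path = tmp_path / "thresholds.json"
        models = default_thresholds()
        save_thresholds(models, path)
        back = load_thresholds(path)
        assert back == models


class TestSampleSizeAuc:
    def test_published_design_needs_about_a_thousand_patients(self):
        n = sample_size_auc(SampleSizeSpec(0.80, 0.90, 0.05, 0.90, 0.06))
        assert 800 <= n <= 1200

    def test_monotone_in_effect_size(self):
        base = sample_size_auc(SampleSizeSpec(auc_alt=0.90))
        bigger_gap = sample_size_auc(SampleSizeSpec(auc_alt=0.95))
        assert bigger_gap < base

    def test_monotone_in_alpha_and_power(self):
        base = sample_size_auc(SampleSizeSpec())
        assert sample_size_auc(SampleSizeSpec(alpha=0.01)) > base
        assert sample_size_auc(SampleSizeSpec(power=0.95)) > base

    def test_balanced_prevalence_needs_fewer_patients(self):
        skewed = sample_size_auc(SampleSizeSpec(prevalence=0.06))
        balanced = sample_size_auc(SampleSizeSpec(prevalence=0.5))
        assert balanced < skewed

    def test_vanishing_effect_diverges(self):
        n1 = sample_size_auc(SampleSizeSpec(auc_alt=0.85))
        n2 = sample_size_auc(SampleSizeSpec(auc_alt=0.81))
        assert n2 > n1 > sample_size_auc(SampleSizeSpec(auc_alt=0.90))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(auc_null=0.9, auc_alt=0.8)

    def test_power_verified_by_simulation(self):
        """Monte-Carlo oracle: at the computed n, the one-sided AUC test
        under a binormal model attains roughly the design power."""
        spec = SampleSizeSpec(0.80, 0.90, 0.05, 0.90, 0.5)
        n = sample_size_auc(spec)
        n_pos = int(round(spec.prevalence * n))
        n_neg = n - n_pos
        mu = np.sqrt(2.0) * 1.2815515655446004  # separation giving AUC 0.9
        from scipy.stats import norm, rankdata

        q1 = spec.auc_null / (2 - spec.auc_null)
        q2 = 2 * spec.auc_null**2 / (1 + spec.auc_null)
        var0 = (
            spec.auc_null * (1 - spec.auc_null)
            + (n_pos - 1) * (q1 - spec.auc_null**2)
            + (n_neg - 1) * (q2 - spec.auc_null**2)
        ) / (n_pos * n_neg)
        crit = spec.auc_null + norm.ppf(1 - spec.alpha) * np.sqrt(var0)
        rng = np.random.default_rng(99)
        hits = 0
        reps = 400
        for _ in range(reps):
            neg = rng.standard_normal(n_neg)
            pos = rng.standard_normal(n_pos) + mu
            ranks = rankdata(np.concatenate([neg, pos]))
            auc = (ranks[n_neg:].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
            hits += auc > crit
        assert hits / reps > 0.80  # design power 0.90, allow MC slack


class TestThresholdModel:
    def test_zero_slope_rejected(self):
        with pytest.raises(FitError):
            ThresholdModel("m", k=0.0, a=1.0, direction="extravasation_below")

    def test_direction_semantics(self):
        below = ThresholdModel("m", k=-5.0, a=0.5, direction="extravasation_below")
        above = ThresholdModel("m", k=5.0, a=300.0, direction="extravasation_above")
        assert below.flags_extravasation(0.4) and not below.flags_extravasation(0.6)
        assert above.flags_extravasation(350.0) and not above.flags_extravasation(250.0)
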