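"""Timing-process generators, accelerometer synthesis, and study simulation."""
import logging

import numpy as np
import pytest

from isochron.errors import ValidationError
from isochron.stats import lag_autocorr, lag_one_autocorr, windowed_lag_one
from isochron.synthetic import (
    EmergentParams,
    EventBasedParams,
    StudyDesign,
    gen_accel_trace,
    gen_emergent,
    gen_event_based,
    gen_study,
    gen_switching,
)


class TestEventBased:
    def test_noise_free_series_is_exactly_isochronous(self):
        s = gen_event_based(EventBasedParams(500, 0, 0), 100, seed=0)
        assert np.all(s.durations_ms == 500.0)

    def test_pure_motor_delay_reaches_the_minus_half_limit(self):
        s = gen_event_based(EventBasedParams(500, 0, 10), 100_000, seed=1)
        assert lag_one_autocorr(s) == pytest.approx(-0.5, abs=0.02)

    def test_mixed_variances_follow_the_closed_form(self):
        # -sd_M^2 / (sd_T^2 + 2 sd_M^2) = -100/600 = -1/6
        s = gen_event_based(EventBasedParams(500, 20, 10), 100_000, seed=1)
        assert lag_one_autocorr(s) == pytest.approx(-1 / 6, abs=0.02)
        assert lag_autocorr(s.durations_ms, 2) == pytest.approx(0.0, abs=0.02)

    def test_lag_one_autocovariance_matches_minus_motor_variance(self):
        p = EventBasedParams(500, 20, 10)
        s = gen_event_based(p, 200_000, seed=4)
        x = s.durations_ms - s.durations_ms.mean()
        acov1 = float(np.dot(x[:-1], x[1:]) / (len(x) - 1))
        assert acov1 == pytest.approx(-p.motor_delay_sd_ms**2, rel=0.1)

    def test_invalid_arguments(self):
        with pytest.raises(ValidationError):
            gen_event_based(EventBasedParams(500, 10, 5), 1, seed=0)
        with pytest.raises(ValidationError):
            EventBasedParams(500, -1, 5)
        with pytest.raises(ValidationError):
            EventBasedParams(0, 1, 1)

    def test_implied_lag_one_is_bounded(self):
        assert -0.5 <= EventBasedParams(500, 0, 50).lag_one_autocorr <= 0
        assert EventBasedParams(500, 10, 0).lag_one_autocorr == 0.0

    def test_negative_durations_are_resampled(self, caplog):
        with caplog.at_level(logging.WARNING, logger="isochron.synthetic"):
            s = gen_event_based(EventBasedParams(50, 40, 0), 2_000, seed=2)
        assert np.all(s.durations_ms > 0)
        assert any("resampled" in r.message for r in caplog.records)


class TestEmergent:
    def test_white_noise_limit(self):
        s = gen_emergent(EmergentParams(500, 0.0, 10), 100_000, seed=3)
        assert lag_one_autocorr(s) == pytest.approx(0.0, abs=0.02)

    def test_stationary_autocorrelation_equals_the_coefficient(self):
        s = gen_emergent(EmergentParams(500, 0.4, 10), 100_000, seed=3)
        assert lag_one_autocorr(s) == pytest.approx(0.4, abs=0.02)

    @pytest.mark.parametrize("lag", [2, 3])
    def test_higher_lags_decay_geometrically(self, lag):
        s = gen_emergent(EmergentParams(500, 0.4, 10), 100_000, seed=3)
        assert lag_autocorr(s.durations_ms, lag) == pytest.approx(0.4**lag, abs=0.02)

    def test_zero_innovation_gives_constant_series(self):
        s = gen_emergent(EmergentParams(500, 0.3, 0.0), 50, seed=0)
        assert np.all(s.durations_ms == 500.0)

    @pytest.mark.parametrize("phi", [-0.1, 0.5, 0.9])
    def test_coefficient_domain(self, phi):
        with pytest.raises(ValidationError):
            EmergentParams(500, phi, 10)


class TestSwitching:
    def test_single_segment_matches_plain_generator(self):
        p = EventBasedParams(500, 20, 10)
        a = gen_switching([(p, 200)], seed=7)
        b = gen_event_based(p, 200, seed=7)
        assert np.array_equal(a.durations_ms, b.durations_ms)

    def test_zero_noise_segments_form_a_step_function(self):
        segs = [(EventBasedParams(400, 0, 0), 50), (EventBasedParams(600, 0, 0), 50)]
        s = gen_switching(segs, seed=0)
        assert np.all(s.durations_ms[:50] == 400.0)
        assert np.all(s.durations_ms[50:] == 600.0)
        assert list(s.regime_labels[:50]) == ["event_based"] * 50

    def test_empty_segment_list_rejected(self):
        with pytest.raises(ValidationError):
            gen_switching([], seed=0)

    def test_windowed_sign_flips_across_the_regime_boundary(self):
        """Event-based then emergent: window signs flip negative -> positive."""
        hits = 0
        n_rep = 100
        for r in range(n_rep):
            s = gen_switching(
                [(EventBasedParams(500, 20, 10), 200), (EmergentParams(500, 0.4, 10), 200)],
                seed=30_000 + r,
            )
            w = windowed_lag_one(s, 30)
            if np.mean(w[:150] < 0) > 0.5 and np.mean(w[-150:] > 0) > 0.5:
                hits += 1
        assert hits >= 90


class TestAccelTrace:
    def test_minima_spacing_for_constant_intervals(self):
        from isochron.kinematics import detect_flexion_minima

        s = gen_event_based(EventBasedParams(500, 0, 0), 20, seed=0)
        trace = gen_accel_trace(s, sample_rate_hz=200, noise_sd=0.0)
        events = detect_flexion_minima(trace)
        idx = np.round(events * 200).astype(int)
        inner = idx[(events > 5.5) & (events < trace.t_s[-1] - 5.5)]
        assert np.all(np.diff(inner) == 100)

    def test_signal_channel_carries_the_oscillation(self):
        s = gen_event_based(EventBasedParams(500, 0, 0), 10, seed=0)
        trace = gen_accel_trace(s, noise_sd=0.0, signal_channel=1)
        variances = trace.channels.var(axis=0)
        assert np.argmax(variances) == 1

    def test_empty_series_rejected(self):
        empty = gen_event_based(EventBasedParams(500, 0, 0), 2, seed=0)
        empty.durations_ms = np.empty(0)
        with pytest.raises(ValidationError):
            gen_accel_trace(empty)

    def test_nonpositive_sample_rate_rejected(self):
        s = gen_event_based(EventBasedParams(500, 0, 0), 5, seed=0)
        with pytest.raises(ValidationError):
            gen_accel_trace(s, sample_rate_hz=0)


class TestStudy:
    def test_zero_variability_design_reproduces_expected_durations(self):
        design = StudyDesign(
            n_subjects=2,
            sets_per_tempo=1,
            intervals_per_set=10,
            within_individual_sd=0.0,
            within_set_sd=0.0,
            residual_sd_nktt=0.0,
            mean_error_slow=0.0,
            tempo_effect=0.0,
        )
        study = gen_study(design, seed=0)
        for s in study.series:
            assert np.all(s.durations_ms == s.expected_ms)

    def test_same_seed_is_bit_identical(self, small_design):
        a = gen_study(small_design, seed=9)
        b = gen_study(small_design, seed=9)
        for sa, sb in zip(a.series, b.series):
            assert np.array_equal(sa.durations_ms, sb.durations_ms)
        assert a.set_labels == b.set_labels

    def test_different_seeds_differ(self, small_design):
        a = gen_study(small_design, seed=9)
        b = gen_study(small_design, seed=10)
        assert not np.array_equal(a.series[0].durations_ms, b.series[0].durations_ms)

    def test_pooled_residual_variance_ratio_converges(self):
        design = StudyDesign(n_subjects=10, sets_per_tempo=2, intervals_per_set=200)
        df = gen_study(design, seed=21).error_frame()
        per_set = df.groupby("set").agg(
            ktt=("ktt", "first"), v=("response_s", lambda y: np.var(y, ddof=1))
        )
        pooled = per_set[per_set.ktt == 1].v.mean() / per_set[per_set.ktt == 0].v.mean()
        assert pooled == pytest.approx(design.ktt_variance_ratio, rel=0.05)

    def test_fixed_effect_structure_in_the_errors(self):
        design = StudyDesign(
            n_subjects=40,
            sets_per_tempo=2,
            intervals_per_set=40,
            within_individual_sd=0.0,
            within_set_sd=0.0,
            residual_sd_nktt=0.001,
        )
        df = gen_study(design, seed=5).error_frame()
        slow = df[df.speed == "slow"].response_s.mean()
        fast = df[df.speed == "fast"].response_s.mean()
        assert slow == pytest.approx(design.mean_error_slow, abs=3e-4)
        assert fast - slow == pytest.approx(design.tempo_effect, abs=3e-4)

    def test_emergent_probability_controls_the_labels(self):
        design = StudyDesign(
            n_subjects=4, sets_per_tempo=1, emergent_prob_ktt=1.0, emergent_prob_nktt=0.0
        )
        study = gen_study(design, seed=3)
        for (subject, case, *_), label in study.set_labels.items():
            assert label == ("emergent" if case == "KTT" else "event_based")
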