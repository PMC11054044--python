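"""Moving-mean threshold breath detection."""

import numpy as np
import pytest

from masksignal import (
    BreathDetector,
    BreathingModel,
    DetectorConfig,
    ValidationError,
    detect_breaths,
    moving_mean,
    peak_to_peak_stats,
    simulate_session,
)

from conftest import make_sine


class TestMovingMean:
    def test_constant_series_is_unchanged(self):
        x = np.full(50, 3.7)
        assert np.allclose(moving_mean(x, 5), 3.7)

    def test_shrinking_edge_means_hand_computed(self):
        out = moving_mean(np.array([0.0, 1, 2, 3, 4]), 3)
        assert np.allclose(out, [0.5, 1, 2, 3, 3.5])

    def test_full_period_window_averages_sine_to_zero(self):
        t, x = make_sine(12.0, 60.0)  # 5 s period
        mm = moving_mean(x, 50)  # window = one period
        interior = mm[50:-50]
        assert np.max(np.abs(interior)) < 1e-10

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValidationError):
            moving_mean(np.zeros(10), 11)

    def test_window_below_two_samples_raises(self):
        with pytest.raises(ValidationError):
            moving_mean(np.zeros(10), 1)


class TestDetectBreaths:
    def test_clean_sine_counts_every_cycle(self):
        t, x = make_sine(15.0, 60.0)
        res = detect_breaths(x, 10.0, DetectorConfig(hysteresis=0.0))
        assert res.n_events == 15
        assert res.rate == pytest.approx(15.0)

    def test_constant_series_yields_zero_events_not_error(self):
        res = detect_breaths(np.full(1200, 5.0), 10.0)
        assert res.n_events == 0
        assert res.rate == 0.0

    def test_rate_invariant_to_offset_and_scale(self):
        t, x = make_sine(12.0, 120.0)
        cfg = DetectorConfig(hysteresis=0.0)
        base = detect_breaths(x, 10.0, cfg).rate
        assert detect_breaths(x + 1000.0, 10.0, cfg).rate == base
        assert detect_breaths(7.5 * x, 10.0, cfg).rate == base

    def test_series_shorter_than_two_windows_raises(self):
        with pytest.raises(ValidationError):
            detect_breaths(np.zeros(60), 10.0, DetectorConfig(window=5.0))

    def test_refractory_suppresses_split_peaks(self):
        # two crossings 0.8 s apart must merge into one event
        t = np.arange(0.0, 60.0, 0.1)
        x = -np.cos(2 * np.pi * t / 6.0)
        x += 1.5 * np.exp(-0.5 * ((t % 6.0 - 2.2) / 0.2) ** 2) * -1.0
        n_loose = detect_breaths(
            x, 10.0, DetectorConfig(min_breath_interval=0.3, hysteresis=0.0)
        ).n_events
        n_tight = detect_breaths(
            x, 10.0, DetectorConfig(min_breath_interval=2.5, hysteresis=0.0)
        ).n_events
        assert n_loose > n_tight

    def test_amplitude_gate_rejects_subthreshold_oscillation(self):
        t, x = make_sine(12.0, 120.0, amp=0.01)
        res = detect_breaths(x, 10.0, DetectorConfig(min_amplitude=1.0, hysteresis=0.0))
        assert res.n_events == 0


class TestPeakToPeak:
    def test_sine_per_breath_p2p_is_twice_amplitude(self):
        t, x = make_sine(12.0, 120.0, amp=3.0)
        res = detect_breaths(x, 10.0, DetectorConfig(hysteresis=0.0))
        stats = peak_to_peak_stats(x, 10.0, res.event_times)
        assert stats["mean"] == pytest.approx(6.0, rel=0.02)

    def test_no_events_gives_empty_summary(self):
        assert peak_to_peak_stats(np.zeros(100), 10.0, np.array([])) == {}


class TestOnSimulatedSessions:
    def test_inner_pressure_p2p_in_band_outer_below_10pa(self, short_session):
        inner = BreathDetector.from_record(short_session, "inner_pressure").fit()
        assert 20.0 <= np.mean(inner.per_breath_p2p) <= 40.0
        outer = BreathDetector.from_record(short_session, "outer_pressure").fit()
        assert np.mean(outer.per_breath_p2p) < 10.0

    def test_rate_recovery_across_band(self, street_script):
        for rate in (6.0, 12.0, 20.0):
            for seed in (0, 1, 2):
                rec = simulate_session(street_script, BreathingModel(rate=rate), seed=seed)
                for ch in ("inner_pressure", "inner_temp"):
                    det = BreathDetector.from_record(rec, ch).fit()
                    assert abs(det.rate - rate) <= 1.0, (rate, seed, ch)

    def test_stutters_raise_pressure_count_above_temperature(self, street_script):
        # breath stutters appear in the pressure channel but are smoothed
        # away by thermal inertia, so pressure counts >= temperature counts
        for seed in range(5):
            rec = simulate_session(
                street_script, BreathingModel(rate=9.0, stutter_prob=0.3), seed=seed
            )
            n_p = BreathDetector.from_record(rec, "inner_pressure").fit().n_events
            n_t = BreathDetector.from_record(rec, "inner_temp").fit().n_events
            assert n_p >= n_t

    def test_summary_mentions_rate_and_source(self, short_session):
        res = BreathDetector.from_record(short_session, "inner_pressure").fit()
        text = res.summary()
        assert "inner_pressure" in text and "breaths/min" in text
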