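"""Simulator signal structure, determinism, and quantization."""

import numpy as np
import pytest

from masksignal import (
    BreathDetector,
    BreathingModel,
    RangeError,
    ScenarioScript,
    Segment,
    SensorSpec,
    ValidationError,
    moving_mean,
    saturation_profile,
    simulate_session,
)


class TestSaturationProfile:
    def test_starts_at_ambient_humidity(self):
        assert saturation_profile(0.0, start=40.0) == pytest.approx(40.0)

    def test_reaches_95_percent_within_30_minutes(self):
        assert saturation_profile(30 * 60.0) >= 95.0

    def test_monotone_and_bounded_by_100(self):
        t = np.linspace(0, 10_000, 2000)
        rh = saturation_profile(t)
        assert (np.diff(rh) >= 0).all()
        assert (rh <= 100.0).all()

    def test_negative_time_raises(self):
        with pytest.raises(ValidationError):
            saturation_profile(-1.0)


class TestSimulateSession:
    def test_bit_identical_under_same_seed(self, street_script):
        b = BreathingModel(rate=11.0, stutter_prob=0.2)
        r1 = simulate_session(street_script, b, seed=42)
        r2 = simulate_session(street_script, b, seed=42)
        assert r1.equals(r2, atol=0.0)

    def test_different_seeds_differ(self, street_script):
        r1 = simulate_session(street_script, seed=1)
        r2 = simulate_session(street_script, seed=2)
        assert not r1.equals(r2)

    def test_cycle_count_matches_scripted_rate(self, street_script):
        # 2 min at 11/min -> 22 oscillation cycles
        rec = simulate_session(street_script, BreathingModel(rate=11.0), seed=1)
        det = BreathDetector.from_record(rec, "inner_pressure").fit()
        assert abs(det.n_events - 22) <= 1

    def test_no_excitation_zero_noise_gives_flat_series(self):
        script = ScenarioScript(
            segments=[Segment("street", 60.0, ambient_temp=10.0)]
        )
        b = BreathingModel(
            inner_pressure_p2p=0.0,
            outer_pressure_p2p=0.0,
            inner_temp_p2p=0.0,
            outer_temp_p2p=0.0,
        )
        rec = simulate_session(script, b, seed=0, noise_scale=0.0)
        p = rec.channel("inner_pressure")
        assert np.ptp(p[100:]) <= 0.18 + 1e-9  # flat at baseline, one LSB
        assert np.allclose(p[100:], 101_325.0, atol=0.2)
        t_in = rec.channel("inner_temp")
        assert np.ptp(t_in[-100:]) <= 0.01 + 1e-9

    def test_stairs_shift_outer_pressure_by_floor_drops(self):
        script = ScenarioScript(
            segments=[
                Segment("street", 30.0),
                Segment("stairs", 40.0, floor_delta=2),
                Segment("indoors", 30.0),
            ]
        )
        rec = simulate_session(script, seed=3)
        p = rec.channel("outer_pressure")
        drop = np.mean(p[-50:]) - np.mean(p[:50])
        assert drop == pytest.approx(-2 * 57.5, abs=2.0)

    def test_temperature_lags_pressure_by_three_seconds(self, short_session):
        fs = short_session.sample_rate
        bp = short_session.channel("inner_pressure")
        bt = short_session.channel("inner_temp")
        bp = bp - moving_mean(bp, 50)
        bt = bt - moving_mean(bt, 50)
        lags = np.arange(0, 45)
        cc = [np.dot(bt[l:], bp[: bp.size - l]) for l in lags]
        peak = lags[int(np.argmax(cc))]
        assert abs(peak - 3.0 * fs) <= 1

    def test_channels_quantized_to_sensor_resolutions(self, short_session):
        spec = SensorSpec()
        for ch, res in (
            ("inner_temp", spec.temp_resolution),
            ("inner_pressure", spec.pressure_resolution),
            ("inner_humidity", spec.humidity_resolution),
        ):
            x = short_session.channel(ch)
            steps = x / res
            assert np.allclose(steps, np.round(steps), atol=1e-6), ch

    def test_aqi_accuracy_progresses_zero_to_three(self):
        script = ScenarioScript(
            segments=[Segment("street", 2500.0, ambient_aqi=60.0)],
            accuracy_times=(300.0, 1200.0, 2000.0),
        )
        rec = simulate_session(script, seed=0)
        acc = rec.channel("outer_aqi_accuracy")
        assert acc[0] == 0 and acc[-1] == 3
        assert (np.diff(acc) >= 0).all()
        assert set(np.unique(acc)) == {0, 1, 2, 3}

    def test_empty_script_rejected(self):
        with pytest.raises(ValidationError):
            simulate_session(ScenarioScript(segments=[]), seed=0)

    def test_out_of_range_baseline_rejected(self):
        with pytest.raises(RangeError):
            Segment("street", 10.0, pressure_baseline=200_000.0)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValidationError):
            Segment("street", 0.0)


class TestBreathingModelValidation:
    def test_outer_swing_must_not_exceed_inner(self):
        with pytest.raises(ValidationError):
            BreathingModel(inner_pressure_p2p=5.0, outer_pressure_p2p=6.0)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValidationError):
            BreathingModel(rate=0.0)
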