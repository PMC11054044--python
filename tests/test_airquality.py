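"""AQI classification, gating, humidity validity, and zone segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masksignal import (
    AQI_CLASSES,
    ScenarioScript,
    Segment,
    ValidationError,
    classify_aqi,
    gate_by_accuracy,
    humidity_validity,
    segment_zones,
    simulate_session,
)


class TestClassifyAqi:
    @pytest.mark.parametrize(
        "value,label",
        [
            (25, "excellent"),
            (75, "good"),
            (125, "lightly polluted"),
            (175, "moderately polluted"),
            (225, "heavily polluted"),
            (300, "severely polluted"),
            (400, "extremely polluted"),
            (350, "severely polluted"),
            (351, "extremely polluted"),
        ],
    )
    def test_class_examples(self, value, label):
        assert classify_aqi(value) == label

    @given(v=st.floats(0.0, 500.0))
    @settings(max_examples=200, deadline=None)
    def test_total_on_range_and_monotone(self, v):
        label = classify_aqi(v)
        labels = [lab for _, lab in AQI_CLASSES]
        # class index is monotone in the value
        assert labels.index(label) <= labels.index(classify_aqi(min(v + 60.0, 500.0)))

    def test_classes_partition_the_range(self):
        uppers = [hi for hi, _ in AQI_CLASSES]
        assert uppers == sorted(uppers) and uppers[-1] == 500

    @pytest.mark.parametrize("bad", [-1.0, 501.0, float("nan")])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            classify_aqi(bad)


class TestGating:
    def test_all_calibrated_all_reliable(self):
        t = np.arange(10.0)
        g = gate_by_accuracy(np.zeros(10), np.full(10, 3), t)
        assert g.reliable.all() and g.time_to_reliability == 0.0

    def test_all_stabilizing_none_reliable(self):
        t = np.arange(10.0)
        g = gate_by_accuracy(np.zeros(10), np.zeros(10, int), t)
        assert not g.reliable.any() and g.time_to_reliability is None

    def test_degenerate_gate_marks_everything_reliable(self):
        t = np.arange(10.0)
        g = gate_by_accuracy(np.zeros(10), np.array([0, 0, 1, 1, 2, 2, 3, 3, 3, 3]), t, min_status=0)
        assert g.reliable.all()

    def test_simulator_default_reliability_after_30_minutes(self):
        script = ScenarioScript(
            segments=[Segment("street", 2400.0, ambient_aqi=60.0)]
        )
        rec = simulate_session(script, seed=0)
        g = gate_by_accuracy(
            rec.channel("outer_aqi"), rec.channel("outer_aqi_accuracy"), rec.time
        )
        assert g.time_to_reliability is not None
        assert g.time_to_reliability > 30 * 60.0


class TestHumidityValidity:
    def test_dry_channel_valid_throughout(self):
        res = humidity_validity(np.full(1200, 40.0), 10.0)
        assert not res.saturated and res.valid_until is None

    def test_single_sample_spike_does_not_invalidate(self):
        h = np.full(1200, 40.0)
        h[600] = 96.0
        res = humidity_validity(h, 10.0)
        assert not res.saturated

    def test_sustained_saturation_invalidates_at_onset(self):
        h = np.full(2400, 40.0)
        h[1200:] = 96.0
        res = humidity_validity(h, 10.0)
        assert res.saturated
        assert res.valid_until == pytest.approx(120.0, abs=0.2)

    def test_simulated_session_invalidates_between_20_and_30_minutes(self):
        script = ScenarioScript(segments=[Segment("street", 1900.0)])
        rec = simulate_session(script, seed=2)
        res = humidity_validity(rec.channel("inner_humidity"), rec.sample_rate)
        assert res.saturated
        assert 20 * 60.0 <= res.valid_until <= 30 * 60.0


class TestZoneSegmentation:
    def test_flat_session_is_single_segment(self):
        script = ScenarioScript(segments=[Segment("street", 300.0, ambient_temp=0.0)])
        rec = simulate_session(script, seed=0)
        segs = segment_zones(
            rec.channel("outer_temp"),
            rec.channel("outer_aqi"),
            rec.channel("outer_aqi_accuracy"),
            rec.sample_rate,
        )
        assert len(segs) == 1
        assert segs[0].label == "outdoor"

    def test_street_shop_street_gives_three_segments_near_truth(self):
        script = ScenarioScript(
            segments=[
                Segment("street", 300.0, ambient_temp=0.0, ambient_aqi=60.0),
                Segment("shop", 300.0, ambient_temp=22.0, ambient_aqi=140.0),
                Segment("street", 300.0, ambient_temp=0.0, ambient_aqi=60.0),
            ]
        )
        rec = simulate_session(script, seed=1)
        segs = segment_zones(
            rec.channel("outer_temp"),
            rec.channel("outer_aqi"),
            rec.channel("outer_aqi_accuracy"),
            rec.sample_rate,
        )
        assert [s.label for s in segs] == ["outdoor", "indoor", "outdoor"]
        # boundaries within two windows of the scripted transitions
        assert segs[0].end_s == pytest.approx(300.0, abs=120.0)
        assert segs[1].end_s == pytest.approx(600.0, abs=120.0)

    def test_segments_tile_session_without_overlap(self):
        script = ScenarioScript(
            segments=[
                Segment("street", 300.0, ambient_temp=0.0),
                Segment("shop", 300.0, ambient_temp=22.0),
            ]
        )
        rec = simulate_session(script, seed=3)
        segs = segment_zones(
            rec.channel("outer_temp"),
            rec.channel("outer_aqi"),
            rec.channel("outer_aqi_accuracy"),
            rec.sample_rate,
        )
        assert segs[0].start_s == 0.0
        assert segs[-1].end_s == pytest.approx(rec.duration)
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.end_s == b.start_s

    def test_unreliable_aqi_creates_no_boundaries(self):
        # AQI steps before calibration must not split the session; the
        # temperature is flat, so one segment results
        script = ScenarioScript(
            segments=[
                Segment("street", 300.0, ambient_temp=0.0, ambient_aqi=20.0),
                Segment("street", 300.0, ambient_temp=0.0, ambient_aqi=180.0),
            ],
            accuracy_times=(2000.0, 2100.0, 2200.0),  # never reliable here
        )
        rec = simulate_session(script, seed=0)
        segs = segment_zones(
            rec.channel("outer_temp"),
            rec.channel("outer_aqi"),
            rec.channel("outer_aqi_accuracy"),
            rec.sample_rate,
        )
        assert len(segs) == 1

    def test_calibrated_outdoor_aqi_in_scripted_band(self):
        script = ScenarioScript(
            segments=[Segment("street", 600.0, ambient_temp=0.0, ambient_aqi=75.0)],
            accuracy_times=(10.0, 20.0, 30.0),
        )
        rec = simulate_session(script, seed=5)
        segs = segment_zones(
            rec.channel("outer_temp"),
            rec.channel("outer_aqi"),
            rec.channel("outer_aqi_accuracy"),
            rec.sample_rate,
        )
        assert len(segs) == 1
        assert 50.0 <= segs[0].mean_aqi <= 100.0
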