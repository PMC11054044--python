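"""Temperature-pressure source selection and fused respiration."""

import numpy as np
import pytest

from masksignal import (
    BreathingModel,
    RespirationFusion,
    ScenarioScript,
    Segment,
    SourceState,
    ValidationError,
    drift_rate,
    select_source,
    simulate_session,
)

from conftest import make_sine


class TestDriftRate:
    def test_linear_ramp_slope_is_exact(self):
        t = np.arange(0.0, 60.0, 0.1)
        x = 0.2 / 60.0 * t  # 0.2 °C over 60 s
        assert drift_rate(x, 10.0) == pytest.approx(0.2, abs=1e-9)

    def test_constant_series_has_zero_drift(self):
        assert drift_rate(np.full(600, 7.0), 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_breath_sine_has_negligible_drift(self):
        t, x = make_sine(12.0, 60.0, amp=0.4)
        assert abs(drift_rate(x + 23.0, 10.0)) < 0.02

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValidationError):
            drift_rate(np.zeros(100), 10.0, window=60.0)

    def test_sign_preserved(self):
        t = np.arange(0.0, 60.0, 0.1)
        assert drift_rate(-0.5 / 60.0 * t, 10.0) == pytest.approx(-0.5, abs=1e-9)


class TestSelectSource:
    @pytest.mark.parametrize(
        "temp_drift,pressure_drift,expected",
        [
            (0.05, 5.0, SourceState.TEMPERATURE),
            (0.5, 5.0, SourceState.PRESSURE),
            (0.5, 60.0, SourceState.PAUSED),
            (-0.5, -60.0, SourceState.PAUSED),  # absolute values compared
            (0.1, 30.0, SourceState.TEMPERATURE),  # thresholds inclusive
        ],
    )
    def test_switching_rule(self, temp_drift, pressure_drift, expected):
        assert select_source(temp_drift, pressure_drift) is expected

    def test_story_transition_alone_never_pauses(self):
        # ~57.5 Pa over 10 s with steady temperature: stays on temperature
        assert select_source(0.02, 57.5) is SourceState.TEMPERATURE

    def test_nonfinite_drift_rejected(self):
        with pytest.raises(ValidationError):
            select_source(float("nan"), 0.0)


class TestFusedRespiration:
    def test_flat_ambience_selects_temperature_everywhere(self, street_script):
        rec = simulate_session(street_script, BreathingModel(rate=12.0), seed=4)
        res = RespirationFusion(rec).fit()
        assert (res.windows["active_source"] == "TEMPERATURE").all()
        assert (res.windows["rate"] - 12.0).abs().max() <= 1.0

    def test_temperature_step_switches_to_pressure_and_rate_survives(self):
        script = ScenarioScript(
            segments=[
                Segment("street", 240.0, ambient_temp=0.0),
                Segment("shop", 240.0, ambient_temp=22.0),
            ]
        )
        rec = simulate_session(script, BreathingModel(rate=12.0), seed=3)
        res = RespirationFusion(rec).fit()
        w = res.windows
        assert (w["raw_source"] == "PRESSURE").any()
        # windows fully inside the thermal transient run on pressure
        inside = w[(w["start_s"] >= 240.0) & (w["end_s"] <= 360.0)]
        assert (inside["raw_source"] == "PRESSURE").all()
        assert (w["rate"].dropna() - 12.0).abs().max() <= 1.0
        assert not w["waiting"].any()

    def test_simultaneous_step_and_climb_pauses(self):
        script = ScenarioScript(
            segments=[
                Segment("street", 180.0, ambient_temp=0.0),
                Segment("stairs", 120.0, ambient_temp=22.0, floor_delta=8),
                Segment("indoors", 180.0),
            ],
            stair_ramp_s=15.0,
            stair_landing_s=0.0,
        )
        rec = simulate_session(script, seed=2)
        res = RespirationFusion(rec).fit()
        w = res.windows
        assert (w["raw_source"] == "PAUSED").any()
        paused = w[w["waiting"]]
        assert len(paused) and paused["rate"].isna().all()

    def test_record_shorter_than_window_rejected(self):
        script = ScenarioScript(segments=[Segment("street", 30.0)])
        rec = simulate_session(script, seed=0)
        with pytest.raises(ValidationError):
            RespirationFusion(rec).fit()

    def test_fused_equals_single_channel_when_one_source_used(self, street_script):
        from masksignal import BreathDetector

        rec = simulate_session(street_script, BreathingModel(rate=12.0), seed=4)
        res = RespirationFusion(rec).fit()
        assert (res.windows["active_source"] == "TEMPERATURE").all()
        cfg = res.detector_config
        for _, row in res.windows.iterrows():
            sub = rec.slice(row.start_s, row.end_s)
            det = BreathDetector.from_record(sub, "inner_temp", cfg).fit()
            # from_record resolves the amplitude gate from the sensor spec,
            # the fusion path uses the raw config: counts agree regardless
            assert det.rate == pytest.approx(row.rate, abs=1.0)

    def test_summary_reports_sources_and_rate(self, street_script):
        rec = simulate_session(street_script, seed=0)
        text = RespirationFusion(rec).fit().summary()
        assert "TEMPERATURE" in text and "breaths/min" in text
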