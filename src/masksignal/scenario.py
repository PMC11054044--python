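"""Scenario scripts and breathing models for the session simulator.

A :class:`ScenarioScript` is an ordered list of :class:`Segment` objects —
street, shop, bus, indoors, stairs — each carrying the ambient conditions
the wearer moves through.  A :class:`BreathingModel` describes the wearer's
respiration as seen by the in-mask sensors.  Both are plain dataclasses and
round-trip through YAML so scenarios can be scripted from the command line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import RangeError, ValidationError
from .sensors import PRESSURE_RANGE_PA

SEGMENT_LABELS = ("street", "shop", "bus", "indoors", "stairs", "custom")

WAVEFORMS = ("sinusoid", "asymmetric")


@dataclass
class BreathingModel:
    """Respiration as the dual sensors see it.

    Parameters
    ----------
    rate : float
        Respiration rate, breaths/min.
    inner_pressure_p2p : float
        Peak-to-peak breath pressure swing on the in-mask side, Pa
        (field traces sit in the 20-40 Pa band).
    outer_pressure_p2p : float
        Attenuated swing on the ambient side, Pa (< 10 Pa in field traces).
    inner_temp_p2p : float
        Breath temperature swing on the in-mask side, °C (<= 1 °C).
    outer_temp_p2p : float
        Residual breath temperature swing on the ambient side, °C.
    temp_lag : float
        Thermal delay of the temperature channel behind pressure, s (~3 s:
        the sensing element's thermal inertia).
    waveform : str
        'sinusoid' or 'asymmetric' (faster exhale than inhale).
    stutter_prob : float
        Probability per breath of a split/minor sub-peak.  Stutters show in
        the pressure channel but are smoothed away by thermal inertia, so
        pressure-based counts can exceed temperature-based counts.
    exhale_temp : float
        Temperature of exhaled air heating the in-mask microclimate, °C.
    """

    rate: float = 12.0
    inner_pressure_p2p: float = 30.0
    outer_pressure_p2p: float = 6.0
    inner_temp_p2p: float = 0.8
    outer_temp_p2p: float = 0.25
    temp_lag: float = 3.0
    waveform: str = "sinusoid"
    stutter_prob: float = 0.0
    exhale_temp: float = 34.0

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValidationError(f"breathing rate must be > 0, got {self.rate}")
        if not self.outer_pressure_p2p >= 0:
            raise ValidationError("outer_pressure_p2p must be >= 0")
        # the in-mask swing always dominates; equality only in the
        # degenerate no-excitation case (both zero)
        if self.inner_pressure_p2p < self.outer_pressure_p2p or (
            self.inner_pressure_p2p == self.outer_pressure_p2p
            and self.inner_pressure_p2p > 0
        ):
            raise ValidationError(
                "inner_pressure_p2p must exceed outer_pressure_p2p "
                f"({self.inner_pressure_p2p} vs {self.outer_pressure_p2p})"
            )
        if self.temp_lag < 0:
            raise ValidationError("temp_lag must be >= 0")
        if self.waveform not in WAVEFORMS:
            raise ValidationError(f"waveform must be one of {WAVEFORMS}")
        if not 0 <= self.stutter_prob <= 1:
            raise ValidationError("stutter_prob must be a probability")


@dataclass
class Segment:
    """One scripted stretch of the session.

    ``ambient_temp``, ``ambient_aqi`` and ``pressure_baseline`` may be None,
    meaning "carry over from the previous segment".  ``floor_delta`` only
    matters for 'stairs' segments: positive = ascending (pressure drops).
    """

    label: str
    duration: float
    ambient_temp: float | None = None
    ambient_aqi: float | None = None
    floor_delta: int = 0
    pressure_baseline: float | None = None

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValidationError(
                f"segment label {self.label!r} not in {SEGMENT_LABELS}"
            )
        if not self.duration > 0:
            raise ValidationError(f"segment duration must be > 0, got {self.duration}")
        if self.pressure_baseline is not None and not (
            PRESSURE_RANGE_PA[0] <= self.pressure_baseline <= PRESSURE_RANGE_PA[1]
        ):
            raise RangeError(
                f"pressure baseline {self.pressure_baseline} Pa outside sensor "
                f"range {PRESSURE_RANGE_PA}"
            )
        if self.ambient_aqi is not None and not 0 <= self.ambient_aqi <= 500:
            raise ValidationError("ambient_aqi must lie in [0, 500]")


@dataclass
class ScenarioScript:
    """Ordered segments plus session-level simulator settings.

    Parameters
    ----------
    segments : list of Segment
        Non-empty ordered script.
    sample_rate : float
        Acquisition rate, Hz (default 10).
    ambient_rh : float
        Outdoor relative humidity, %rh.
    humidity_attenuation : float
        Fraction of ambient humidity reaching the outward sensor through
        the moisture-capturing mask fabric.
    humidity_time_constant : float
        Exponential time constant of in-mask humidity saturation, s.  The
        default (500 s from a 40 %rh start) crosses 95 %rh at ~21 min,
        inside the 20-30 min saturation window seen in wear trials.
    per_floor_pa : float
        Pressure drop per storey, Pa (55-60 Pa per floor in the two-storey
        validation; default the midpoint).
    stair_ramp_s, stair_landing_s : float
        Seconds of pressure ramp per floor and flat landing between floors.
    accuracy_times : tuple of three floats
        Session times (s) at which the AQI calibration status advances to
        1, 2 and 3.  Status >= 2 ("calibration in progress") is the usual
        reliability gate; the default places it beyond 30 min.
    outdoor_aqi_reset : bool
        If True, 'street' segments pull the AQI target to 0 (fresh outdoor
        air resetting the index) instead of using their scripted level.
    """

    segments: list[Segment] = field(default_factory=list)
    name: str = "session"
    sample_rate: float = 10.0
    ambient_rh: float = 40.0
    humidity_attenuation: float = 0.4
    humidity_time_constant: float = 500.0
    per_floor_pa: float = 57.5
    stair_ramp_s: float = 10.0
    stair_landing_s: float = 5.0
    accuracy_times: tuple[float, float, float] = (600.0, 1920.0, 2400.0)
    outdoor_aqi_reset: bool = False

    def __post_init__(self) -> None:
        if self.segments and not isinstance(self.segments[0], Segment):
            self.segments = [Segment(**s) for s in self.segments]
        if not self.sample_rate > 0:
            raise ValidationError("sample_rate must be > 0")
        if not 0 <= self.ambient_rh <= 100:
            raise ValidationError("ambient_rh must lie in [0, 100]")
        if list(self.accuracy_times) != sorted(self.accuracy_times):
            raise ValidationError("accuracy_times must be non-decreasing")

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["accuracy_times"] = list(self.accuracy_times)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioScript":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict) or "segments" not in d:
            raise ValidationError(f"{path}: scenario file needs a 'segments' list")
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"{path}: unknown scenario keys {sorted(unknown)}")
        if "accuracy_times" in d:
            d["accuracy_times"] = tuple(d["accuracy_times"])
        return cls(**d)


def winter_walk(
    stutter_prob: float = 0.0, rate: float = 12.0
) -> tuple[ScenarioScript, BreathingModel]:
    """The demo scenario: an evening winter walk through a city.

    Cold streets (~0 °C), two shop visits, a bus leg with elevated AQI, and
    a two-storey stair climb indoors at the end.  Mirrors the kind of urban
    session the monitor was worn on: in-mask temperature settles near 23 °C
    on the street and approaches 30 °C indoors, the AQI degrades in the
    shop and on the bus, and calibrated AQI arrives only after ~32 min.
    """
    segs = [
        Segment("street", 480, ambient_temp=0.0, ambient_aqi=60),
        Segment("shop", 300, ambient_temp=22.0, ambient_aqi=120),
        Segment("street", 360, ambient_temp=0.0, ambient_aqi=70),
        Segment("shop", 480, ambient_temp=22.0, ambient_aqi=200),
        Segment("street", 360, ambient_temp=0.0, ambient_aqi=60),
        Segment("bus", 360, ambient_temp=10.0, ambient_aqi=170),
        Segment("street", 300, ambient_temp=0.0, ambient_aqi=60),
        Segment("stairs", 40, ambient_temp=22.0, ambient_aqi=90, floor_delta=2),
        Segment("indoors", 180, ambient_temp=22.0, ambient_aqi=90),
    ]
    script = ScenarioScript(segments=segs, name="winter-walk")
    breathing = BreathingModel(rate=rate, stutter_prob=stutter_prob)
    return script, breathing
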