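"""AQI interpretation, channel-validity gating, and urban zone segmentation.

The outer sensor's software stack emits a relative Air Quality Index in
[0, 500] plus a calibration status in {0: stabilizing, 1: calibration
required, 2: calibration in progress, 3: calibrated}.  AQI readings are
only trustworthy once the status reaches a gate (>= 2 by default), which
takes upwards of half an hour of wear.  Separately, the in-mask humidity
channel saturates after 20-30 minutes of wear and carries no information
from then on.  Finally, sessions can be segmented into urban zones
(indoor / outdoor / transit) from characteristic steps in the outer
temperature and the reliable part of the AQI trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dsp import baseline_shifts
from .errors import ValidationError

__all__ = [
    "AQI_CLASSES",
    "classify_aqi",
    "GatingResult",
    "gate_by_accuracy",
    "HumidityValidity",
    "humidity_validity",
    "ZoneConfig",
    "ZoneSegment",
    "segment_zones",
]

#: (upper bound inclusive, class label); contiguous partition of [0, 500].
#: The vendor's printed table overlaps at "severely polluted"; the only
#: contiguous reading (251-350) is used, with the top class covering
#: 351-500.
AQI_CLASSES: tuple[tuple[float, str], ...] = (
    (50, "excellent"),
    (100, "good"),
    (150, "lightly polluted"),
    (200, "moderately polluted"),
    (250, "heavily polluted"),
    (350, "severely polluted"),
    (500, "extremely polluted"),
)


def classify_aqi(value: float) -> str:
    """Class label for an AQI value in [0, 500]."""
    if not np.isfinite(value) or not 0 <= value <= 500:
        raise ValidationError(f"AQI value {value!r} outside [0, 500]")
    for hi, label in AQI_CLASSES:
        if value <= hi:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass
class GatingResult:
    """Reliable/unreliable partition of an AQI sample sequence.

    ``reliable`` is a boolean mask over the samples;
    ``time_to_reliability`` is the first sample time with status >= the
    gate (None if never reached).
    """

    reliable: np.ndarray
    time_to_reliability: float | None
    min_status: int

    @property
    def n_reliable(self) -> int:
        return int(self.reliable.sum())

    def summary(self) -> str:
        ttr = (
            "never"
            if self.time_to_reliability is None
            else f"{self.time_to_reliability / 60:.1f} min"
        )
        return (
            f"AQI gating (status >= {self.min_status}): "
            f"{self.n_reliable}/{self.reliable.size} samples reliable, "
            f"reliable from {ttr}"
        )


def gate_by_accuracy(
    values: np.ndarray,
    accuracy: np.ndarray,
    time: np.ndarray,
    min_status: int = 2,
) -> GatingResult:
    """Partition AQI samples by calibration status.

    Samples with ``accuracy >= min_status`` are reliable.  ``min_status=0``
    is the degenerate gate marking everything reliable.
    """
    if min_status not in (0, 1, 2, 3):
        raise ValidationError("min_status must be in {0, 1, 2, 3}")
    accuracy = np.asarray(accuracy)
    time = np.asarray(time, dtype=float)
    if accuracy.size != time.size or accuracy.size != np.asarray(values).size:
        raise ValidationError("values, accuracy and time must be equal length")
    reliable = accuracy >= min_status
    idx = np.flatnonzero(reliable)
    ttr = float(time[idx[0]]) if idx.size else None
    return GatingResult(reliable=reliable, time_to_reliability=ttr, min_status=min_status)


@dataclass
class HumidityValidity:
    """Validity verdict for the in-mask humidity channel.

    ``valid_until`` is the first time saturation is sustained (None if the
    channel stays valid throughout); ``saturated`` says whether the channel
    was invalidated at all.
    """

    valid_until: float | None
    saturated: bool
    saturation_level: float
    sustain: float

    def summary(self) -> str:
        if not self.saturated:
            return "inner humidity: valid throughout the session"
        return (
            f"inner humidity: saturated (>= {self.saturation_level:g} %rh for "
            f">= {self.sustain:g} s) from {self.valid_until / 60:.1f} min; no "
            "information beyond that point"
        )


def humidity_validity(
    humidity: np.ndarray,
    sample_rate: float,
    saturation_level: float = 95.0,
    sustain: float = 60.0,
) -> HumidityValidity:
    """Flag the in-mask humidity channel invalid once saturation sustains.

    The channel is invalid from the first time ``humidity >=
    saturation_level`` holds continuously for ``sustain`` seconds.  A brief
    spike shorter than ``sustain`` does not invalidate.
    """
    h = np.asarray(humidity, dtype=float)
    if h.size == 0:
        raise ValidationError("empty humidity series")
    need = max(1, int(round(sustain * sample_rate)))
    above = h >= saturation_level
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            start = (i - need + 1) / sample_rate
            return HumidityValidity(
                valid_until=start,
                saturated=True,
                saturation_level=saturation_level,
                sustain=sustain,
            )
    return HumidityValidity(
        valid_until=None,
        saturated=False,
        saturation_level=saturation_level,
        sustain=sustain,
    )


@dataclass(frozen=True)
class ZoneConfig:
    """Zone-segmentation settings.

    Temperature is the primary evidence (always available); AQI is
    secondary and consulted only where reliable.  A segment is *indoor*
    when its mean outer temperature exceeds ``indoor_temp`` (the exhale-
    heated microclimate approaches 30 °C indoors), *transit* when the
    temperature is intermediate but the reliable AQI is elevated (e.g. a
    bus), *outdoor* otherwise, and *unknown* when the AQI is unreliable
    and the temperature is inconclusive.
    """

    temp_step: float = 3.0
    aqi_step: float = 50.0
    window: float = 60.0
    indoor_temp: float = 26.0
    outdoor_temp: float = 24.0
    transit_aqi: float = 120.0
    min_status: int = 2

    def __post_init__(self) -> None:
        if not (self.temp_step > 0 and self.aqi_step > 0 and self.window > 0):
            raise ValidationError("steps and window must be > 0")
        if self.indoor_temp <= self.outdoor_temp:
            raise ValidationError("indoor_temp must exceed outdoor_temp")


@dataclass
class ZoneSegment:
    """One labelled stretch of the session; segments tile it without overlap."""

    start_s: float
    end_s: float
    label: str
    mean_outer_temp: float
    mean_aqi: float  # NaN when no reliable AQI in the segment


def segment_zones(
    outer_temp: np.ndarray,
    aqi: np.ndarray,
    aqi_accuracy: np.ndarray,
    sample_rate: float,
    config: ZoneConfig | None = None,
) -> list[ZoneSegment]:
    """Segment a session into urban zones from outer-channel evidence.

    Change-points are baseline shifts of the moving-mean outer temperature
    (>= ``temp_step`` °C within ``window``) and of the reliable AQI trace
    (>= ``aqi_step``).  AQI samples recorded before the calibration gate
    never create boundaries.  Segments tile the session; each is labelled
    from its mean outer temperature and mean reliable AQI.
    """
    cfg = config or ZoneConfig()
    temp = np.asarray(outer_temp, dtype=float)
    aqi = np.asarray(aqi, dtype=float)
    acc = np.asarray(aqi_accuracy)
    if not (temp.size == aqi.size == acc.size):
        raise ValidationError("channels must be time-aligned (equal length)")
    fs = float(sample_rate)
    n = temp.size
    duration = n / fs

    bounds: list[float] = []
    for ev in baseline_shifts(temp, fs, cfg.temp_step, cfg.window):
        bounds.append(ev.time_s)
    reliable = acc >= cfg.min_status
    idx = np.flatnonzero(reliable)
    if idx.size:
        i0 = int(idx[0])
        for ev in baseline_shifts(aqi[i0:], fs, cfg.aqi_step, cfg.window):
            bounds.append(ev.time_s + i0 / fs)

    # merge boundaries closer than one window (a shop door produces both a
    # temperature and an AQI shift; that is one boundary, not two)
    merged: list[float] = []
    for b in sorted(bounds):
        if not merged or b - merged[-1] >= cfg.window:
            merged.append(b)
    edges = [0.0] + [b for b in merged if 0 < b < duration] + [duration]

    segments: list[ZoneSegment] = []
    for a, b in zip(edges[:-1], edges[1:]):
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        seg_temp = float(np.mean(temp[i0:i1]))
        rel = reliable[i0:i1]
        seg_aqi = float(np.mean(aqi[i0:i1][rel])) if rel.any() else float("nan")
        if seg_temp >= cfg.indoor_temp:
            label = "indoor"
        elif not np.isnan(seg_aqi) and seg_aqi >= cfg.transit_aqi:
            label = "transit"
        elif seg_temp <= cfg.outdoor_temp:
            label = "outdoor"
        elif np.isnan(seg_aqi):
            label = "unknown"
        else:
            label = "outdoor"
        segments.append(
            ZoneSegment(
                start_s=a,
                end_s=b,
                label=label,
                mean_outer_temp=seg_temp,
                mean_aqi=seg_aqi,
            )
        )
    return segments


def zones_to_frame(segments: list[ZoneSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
            "label": [s.label for s in segments],
            "mean_outer_temp_c": [s.mean_outer_temp for s in segments],
            "mean_aqi": [s.mean_aqi for s in segments],
        }
    )
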