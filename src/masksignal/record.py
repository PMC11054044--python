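"""The dual-channel session container.

A :class:`DualChannelRecord` holds the synchronized inner (in-mask) and
outer (ambient) sensor series at a fixed sample rate, as two pandas
DataFrames sharing one time base, plus provenance metadata.  It is the
in-memory interchange object between the simulator, the session CSV format
and every analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

INNER_COLUMNS = ("temperature_c", "pressure_pa", "humidity_pct", "gas_ohm")
OUTER_COLUMNS = INNER_COLUMNS + ("aqi", "aqi_accuracy")

#: channel name -> (side, column)
CHANNELS = {
    "inner_temp": ("inner", "temperature_c"),
    "inner_pressure": ("inner", "pressure_pa"),
    "inner_humidity": ("inner", "humidity_pct"),
    "inner_gas": ("inner", "gas_ohm"),
    "outer_temp": ("outer", "temperature_c"),
    "outer_pressure": ("outer", "pressure_pa"),
    "outer_humidity": ("outer", "humidity_pct"),
    "outer_gas": ("outer", "gas_ohm"),
    "outer_aqi": ("outer", "aqi"),
    "outer_aqi_accuracy": ("outer", "aqi_accuracy"),
}


@dataclass
class DualChannelRecord:
    """Synchronized inner + outer sensor series at a fixed rate.

    Attributes
    ----------
    sample_rate : float
        Acquisition rate, Hz.
    time : ndarray
        Seconds from session start, uniform at ``1/sample_rate``.
    inner, outer : DataFrame
        Per-side quantities; the AQI columns exist only on the outer side
        (the index is computed for ambient air only).
    metadata : dict
        Seed, scenario name, sensor spec, scripted segment table, gap flags.
    """

    sample_rate: float
    time: np.ndarray
    inner: pd.DataFrame
    outer: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if len(self.inner) != len(self.outer) or len(self.inner) != self.time.size:
            raise ValidationError("inner, outer and time must have equal length")
        for col in INNER_COLUMNS:
            if col not in self.inner.columns:
                raise ValidationError(f"inner side missing column {col!r}")
        for col in OUTER_COLUMNS:
            if col not in self.outer.columns:
                raise ValidationError(f"outer side missing column {col!r}")
        aqi = self.outer["aqi"].to_numpy(dtype=float)
        if ((aqi < 0) | (aqi > 500)).any():
            raise ValidationError("aqi must lie in [0, 500]")
        acc = self.outer["aqi_accuracy"].to_numpy()
        if not np.isin(acc, (0, 1, 2, 3)).all():
            raise ValidationError("aqi_accuracy must be one of {0,1,2,3}")
        for side in (self.inner, self.outer):
            h = side["humidity_pct"].to_numpy(dtype=float)
            if ((h < 0) | (h > 100)).any():
                raise ValidationError("humidity must lie in [0, 100]")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Session duration in seconds (number of samples / rate)."""
        return self.time.size / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by name, e.g. ``'inner_pressure'``."""
        try:
            side, col = CHANNELS[name]
        except KeyError:
            raise ValidationError(
                f"unknown channel {name!r}; one of {sorted(CHANNELS)}"
            ) from None
        frame = self.inner if side == "inner" else self.outer
        return frame[col].to_numpy(dtype=float)

    def slice(self, start_s: float, end_s: float) -> "DualChannelRecord":
        """Sub-record covering ``[start_s, end_s)`` of session time."""
        i0 = int(np.searchsorted(self.time, start_s, side="left"))
        i1 = int(np.searchsorted(self.time, end_s, side="left"))
        if i1 <= i0:
            raise ValidationError("empty time slice")
        return DualChannelRecord(
            sample_rate=self.sample_rate,
            time=self.time[i0:i1].copy(),
            inner=self.inner.iloc[i0:i1].reset_index(drop=True),
            outer=self.outer.iloc[i0:i1].reset_index(drop=True),
            metadata=dict(self.metadata),
        )

    def equals(self, other: "DualChannelRecord", atol: float = 1e-6) -> bool:
        """Numeric equality within ``atol`` on every shared channel."""
        if len(self) != len(other) or self.sample_rate != other.sample_rate:
            return False
        if not np.allclose(self.time, other.time, atol=atol):
            return False
        for col in INNER_COLUMNS:
            if not np.allclose(self.inner[col], other.inner[col], atol=atol):
                return False
        for col in OUTER_COLUMNS:
            if not np.allclose(
                self.outer[col].astype(float), other.outer[col].astype(float), atol=atol
            ):
                return False
        return True
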