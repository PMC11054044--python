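"""Temperature-pressure source selection for respiration monitoring.

The in-mask temperature channel is the preferred respiration source: its
thermal inertia suppresses flow turbulence and breath stutters.  But it is
useless while the ambient temperature is changing (entering a shop on a
winter day swamps the 0.8 °C breath swing), whereas the pressure channel
does not care about temperature (its temperature coefficient, ±1.3 Pa/K,
is far below the 20-40 Pa breath band).  The switching rule:

* temperature baseline steady (|drift| <= 0.1 °C/min)  ->  TEMPERATURE;
* temperature drifting but pressure baseline steady    ->  PRESSURE;
* both baselines moving (e.g. an ambient step during a continuous stair
  climb)                                               ->  PAUSED: report
  nothing and flag that processing is waiting for a steady state.

The pressure-baseline test runs on the moving mean, so breath dynamics
(~10-50 Pa/s oscillation, zero-mean) never trip it, and its threshold
(30 Pa per 10 s) sits between the breath band and the ~50-60 Pa / 10 s
signature of a storey transition — so a stair climb alone, with steady
temperature, does not interrupt temperature-based monitoring.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dsp import interior_slice, moving_mean, ols_slope
from .errors import ValidationError
from .record import DualChannelRecord
from .respiration import BreathDetector, DetectorConfig

__all__ = [
    "FusionConfig",
    "SourceState",
    "drift_rate",
    "select_source",
    "RespirationFusion",
    "FusionResults",
    "fused_respiration",
]


class SourceState(enum.Enum):
    TEMPERATURE = "TEMPERATURE"
    PRESSURE = "PRESSURE"
    PAUSED = "PAUSED"


@dataclass(frozen=True)
class FusionConfig:
    """Source-selection settings.

    Parameters
    ----------
    temp_drift_threshold : float
        °C/min above which the temperature baseline counts as drifting.
    drift_window : float
        Seconds of signal over which each drift is estimated.
    pressure_baseline_threshold : float
        Pa per 10 s above which the pressure baseline counts as moving.
        Default 30: above breath-band residue, below the ~50-60 Pa/10 s
        storey signature sustained over a full window.
    evaluation_stride : float
        Seconds between source evaluations.
    hysteresis : int
        Number of consecutive evaluations a new state must persist before
        the active source switches (chatter suppression at the threshold).
    """

    temp_drift_threshold: float = 0.1
    drift_window: float = 60.0
    pressure_baseline_threshold: float = 30.0
    evaluation_stride: float = 30.0
    hysteresis: int = 2

    def __post_init__(self) -> None:
        for name in (
            "temp_drift_threshold",
            "drift_window",
            "pressure_baseline_threshold",
            "evaluation_stride",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.hysteresis < 1:
            raise ValidationError("hysteresis must be >= 1")


def drift_rate(
    x: np.ndarray,
    sample_rate: float,
    window: float | None = None,
    smooth: float = 5.0,
) -> float:
    """Baseline drift of ``x``: slope of its moving mean, per minute.

    The series is smoothed with a centred moving mean of ``smooth`` seconds
    (removing the breath band), edge-shrunk samples are excluded, and an
    ordinary-least-squares slope is fitted over the trailing ``window``
    seconds (whole series when None).  The sign is preserved; threshold
    comparisons use the absolute value.
    """
    x = np.asarray(x, dtype=float)
    fs = float(sample_rate)
    if window is not None:
        wn = int(round(window * fs))
        if wn > x.size:
            raise ValidationError(
                f"drift window ({window} s) longer than series ({x.size / fs:.1f} s)"
            )
        x = x[-wn:]
    sm = max(2, int(round(smooth * fs)))
    if sm > x.size:
        raise ValidationError("smoothing window longer than series")
    mm = moving_mean(x, sm)[interior_slice(x.size, sm)]
    if mm.size < 2:
        raise ValidationError("series too short for drift estimation")
    return ols_slope(mm, 1.0 / fs) * 60.0


def select_source(
    temp_drift: float, pressure_drift: float, config: FusionConfig | None = None
) -> SourceState:
    """Apply the switching rule to a (temperature, pressure) drift pair.

    ``temp_drift`` in °C/min, ``pressure_drift`` in Pa per 10 s; absolute
    values are compared against the configured thresholds.  Total function:
    every finite input pair maps to a state.
    """
    cfg = config or FusionConfig()
    if not (np.isfinite(temp_drift) and np.isfinite(pressure_drift)):
        raise ValidationError("drift values must be finite")
    temp_steady = abs(temp_drift) <= cfg.temp_drift_threshold
    pressure_steady = abs(pressure_drift) <= cfg.pressure_baseline_threshold
    if temp_steady:
        return SourceState.TEMPERATURE
    if pressure_steady:
        return SourceState.PRESSURE
    return SourceState.PAUSED


@dataclass
class FusionResults:
    """Per-window source decisions and fused respiration rates.

    ``windows`` is a DataFrame with one row per evaluation window:
    ``start_s, end_s, temp_drift, pressure_drift, raw_source,
    active_source, rate, waiting``.  ``raw_source`` is the instantaneous
    rule decision; ``active_source`` applies the hysteresis.  PAUSED
    windows have ``rate`` NaN and ``waiting`` True.
    """

    windows: pd.DataFrame
    config: FusionConfig
    detector_config: DetectorConfig

    @property
    def rates(self) -> pd.Series:
        return self.windows["rate"]

    @property
    def fused_rate(self) -> float:
        """Mean rate over non-paused windows (NaN if all paused)."""
        r = self.windows["rate"].dropna()
        return float(r.mean()) if len(r) else float("nan")

    def summary(self) -> str:
        counts = self.windows["active_source"].value_counts().to_dict()
        lines = [
            "Fused respiration (temperature/pressure switching)",
            f"  evaluation windows: {len(self.windows)}",
            f"  source usage:       "
            + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
            f"  fused rate:         {self.fused_rate:.2f} breaths/min",
            f"  paused windows:     {int(self.windows['waiting'].sum())}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        w = self.windows
        colors = {"TEMPERATURE": "tab:blue", "PRESSURE": "tab:orange", "PAUSED": "tab:red"}
        for src, grp in w.groupby("active_source"):
            ax.plot(
                grp["start_s"], grp["rate"], "o", color=colors.get(src, "k"), label=src
            )
        ax.set_xlabel("window start [s]")
        ax.set_ylabel("rate [breaths/min]")
        ax.legend(loc="best", fontsize="small")
        return ax


class RespirationFusion:
    """Windowed source selection + breath detection over a dual-channel record."""

    def __init__(
        self,
        record: DualChannelRecord,
        config: FusionConfig | None = None,
        detector_config: DetectorConfig | None = None,
    ) -> None:
        self.record = record
        self.config = config or FusionConfig()
        self.detector_config = detector_config or DetectorConfig()

    def fit(self) -> FusionResults:
        rec = self.record
        cfg = self.config
        fs = rec.sample_rate
        win = cfg.drift_window
        if rec.duration < win:
            raise ValidationError(
                f"record ({rec.duration:.0f} s) shorter than one evaluation "
                f"window ({win:.0f} s)"
            )
        temp = rec.channel("inner_temp")
        pres = rec.channel("inner_pressure")
        wn = int(round(win * fs))
        stride_n = int(round(cfg.evaluation_stride * fs))
        starts = list(range(0, temp.size - wn + 1, stride_n))

        rows = []
        active: SourceState | None = None
        pending: SourceState | None = None
        pending_count = 0
        for i0 in starts:
            sl = slice(i0, i0 + wn)
            td = drift_rate(temp[sl], fs)
            pd_rate = drift_rate(pres[sl], fs) / 6.0  # per min -> per 10 s
            raw = select_source(td, pd_rate, cfg)
            if active is None:
                active = raw
                pending, pending_count = None, 0
            elif raw != active:
                if raw == pending:
                    pending_count += 1
                else:
                    pending, pending_count = raw, 1
                if pending_count >= cfg.hysteresis:
                    active = raw
                    pending, pending_count = None, 0
            else:
                pending, pending_count = None, 0

            if active == SourceState.PAUSED:
                rate = float("nan")
            else:
                channel = temp if active == SourceState.TEMPERATURE else pres
                det = BreathDetector(
                    channel[sl], fs, config=self.detector_config, source=active.value
                ).fit()
                rate = det.rate
            rows.append(
                dict(
                    start_s=i0 / fs,
                    end_s=(i0 + wn) / fs,
                    temp_drift=td,
                    pressure_drift=pd_rate,
                    raw_source=raw.value,
                    active_source=active.value,
                    rate=rate,
                    waiting=active == SourceState.PAUSED,
                )
            )
        return FusionResults(
            windows=pd.DataFrame(rows),
            config=cfg,
            detector_config=self.detector_config,
        )


def fused_respiration(
    record: DualChannelRecord,
    config: FusionConfig | None = None,
    detector_config: DetectorConfig | None = None,
) -> FusionResults:
    """Functional entry point over :class:`RespirationFusion`."""
    return RespirationFusion(record, config, detector_config).fit()
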