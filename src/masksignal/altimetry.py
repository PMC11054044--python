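"""Barometric altimetry: relative height and floor-change detection.

The ambient-side pressure channel resolves the ~55-60 Pa drop of one
storey (4.5-5 m).  Absolute altitude is out of reach — the embedded sensor
carries an uncalibrated offset — so everything here is *relative*: height
differences via the linearized hypsometric relation

    Δh = (p_ref - p) / (ρ g),   ρ = p_mid / (R_d T),

with p_mid the mean of the two pressures.  Over building scales the linear
form agrees with the log-form barometric formula to better than 0.1%.

``FloorDetector(...).fit()`` finds storey transitions as shifts of the
moving-mean pressure baseline: the breath band (zero-mean oscillation) is
averaged away, so a 40 Pa peak-to-peak breath swing never fakes a floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dsp import baseline_shifts
from .errors import RangeError, ValidationError
from .sensors import PRESSURE_RANGE_PA

__all__ = [
    "AtmosphereModel",
    "pressure_to_height",
    "FloorDetector",
    "FloorEvents",
    "detect_floor_changes",
]


@dataclass(frozen=True)
class AtmosphereModel:
    """Constants for the hypsometric conversion.

    Reference temperature defaults to the standard atmosphere (288.15 K),
    not the in-mask temperature: the ambient-facing sensor drives
    altimetry.  ``reference_pressure`` is the calibration anchor where
    relative height is zero (sea-level standard by default; field use
    calibrates it to a known floor).
    """

    reference_pressure: float = 101_325.0
    reference_temperature: float = 288.15
    gas_constant_dry_air: float = 287.05
    gravity: float = 9.80665

    def __post_init__(self) -> None:
        for name in (
            "reference_pressure",
            "reference_temperature",
            "gas_constant_dry_air",
            "gravity",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not PRESSURE_RANGE_PA[0] <= self.reference_pressure <= PRESSURE_RANGE_PA[1]:
            raise RangeError(
                f"reference pressure {self.reference_pressure} Pa outside "
                f"sensor range {PRESSURE_RANGE_PA}"
            )

    def density(self, pressure: float) -> float:
        """Dry-air density at ``pressure`` and the reference temperature, kg/m³."""
        return pressure / (self.gas_constant_dry_air * self.reference_temperature)


def pressure_to_height(
    p: float | np.ndarray,
    atm: AtmosphereModel | None = None,
    reference_pressure: float | None = None,
) -> float | np.ndarray:
    """Height of pressure ``p`` relative to the reference, metres.

    Linearized hypsometric form: ``Δh = (p_ref - p) / (ρ g)`` with the
    density evaluated at the mid-pressure.  Lower pressure reads as higher
    altitude; ``p == p_ref`` maps to exactly 0.

    Raises :class:`RangeError` for pressures outside the sensor's
    300-1100 hPa operating range.
    """
    atm = atm or AtmosphereModel()
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < PRESSURE_RANGE_PA[0]) | (p_arr > PRESSURE_RANGE_PA[1])).any():
        raise RangeError(f"pressure outside sensor range {PRESSURE_RANGE_PA}")
    p_ref = atm.reference_pressure if reference_pressure is None else reference_pressure
    p_mid = 0.5 * (p_arr + p_ref)
    rho = atm.density(p_mid)
    out = (p_ref - p_arr) / (rho * atm.gravity)
    return float(out) if np.isscalar(p) else out


@dataclass
class FloorEvents:
    """Detected storey transitions.

    ``events``: DataFrame with ``time_s, delta_pa, delta_height_m``; one
    row per transition, positive height = ascent.  ``total_height`` sums
    the signed transitions.
    """

    events: pd.DataFrame
    total_height: float
    calibration_offset: float
    atmosphere: AtmosphereModel

    @property
    def n_events(self) -> int:
        return len(self.events)

    def summary(self) -> str:
        lines = [
            "Floor-change detection (baseline pressure shifts)",
            f"  events:        {self.n_events}",
            f"  total Δheight: {self.total_height:+.2f} m",
        ]
        for _, row in self.events.iterrows():
            lines.append(
                f"    t={row.time_s:8.1f} s  Δp={row.delta_pa:+7.1f} Pa  "
                f"Δh={row.delta_height_m:+.2f} m"
            )
        return "\n".join(lines)


class FloorDetector:
    """Detect storey transitions on a uniformly sampled pressure series.

    Parameters
    ----------
    pressure : ndarray
        Pressure series, Pa (typically the ambient-facing channel).
    sample_rate : float
        Hz.
    atm : AtmosphereModel, optional
    step_threshold : float
        Minimum baseline shift, Pa, to count a transition.  Default 40:
        above breath-band residue, below the ~55-60 Pa one-floor drop.
    window : float
        Baseline comparison window, s (default 10, the duration of one
        floor's pressure ramp).
    """

    def __init__(
        self,
        pressure: np.ndarray,
        sample_rate: float,
        atm: AtmosphereModel | None = None,
        step_threshold: float = 40.0,
        window: float = 10.0,
    ) -> None:
        self.pressure = np.asarray(pressure, dtype=float)
        if not sample_rate > 0:
            raise ValidationError("sample_rate must be > 0")
        if not step_threshold > 0 or not window > 0:
            raise ValidationError("step_threshold and window must be > 0")
        self.sample_rate = float(sample_rate)
        self.atm = atm or AtmosphereModel()
        self.step_threshold = step_threshold
        self.window = window

    def fit(self) -> FloorEvents:
        p = self.pressure
        shifts = baseline_shifts(
            p, self.sample_rate, self.step_threshold, self.window
        )
        rows = []
        for ev in shifts:
            dp = ev.delta  # baseline change over the window: p_after - p_before
            # convert the local pressure step to a height step; the session
            # mean anchors the density (the absolute offset cancels)
            p_after = float(np.mean(p)) + dp / 2.0
            p_before = p_after - dp
            dh = pressure_to_height(p_after, self.atm, reference_pressure=p_before)
            rows.append(dict(time_s=ev.time_s, delta_pa=dp, delta_height_m=dh))
        events = pd.DataFrame(rows, columns=["time_s", "delta_pa", "delta_height_m"])
        total = float(events["delta_height_m"].sum()) if len(events) else 0.0
        offset = float(np.mean(p)) - self.atm.reference_pressure
        return FloorEvents(
            events=events,
            total_height=total,
            calibration_offset=offset,
            atmosphere=self.atm,
        )


def detect_floor_changes(
    pressure: np.ndarray,
    sample_rate: float,
    step_threshold: float = 40.0,
    window: float = 10.0,
    atm: AtmosphereModel | None = None,
) -> FloorEvents:
    """Functional entry point over :class:`FloorDetector`."""
    return FloorDetector(
        pressure, sample_rate, atm=atm, step_threshold=step_threshold, window=window
    ).fit()
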