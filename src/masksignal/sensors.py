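"""Sensor characteristics of the environmental sensing element.

The monitor carries two identical environmental sensor clusters (one facing
the wearer's airspace under the mask, one facing the ambient), each
measuring temperature, pressure, relative humidity and gas resistance.
:class:`SensorSpec` captures the datasheet figures the simulator and the
detectors need: output resolutions (quantization steps), accuracy bounds,
and the pressure channel's temperature coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ValidationError

#: Operating pressure range of the barometric element, Pa (300-1100 hPa).
PRESSURE_RANGE_PA = (30_000.0, 110_000.0)


@dataclass(frozen=True)
class SensorSpec:
    """Datasheet characteristics of one environmental sensor cluster.

    Parameters
    ----------
    temp_resolution : float
        Output resolution of the temperature channel, °C.
    temp_abs_accuracy : float
        Absolute temperature accuracy bound at ambient conditions, °C.
    pressure_resolution : float
        Output resolution of the barometric channel, Pa.
    pressure_rel_accuracy : float
        Relative pressure accuracy bound, Pa.
    humidity_resolution : float
        Output resolution of the humidity channel, %rh.
    humidity_abs_accuracy : float
        Absolute humidity accuracy bound, %rh.
    pressure_temp_coeff : float
        Temperature coefficient offset of the pressure channel, Pa/K.
    """

    temp_resolution: float = 0.01
    temp_abs_accuracy: float = 0.5
    pressure_resolution: float = 0.18
    pressure_rel_accuracy: float = 12.0
    humidity_resolution: float = 0.008
    humidity_abs_accuracy: float = 3.0
    pressure_temp_coeff: float = 1.3

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValidationError(f"SensorSpec.{f.name} must be > 0, got {v!r}")

    def resolution_for(self, quantity: str) -> float:
        """Quantization step for ``quantity`` in {'temperature', 'pressure', 'humidity'}."""
        try:
            return {
                "temperature": self.temp_resolution,
                "pressure": self.pressure_resolution,
                "humidity": self.humidity_resolution,
            }[quantity]
        except KeyError:  # pragma: no cover - defensive
            raise ValidationError(f"unknown quantity {quantity!r}") from None
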