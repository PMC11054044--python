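"""Duty-cycle power budget and battery endurance.

Each component of the monitor draws its current for a fraction
(``time_ratio``) of every 1-second operating cycle; the cycle-averaged
current is the duty-weighted sum Σ time_ratio × current, and battery
endurance is simply capacity / average current.  The default budget
(``data/consumption.yaml``) describes the as-built electronics — two
environmental sensors sampled continuously, a BLE microcontroller mostly
in deep sleep with sub-millisecond radio and bus bursts — and averages
~1.87 mA, so a 180 mAh single cell lasts a working week (> 96 h).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError

__all__ = [
    "PowerBudgetEntry",
    "PowerBudget",
    "average_current",
    "battery_life",
]


@dataclass(frozen=True)
class PowerBudgetEntry:
    """One component's duty-cycled draw.

    ``time_ratio`` is the dimensionless fraction of a 1-s cycle the
    component is on; ``current_ma`` its draw while on, mA.
    """

    component: str
    time_ratio: float
    current_ma: float

    def __post_init__(self) -> None:
        if not 0 <= self.time_ratio <= 1:
            raise ValidationError(
                f"{self.component}: time_ratio must lie in [0, 1], "
                f"got {self.time_ratio}"
            )
        if self.current_ma < 0:
            raise ValidationError(f"{self.component}: current must be >= 0")

    @property
    def consumption_masec(self) -> float:
        """Charge drawn per cycle, mA·s (time_ratio × current)."""
        return self.time_ratio * self.current_ma


def average_current(entries: list[PowerBudgetEntry]) -> float:
    """Cycle-averaged current, mA: Σ time_ratio × current."""
    return float(sum(e.consumption_masec for e in entries))


def battery_life(capacity_mah: float, avg_current_ma: float) -> float:
    """Battery endurance in hours: capacity / average current."""
    if capacity_mah < 0:
        raise ValidationError("capacity must be >= 0")
    if not avg_current_ma > 0:
        raise ValidationError("average current must be > 0")
    return capacity_mah / avg_current_ma


@dataclass
class PowerBudget:
    """A full budget: entries plus the battery it runs from."""

    entries: list[PowerBudgetEntry]
    battery_capacity_mah: float = 180.0

    @property
    def average_current_ma(self) -> float:
        return average_current(self.entries)

    @property
    def endurance_h(self) -> float:
        return battery_life(self.battery_capacity_mah, self.average_current_ma)

    @classmethod
    def default(cls) -> "PowerBudget":
        """The packaged as-built consumption budget."""
        with resources.files("masksignal.data").joinpath("consumption.yaml").open() as f:
            return cls._from_dict(yaml.safe_load(f))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PowerBudget":
        return cls._from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def _from_dict(cls, d: dict) -> "PowerBudget":
        if not isinstance(d, dict) or "components" not in d:
            raise ValidationError("budget file needs a 'components' list")
        entries = [
            PowerBudgetEntry(
                component=str(c["component"]),
                time_ratio=float(c["time_ratio"]),
                current_ma=float(c["current_ma"]),
            )
            for c in d["components"]
        ]
        return cls(
            entries=entries,
            battery_capacity_mah=float(d.get("battery_capacity_mah", 180.0)),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "component": [e.component for e in self.entries],
                "time_ratio": [e.time_ratio for e in self.entries],
                "current_ma": [e.current_ma for e in self.entries],
                "consumption_masec": [e.consumption_masec for e in self.entries],
            }
        )
        return df

    def summary(self) -> str:
        lines = ["Duty-cycle power budget"]
        for e in self.entries:
            lines.append(
                f"  {e.component:<34} ratio {e.time_ratio:<10.4g} "
                f"{e.current_ma:>8.4g} mA  -> {e.consumption_masec:.4g} mA·s"
            )
        lines.append(f"  average current: {self.average_current_ma:.4f} mA")
        lines.append(
            f"  battery {self.battery_capacity_mah:g} mAh -> "
            f"endurance {self.endurance_h:.1f} h"
        )
        return "\n".join(lines)
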