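"""Particle filtration efficiency per size bin.

A laser particle counter reports Particle Number Concentrations (PNC,
particles/m³) in six optical size bins (0.3-0.5, 0.5-1, 1-5, 5-10, 10-25,
>25 µm).  Filtration efficiency of a mask is the fractional reduction of
PNC behind the mask relative to ambient, per bin:

    PFE = (PNC_A - PNC_C) / PNC_A × 100  [%]

with PNC_A the ambient and PNC_C the behind-mask concentration.  PFE is
scale-invariant in the counts (the ambient concentration level does not
matter) and never exceeds 100%.  Negative values — behind-mask counts
above ambient — are retained with a warning flag rather than clamped:
a prepared mask occasionally out-measuring its reference is measurement
information, not an error.  Bins whose expected ambient *count* (PNC ×
sampled volume) falls below 10 are flagged low-count, where Poisson
counting error dominates the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SizeBin",
    "LASAIR_BINS",
    "ParticleCountSet",
    "PFEResult",
    "pfe",
    "compare_pfe",
]

#: default counter volume flow, m³/s (30 l/min, average calm breathing)
_FLOW_M3_PER_S = 30.0e-3 / 60.0

_LOW_COUNT = 10.0


@dataclass(frozen=True)
class SizeBin:
    """One optical size bin, µm; ``high_um`` may be ``inf`` for the top bin."""

    low_um: float
    high_um: float

    def __post_init__(self) -> None:
        if not (self.low_um >= 0 and self.high_um > self.low_um):
            raise ValidationError(f"invalid size bin [{self.low_um}, {self.high_um})")

    def __str__(self) -> str:
        if np.isinf(self.high_um):
            return f">{self.low_um:g} µm"
        return f"{self.low_um:g}-{self.high_um:g} µm"


#: the six bins of the Lasair III 310C counter
LASAIR_BINS: tuple[SizeBin, ...] = (
    SizeBin(0.3, 0.5),
    SizeBin(0.5, 1.0),
    SizeBin(1.0, 5.0),
    SizeBin(5.0, 10.0),
    SizeBin(10.0, 25.0),
    SizeBin(25.0, float("inf")),
)


@dataclass
class ParticleCountSet:
    """Per-bin particle number concentrations for one measurement.

    Parameters
    ----------
    pnc : array
        Particles/m³ per bin, >= 0.
    role : str
        'ambient' or 'behind_mask'.
    bins : tuple of SizeBin
        Defaults to the six counter bins.
    duration : float
        Sampling duration, s (each measurement step runs 1 min).
    """

    pnc: np.ndarray
    role: str
    bins: tuple[SizeBin, ...] = LASAIR_BINS
    duration: float = 60.0

    def __post_init__(self) -> None:
        self.pnc = np.asarray(self.pnc, dtype=float)
        if self.role not in ("ambient", "behind_mask"):
            raise ValidationError("role must be 'ambient' or 'behind_mask'")
        if self.pnc.size != len(self.bins):
            raise ValidationError(
                f"{self.pnc.size} concentrations for {len(self.bins)} bins"
            )
        if (self.pnc < 0).any():
            raise ValidationError("particle concentrations must be >= 0")
        if not self.duration > 0:
            raise ValidationError("duration must be > 0")

    @classmethod
    def from_csv(cls, path: str | Path, role: str | None = None) -> "ParticleCountSet":
        """Read a bin table: columns bin_low_um, bin_high_um, pnc_per_m3, role."""
        df = pd.read_csv(path)
        need = {"bin_low_um", "bin_high_um", "pnc_per_m3"}
        if not need <= set(df.columns):
            raise ValidationError(f"{path}: needs columns {sorted(need)}")
        if role is None:
            if "role" not in df.columns or df["role"].nunique() != 1:
                raise ValidationError(f"{path}: ambiguous role; pass role=")
            role = str(df["role"].iloc[0])
        bins = tuple(
            SizeBin(float(l), float(h))
            for l, h in zip(df["bin_low_um"], df["bin_high_um"])
        )
        return cls(pnc=df["pnc_per_m3"].to_numpy(float), role=role, bins=bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_um": [b.low_um for b in self.bins],
                "bin_high_um": [b.high_um for b in self.bins],
                "pnc_per_m3": self.pnc,
                "role": self.role,
            }
        )

    @property
    def sampled_volume_m3(self) -> float:
        return _FLOW_M3_PER_S * self.duration


@dataclass
class PFEResult:
    """Per-bin filtration efficiencies with validity flags.

    ``efficiency_pct`` is NaN where the ambient bin is empty (flagged
    ``invalid``); negative efficiencies are kept and flagged ``negative``;
    ``low_count`` marks bins with fewer than ~10 expected ambient counts.
    """

    bins: tuple[SizeBin, ...]
    efficiency_pct: np.ndarray
    invalid: np.ndarray
    negative: np.ndarray
    low_count: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": [str(b) for b in self.bins],
                "pfe_pct": self.efficiency_pct,
                "invalid": self.invalid,
                "negative": self.negative,
                "low_count": self.low_count,
            }
        )

    @property
    def flagged(self) -> np.ndarray:
        """Any-flag mask per bin."""
        return self.invalid | self.negative | self.low_count

    def summary(self) -> str:
        lines = ["Particle filtration efficiency per size bin"]
        for b, e, inv, neg, low in zip(
            self.bins, self.efficiency_pct, self.invalid, self.negative, self.low_count
        ):
            flags = ",".join(
                f
                for f, on in (("invalid", inv), ("negative", neg), ("low-count", low))
                if on
            )
            val = "   n/a" if np.isnan(e) else f"{e:6.1f}%"
            lines.append(f"  {str(b):>12}: {val}" + (f"  [{flags}]" if flags else ""))
        return "\n".join(lines)


def _check_bins(a: ParticleCountSet | PFEResult, b: ParticleCountSet | PFEResult) -> None:
    if tuple(a.bins) != tuple(b.bins):
        raise ValidationError("bin definitions do not match")


def pfe(ambient: ParticleCountSet, behind: ParticleCountSet) -> PFEResult:
    """Filtration efficiency per bin from an ambient / behind-mask pair."""
    _check_bins(ambient, behind)
    if ambient.role != "ambient" or behind.role != "behind_mask":
        raise ValidationError(
            f"expected roles ambient/behind_mask, got {ambient.role}/{behind.role}"
        )
    a = ambient.pnc
    c = behind.pnc
    invalid = a == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(invalid, np.nan, (a - c) / np.where(invalid, 1.0, a) * 100.0)
    negative = ~invalid & (c > a)
    low_count = a * ambient.sampled_volume_m3 < _LOW_COUNT
    return PFEResult(
        bins=tuple(ambient.bins),
        efficiency_pct=eff,
        invalid=invalid,
        negative=negative,
        low_count=low_count,
    )


def compare_pfe(reference: PFEResult, prepared: PFEResult) -> pd.DataFrame:
    """Per-bin efficiency difference (prepared - reference), flags propagated.

    A positive difference means the prepared (electronics-embedded) mask
    filtered better than the unmodified reference in that bin.
    """
    _check_bins(reference, prepared)
    diff = prepared.efficiency_pct - reference.efficiency_pct
    flagged = reference.flagged | prepared.flagged
    return pd.DataFrame(
        {
            "bin": [str(b) for b in reference.bins],
            "reference_pct": reference.efficiency_pct,
            "prepared_pct": prepared.efficiency_pct,
            "difference_pct": diff,
            "flagged": flagged,
        }
    )
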