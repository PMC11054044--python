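"""End-to-end pipeline: simulate -> respiration/fusion -> altimetry -> zones
-> AQI/humidity report (-> PFE when particle tables are given).

The pipeline is deterministic under a fixed seed and writes both a
machine-readable JSON report and the session CSV, so each stage remains
independently re-runnable with files as the only interface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .airquality import (
    classify_aqi,
    gate_by_accuracy,
    humidity_validity,
    segment_zones,
    zones_to_frame,
)
from .altimetry import FloorDetector
from .errors import ValidationError
from .filtration import ParticleCountSet, pfe
from .fusion import RespirationFusion
from .power import PowerBudget
from .scenario import BreathingModel, ScenarioScript, winter_walk
from .sessionio import write_session
from .simulate import simulate_session

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "scenario",
    "seed",
    "out_dir",
    "ambient_csv",
    "behind_csv",
    "budget_yaml",
    "log_level",
}


@dataclass
class RunConfig:
    """Pipeline run settings.

    ``scenario`` is a scenario YAML path or the literal ``"demo"`` for the
    built-in winter walk.  Optional particle-count CSVs switch on the PFE
    section; ``budget_yaml`` overrides the packaged consumption budget.
    """

    scenario: str = "demo"
    seed: int = 0
    out_dir: str | Path = "masksignal-out"
    ambient_csv: str | None = None
    behind_csv: str | None = None
    budget_yaml: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on one simulated session and return the report.

    The report dict carries five sections — ``respiration`` (fused rate
    trace), ``floors``, ``zones``, ``airquality`` (reliability and
    humidity validity) and ``power`` — plus ``filtration`` when particle
    tables were supplied.  It is also written to ``report.json`` in the
    output directory together with the session CSV and per-stage tables.
    """
    logging.basicConfig(level=config.log_level.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.scenario == "demo":
        script, breathing = winter_walk(stutter_prob=0.1)
    else:
        script = ScenarioScript.from_yaml(config.scenario)
        breathing = BreathingModel()
    log.info("simulating scenario %r, seed %d", script.name, config.seed)
    record = simulate_session(script, breathing, seed=config.seed)
    write_session(record, out / "session.csv")

    report: dict = {
        "masksignal_version": __version__,
        "scenario": script.name,
        "seed": config.seed,
        "duration_s": record.duration,
    }

    fusion = RespirationFusion(record).fit()
    report["respiration"] = {
        "fused_rate_bpm": fusion.fused_rate,
        "true_rate_bpm": breathing.rate,
        "windows": fusion.windows.to_dict(orient="records"),
    }
    fusion.windows.to_csv(out / "rates.csv", index=False)

    floors = FloorDetector(record.channel("outer_pressure"), record.sample_rate).fit()
    report["floors"] = {
        "n_events": floors.n_events,
        "total_height_m": floors.total_height,
        "events": floors.events.to_dict(orient="records"),
    }
    floors.events.to_csv(out / "floors.csv", index=False)

    zones = segment_zones(
        record.channel("outer_temp"),
        record.channel("outer_aqi"),
        record.channel("outer_aqi_accuracy"),
        record.sample_rate,
    )
    zdf = zones_to_frame(zones)
    report["zones"] = zdf.to_dict(orient="records")
    zdf.to_csv(out / "zones.csv", index=False)

    gate = gate_by_accuracy(
        record.channel("outer_aqi"),
        record.channel("outer_aqi_accuracy"),
        record.time,
    )
    hum = humidity_validity(record.channel("inner_humidity"), record.sample_rate)
    reliable_aqi = record.channel("outer_aqi")[gate.reliable]
    report["airquality"] = {
        "time_to_reliability_s": gate.time_to_reliability,
        "reliable_fraction": gate.n_reliable / len(record),
        "mean_reliable_aqi": float(reliable_aqi.mean()) if reliable_aqi.size else None,
        "aqi_class_at_end": classify_aqi(float(record.channel("outer_aqi")[-1])),
        "inner_humidity_saturated": hum.saturated,
        "inner_humidity_valid_until_s": hum.valid_until,
    }

    budget = (
        PowerBudget.from_yaml(config.budget_yaml)
        if config.budget_yaml
        else PowerBudget.default()
    )
    report["power"] = {
        "average_current_ma": budget.average_current_ma,
        "battery_capacity_mah": budget.battery_capacity_mah,
        "endurance_h": budget.endurance_h,
    }

    if config.ambient_csv and config.behind_csv:
        ambient = ParticleCountSet.from_csv(config.ambient_csv, role="ambient")
        behind = ParticleCountSet.from_csv(config.behind_csv, role="behind_mask")
        result = pfe(ambient, behind)
        report["filtration"] = result.to_frame().to_dict(orient="records")
        result.to_frame().to_csv(out / "pfe.csv", index=False)
    elif config.ambient_csv or config.behind_csv:
        raise ValidationError(
            "filtration stage needs both ambient_csv and behind_csv"
        )

    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default, allow_nan=True)
    )
    log.info("report written to %s", out / "report.json")
    return report
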