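"""Scenario-scripted simulator for dual-channel mask-sensor sessions.

The simulator emulates the signal structure a mask-embedded dual sensor
records during wear, so every analysis stage downstream can be exercised
and validated without field recordings:

* breath oscillations at the scripted rate — 20-40 Pa peak-to-peak on the
  in-mask pressure channel, < 10 Pa outside, <= 1 °C on in-mask
  temperature with a ~3 s thermal delay behind pressure;
* a mask microclimate whose baseline temperature mixes ambient air with
  exhaled air (~34 °C), so streets at 0 °C read ~23 °C and indoor stays
  near 30 °C;
* in-mask humidity rising exponentially to saturation within 20-30 min;
* stair segments ramping the barometric baseline by ~55-60 Pa per storey
  over ~10 s each, with flat landings between floors;
* gas-resistance breath oscillation (~Δ3 kΩ inner, ~Δ10 kΩ outer) and an
  outer-side AQI following scripted zone levels with a bounded random
  fluctuation, gated by a calibration status that reaches "calibrated"
  only after a configurable settling time (> 30 min by default);
* datasheet quantization on every channel, plus a per-session accuracy
  bias and small per-sample noise, both truncated at the accuracy bound.

Determinism contract: identical (script, breathing model, sensor spec,
seed) produce bit-identical records.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .record import DualChannelRecord
from .scenario import BreathingModel, ScenarioScript
from .sensors import SensorSpec

__all__ = ["simulate_session", "saturation_profile"]

# Mixing fraction of ambient air in the microclimate each sensor sees.
# The in-mask side is dominated by exhaled air; the outward side, mounted
# on the mask surface, is still device/exhale-heated but closer to ambient.
_INNER_AMBIENT_MIX = 1.0 / 3.0
_OUTER_AMBIENT_MIX = 0.40

_THERMAL_TAU_S = 30.0  # baseline settling after an ambient step
_AQI_TAU_S = 60.0  # AQI target approach
_GAS_INNER_BASE, _GAS_INNER_AMP = 50_000.0, 1_500.0
_GAS_OUTER_BASE, _GAS_OUTER_AMP = 100_000.0, 5_000.0

_STUTTER_DEPTH = 1.3  # in units of breath amplitude
_STUTTER_WIDTH = 0.08  # gaussian sigma, in breath-phase units


def saturation_profile(
    t: np.ndarray | float,
    time_constant: float = 500.0,
    start: float = 40.0,
    ceiling: float = 100.0,
) -> np.ndarray | float:
    """In-mask relative humidity at time ``t`` seconds into wear.

    Exponential approach from ``start`` toward ``ceiling``:
    ``rh(t) = ceiling - (ceiling - start) * exp(-t / time_constant)``.
    Monotone non-decreasing and bounded by ``ceiling`` (<= 100 %rh).  With
    the defaults the profile crosses 95 %rh at ~21 min, inside the
    20-30 min saturation window observed in wear trials.
    """
    arr = np.asarray(t, dtype=float)
    if (arr < 0).any():
        raise ValidationError("time must be >= 0")
    if not time_constant > 0:
        raise ValidationError("time_constant must be > 0")
    out = ceiling - (ceiling - start) * np.exp(-arr / time_constant)
    return float(out) if np.isscalar(t) else out


def _first_order(target: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """First-order (exponential) tracking of a piecewise target."""
    alpha = dt / (tau + dt)
    out = np.empty_like(target)
    y = target[0]
    for i, g in enumerate(target):
        y += alpha * (g - y)
        out[i] = y
    return out


def _breath_wave(phase: np.ndarray, waveform: str) -> np.ndarray:
    frac = np.mod(phase, 1.0)
    if waveform == "asymmetric":
        # faster exhale: compress the second (falling) half of the cycle
        g = np.where(frac < 0.6, frac * (0.5 / 0.6), 0.5 + (frac - 0.6) * (0.5 / 0.4))
        frac = g
    return np.sin(2.0 * np.pi * frac)


def _quantize(x: np.ndarray, resolution: float) -> np.ndarray:
    return np.round(x / resolution) * resolution


def _noisy(
    rng: np.random.Generator,
    x: np.ndarray,
    resolution: float,
    accuracy: float,
    noise_scale: float,
    taper: np.ndarray | None = None,
) -> np.ndarray:
    """Session bias + per-sample noise, both truncated at the accuracy bound.

    ``taper`` (0..1 per sample) scales the error locally; the humidity
    channel uses it to pin the error to zero near condensation, where the
    sensing element saturates regardless of its mid-range accuracy.
    """
    if noise_scale > 0:
        bias = float(
            np.clip(rng.normal(0.0, noise_scale * accuracy / 3.0), -accuracy, accuracy)
        )
        white = np.clip(
            rng.normal(0.0, noise_scale * resolution, x.size),
            -accuracy,
            accuracy,
        )
        err = bias + white
        if taper is not None:
            err = err * taper
        x = x + err
    return _quantize(x, resolution)


def _segment_spans(script: ScenarioScript) -> list[tuple[int, int]]:
    fs = script.sample_rate
    spans = []
    start = 0
    for seg in script.segments:
        n = int(round(seg.duration * fs))
        if n < 1:
            raise ValidationError(f"segment {seg.label!r} shorter than one sample")
        spans.append((start, start + n))
        start += n
    return spans


def _stair_baseline(
    start_pa: float, n: int, fs: float, floors: int, script: ScenarioScript
) -> np.ndarray:
    """Baseline pressure through a stair segment: ramp + landing per floor."""
    per_floor = -np.sign(floors) * script.per_floor_pa  # ascending -> pressure drops
    nfloors = abs(int(floors))
    ramp_n = max(1, int(round(script.stair_ramp_s * fs)))
    land_n = int(round(script.stair_landing_s * fs))
    need = nfloors * (ramp_n + land_n)
    if need > n and nfloors:
        scale = n / need
        ramp_n = max(1, int(ramp_n * scale))
        land_n = int(land_n * scale)
    out = np.empty(n)
    level = start_pa
    i = 0
    for _ in range(nfloors):
        r = min(ramp_n, n - i)
        if r > 0:
            out[i : i + r] = level + per_floor * (np.arange(1, r + 1) / ramp_n)
            i += r
        level += per_floor
        l = min(land_n, n - i)
        if l > 0:
            out[i : i + l] = level
            i += l
    if i < n:
        out[i:] = level
    return out


def simulate_session(
    script: ScenarioScript,
    breathing: BreathingModel | None = None,
    spec: SensorSpec | None = None,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> DualChannelRecord:
    """Simulate one dual-channel sensor session.

    Parameters
    ----------
    script : ScenarioScript
        Non-empty ordered scenario (segments, sample rate, session knobs).
    breathing : BreathingModel, optional
        Wearer respiration; defaults describe quiet activity at 12/min.
    spec : SensorSpec, optional
        Sensor resolutions/accuracies; defaults are the datasheet values.
    seed : int
        Seed for every random draw (bias, noise, stutters, AQI walk).
    noise_scale : float
        0 disables the accuracy bias and per-sample noise (quantization
        still applies); 1 is the default study condition.

    Returns
    -------
    DualChannelRecord
    """
    if not script.segments:
        raise ValidationError("scenario script has no segments")
    breathing = breathing or BreathingModel()
    spec = spec or SensorSpec()
    rng = np.random.default_rng(seed)
    fs = script.sample_rate
    dt = 1.0 / fs

    spans = _segment_spans(script)
    n = spans[-1][1]
    t = np.arange(n) * dt

    # ---- scripted targets, carried forward across segments -------------
    ambient_temp = np.empty(n)
    aqi_target = np.empty(n)
    baseline = np.empty(n)
    cur_temp, cur_aqi, cur_base = 20.0, 50.0, 101_325.0
    seg_table = []
    for seg, (i0, i1) in zip(script.segments, spans):
        if seg.ambient_temp is not None:
            cur_temp = seg.ambient_temp
        if seg.ambient_aqi is not None:
            cur_aqi = seg.ambient_aqi
        if seg.pressure_baseline is not None:
            cur_base = seg.pressure_baseline
        ambient_temp[i0:i1] = cur_temp
        aqi_target[i0:i1] = 0.0 if (script.outdoor_aqi_reset and seg.label == "street") else cur_aqi
        base_start = cur_base
        if seg.label == "stairs" and seg.floor_delta:
            baseline[i0:i1] = _stair_baseline(
                cur_base, i1 - i0, fs, seg.floor_delta, script
            )
            cur_base = float(baseline[i1 - 1])
        else:
            baseline[i0:i1] = cur_base
        seg_table.append(
            dict(
                label=seg.label,
                start_s=i0 * dt,
                end_s=i1 * dt,
                ambient_temp=cur_temp,
                ambient_aqi=float(aqi_target[i0]),
                floor_delta=seg.floor_delta,
                baseline_start_pa=base_start,
                baseline_end_pa=cur_base,
            )
        )

    # ---- microclimate temperature baselines ----------------------------
    exhale = breathing.exhale_temp
    inner_target = _INNER_AMBIENT_MIX * ambient_temp + (1 - _INNER_AMBIENT_MIX) * exhale
    outer_target = _OUTER_AMBIENT_MIX * ambient_temp + (1 - _OUTER_AMBIENT_MIX) * exhale
    inner_temp_base = _first_order(inner_target, dt, _THERMAL_TAU_S)
    outer_temp_base = _first_order(outer_target, dt, _THERMAL_TAU_S)

    # ---- breath oscillation --------------------------------------------
    f_breath = breathing.rate / 60.0
    phase = f_breath * t - 0.25  # start at a trough: first mean-crossing ~T/4 in
    wave = _breath_wave(phase, breathing.waveform)
    lag_phase = phase - f_breath * breathing.temp_lag
    wave_lagged = _breath_wave(lag_phase, breathing.waveform)

    # stutters: short split peaks in the pressure channel only; thermal
    # inertia smooths them out of the temperature channel entirely.
    stutter = np.zeros(n)
    n_breaths = int(np.ceil(phase[-1])) + 1
    if breathing.stutter_prob > 0 and n_breaths > 0:
        draws = rng.random(n_breaths) < breathing.stutter_prob
        for b in np.flatnonzero(draws):
            center = b + 0.25  # at the pressure crest of breath b
            mask = np.abs(phase - center) < 4 * _STUTTER_WIDTH
            stutter[mask] -= _STUTTER_DEPTH * np.exp(
                -0.5 * ((phase[mask] - center) / _STUTTER_WIDTH) ** 2
            )

    amp_p_in = breathing.inner_pressure_p2p / 2.0
    amp_p_out = breathing.outer_pressure_p2p / 2.0
    amp_t_in = breathing.inner_temp_p2p / 2.0
    amp_t_out = breathing.outer_temp_p2p / 2.0

    pressure_inner = baseline + amp_p_in * (wave + stutter)
    pressure_outer = baseline + amp_p_out * wave
    temp_inner = inner_temp_base + amp_t_in * wave_lagged
    temp_outer = outer_temp_base + amp_t_out * wave_lagged

    # ---- humidity -------------------------------------------------------
    humidity_inner = saturation_profile(
        t, script.humidity_time_constant, start=script.ambient_rh
    )
    humidity_outer = np.full(n, script.ambient_rh * script.humidity_attenuation)

    # ---- gas resistance and AQI ----------------------------------------
    gas_inner = _GAS_INNER_BASE + _GAS_INNER_AMP * wave
    gas_outer = _GAS_OUTER_BASE + _GAS_OUTER_AMP * wave
    aqi_base = _first_order(aqi_target, dt, _AQI_TAU_S)
    ar = np.empty(n)
    if noise_scale > 0:
        eps = rng.normal(0.0, noise_scale, n)
        y = 0.0
        for i in range(n):
            y = 0.98 * y + eps[i]
            ar[i] = y
    else:
        ar[:] = 0.0
    aqi = np.clip(aqi_base + ar, 0.0, 500.0)
    accuracy = np.searchsorted(np.asarray(script.accuracy_times), t, side="right")

    # ---- sensor imperfections ------------------------------------------
    temp_inner = _noisy(rng, temp_inner, spec.temp_resolution, spec.temp_abs_accuracy, noise_scale)
    temp_outer = _noisy(rng, temp_outer, spec.temp_resolution, spec.temp_abs_accuracy, noise_scale)
    pressure_inner = _noisy(rng, pressure_inner, spec.pressure_resolution, spec.pressure_rel_accuracy, noise_scale)
    pressure_outer = _noisy(rng, pressure_outer, spec.pressure_resolution, spec.pressure_rel_accuracy, noise_scale)
    rh_span = max(100.0 - script.ambient_rh, 1e-9)

    def noisy_humidity(h: np.ndarray) -> np.ndarray:
        taper = np.clip((100.0 - h) / rh_span, 0.0, 1.0)
        out = _noisy(
            rng, h, spec.humidity_resolution, spec.humidity_abs_accuracy,
            noise_scale, taper=taper,
        )
        return _quantize(np.clip(out, 0.0, 100.0), spec.humidity_resolution)

    humidity_inner = noisy_humidity(humidity_inner)
    humidity_outer = noisy_humidity(humidity_outer)
    gas_inner = np.round(gas_inner + (rng.normal(0, 50.0 * noise_scale, n) if noise_scale > 0 else 0.0))
    gas_outer = np.round(gas_outer + (rng.normal(0, 50.0 * noise_scale, n) if noise_scale > 0 else 0.0))
    aqi = np.clip(np.round(aqi, 1), 0.0, 500.0)

    inner = pd.DataFrame(
        dict(
            temperature_c=temp_inner,
            pressure_pa=pressure_inner,
            humidity_pct=humidity_inner,
            gas_ohm=gas_inner,
        )
    )
    outer = pd.DataFrame(
        dict(
            temperature_c=temp_outer,
            pressure_pa=pressure_outer,
            humidity_pct=humidity_outer,
            gas_ohm=gas_outer,
            aqi=aqi,
            aqi_accuracy=accuracy.astype(int),
        )
    )
    meta = dict(
        seed=int(seed),
        scenario=script.name,
        sample_rate=fs,
        sensor_spec=asdict(spec),
        breathing=asdict(breathing),
        segments=seg_table,
        noise_scale=noise_scale,
    )
    return DualChannelRecord(
        sample_rate=fs, time=t, inner=inner, outer=outer, metadata=meta
    )
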