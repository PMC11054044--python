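# Methods

This note documents the models, defaults and numerical choices behind
`masksignal`, and what the synthetic sessions do and do not establish
about real wear data.

## The measurement setting

A protective face mask carries two identical environmental sensor
clusters: *inner* (the wearer's airspace under the mask) and *outer*
(ambient-facing, mounted on the mask surface).  Both sample temperature,
pressure, relative humidity and gas resistance at 10 Hz; the outer side
additionally yields an Air Quality Index (AQI) in [0, 500] with a
calibration status 0–3, produced by the sensor vendor's proprietary
software stack.  The package never computes AQI from gas resistance — it
consumes AQI values as given, which is also why the simulator emits AQI
directly.  No AQI is computed for the inner side: exhaled air keeps that
microclimate permanently "polluted" and the index would be meaningless.

## Synthetic sessions

`simulate_session(script, breathing, spec, seed)` is the package's data
source; its defaults *are* the study conditions, chosen to match the
signal structure reported from wear trials, and they are not tuned per
experiment.

**Breathing.**  Breath phase advances at `rate`/60 Hz (default
12 breaths/min, the low end of the normal-activity band; observed field
rates were ~9–11/min).  The pressure waveform is a sinusoid by default
(an asymmetric fast-exhale variant is available); peak-to-peak defaults:
inner pressure 30 Pa (the 20–40 Pa band), outer pressure 6 Pa (< 10 Pa),
inner temperature 0.8 °C (≤ 1 °C), outer temperature 0.25 °C.

**Thermal lag.**  The temperature channel trails pressure by `temp_lag`
(default 3 s).  It is realized as an exact transport delay of the breath
component rather than a first-order low-pass tuned for group delay: a
first-order filter's phase delay at breathing frequencies saturates below
~1.7 s no matter its time constant, so it cannot reproduce a 3 s lag.
The smoothing role of thermal inertia is captured separately: breath
*stutters* (probability `stutter_prob` per breath) inject a short
split-peak into the pressure waveform only, never into temperature.
This reproduces the observed mechanism by which pressure-based breath
counts exceed temperature-based counts.

**Microclimate baselines.**  Both sensors sit in exhale-heated air.  The
inner baseline mixes 1/3 ambient with 2/3 exhaled air (34 °C), the outer
0.4/0.6, each tracking its target through a first-order lag (τ = 30 s).
This reproduces the field pattern: ~23 °C on a 0 °C street, approaching
30 °C indoors, inner/outer within ~2 °C.  Consequence: absolute ambient
temperature is not recoverable from the device — only characteristic
*changes* are, which is exactly what zone segmentation uses.

**Pressure baselines and stairs.**  Each scripted segment carries a
barometric baseline (carried forward when unspecified).  A stairs segment
ramps the baseline by `per_floor_pa` (default 57.5 Pa, the midpoint of
the reported 55–60 Pa/storey) per floor over `stair_ramp_s` (10 s) with
flat landings (`stair_landing_s`, 5 s) between floors; ascent lowers
pressure.

**Humidity.**  Inner humidity follows `saturation_profile`: an
exponential approach from the ambient level (default 40 %rh) toward
100 %rh with time constant 500 s, crossing 95 %rh at ~21 min — inside the
20–30 min saturation window seen in wear trials.  Outer humidity is the
ambient level times a mask-capture attenuation (default 0.4, matching
outer readings of 30–40 % under 80–100 % ambient).

**Gas resistance and AQI.**  Gas resistance oscillates with breathing
(amplitudes ~Δ3 kΩ inner, ~Δ10 kΩ outer around 50/100 kΩ baselines).
AQI follows the scripted per-segment level through a 60 s first-order lag
plus a bounded AR(1) fluctuation (~±10–20 peak-to-peak); an option resets
street segments toward 0 (fresh outdoor air).  The calibration status
advances 0→1→2→3 at `accuracy_times` (defaults 10, 32 and 40 min), so
the usual reliability gate (status ≥ 2) opens only after half an hour.

**Sensor imperfections.**  Every channel is quantized to the datasheet
resolution (0.01 °C, 0.18 Pa, 0.008 %rh) after adding one per-session
constant bias (drawn within the accuracy bound: ±0.5 °C, ±12 Pa relative,
±3 %rh) plus white noise at one resolution step, truncated at the same
bound.  Accuracy figures are treated as bias-like rather than per-sample
white noise: white noise at the accuracy bound would bury the 20–40 Pa
breath band, which contradicts the clean breath traces the hardware
records.  The humidity error is tapered to zero as the reading approaches
saturation — a condensing element reads pinned near 100 %rh regardless of
its mid-range accuracy — which keeps the saturation-detection time inside
the 20–30 min window for every seed.

**Determinism.**  One `numpy` generator seeded from `seed` drives all
draws in fixed order; identical inputs give bit-identical records.

**What the simulator does not emulate:** flow turbulence beyond scripted
stutters, motion artefacts, posture and fit effects, weather-front
pressure drift, sensor aging, and the true nonlinear behaviour of the
proprietary AQI algorithm.  Passing recovery tests on these sessions
therefore demonstrates correctness of the *algorithms* under the stated
signal model, not field-grade performance.

## Breath detection

The detector uses the signal's own centred moving mean (window 5 s,
shrinking at the edges) as an adaptive threshold; one rising crossing =
one breath.  Default settings: refractory interval 1.5 s (caps the
detectable rate at 40/min, far above the normal 12–20/min band);
amplitude gate of 4 resolution steps (suppresses quantization chatter on
a flat channel); no pre-filtering at 10 Hz.  A symmetric arming band
(half the amplitude gate) requires the signal to leave mean − h before
the next event can fire at mean + h, so noise dithering exactly at the
threshold cannot re-trigger; on clean signals the crossing count is
unchanged and the band can be set to 0.  The estimate is invariant to
constant offsets and to amplitude rescaling above the gate.  The 5 s
window is a deliberate compromise: long enough to track the baseline
rather than individual breaths at 12/min, short enough to follow ambient
drift.  Rates near or below 6/min approach the window's half-period and
are the edge of validity.

## Fusion

Drift is the least-squares slope of the 5 s-smoothed series over a 60 s
window (edge-shrunk smoothing samples excluded so a pure ramp yields its
exact slope), evaluated every 30 s.  Thresholds: 0.1 °C/min for
temperature; 30 Pa per 10 s for the pressure baseline — between
breath-band residue (zero-mean, averaged away by the smoothing) and the
~50–60 Pa/10 s storey signature sustained across a window.  State rule:
temperature steady → TEMPERATURE; temperature drifting, pressure steady
→ PRESSURE; both moving → PAUSED (no rate, waiting flag).  The *active*
source additionally applies a two-evaluation hysteresis to suppress
chatter at the threshold; the instantaneous rule decision is kept
alongside it in the results.  The evaluation cadence (30 s stride, 60 s
window) is a package choice — the switching thresholds have stated
values, the cadence does not.

## Altimetry

Heights use the linearized hypsometric form Δh = Δp/(ρg) with ρ evaluated
at the mid-pressure and 288.15 K (standard atmosphere; the outer sensor,
not the exhale-heated inner one, drives altimetry).  Against the
log-form barometric formula the linear form agrees to < 0.1 % for
|Δp| ≤ 200 Pa, well beyond building scales.  The recorded two-storey
floor pressures (102 480 / 102 420 / 102 365 Pa) give 60 and 55 Pa drops
and 4.94 / 4.53 m storeys, inside the 4.5–5 m band of the building's
storey height.  Absolute altitude is explicitly out of scope: the
embedded sensor has an uncalibrated offset, exposed as a single
calibration constant.

Floor detection compares the 5 s-smoothed baseline with itself 10 s
earlier; runs where the difference exceeds 40 Pa (above breath residue,
below one floor) become events.  The step height is measured between the
smoothed plateaus just outside the lag span of the run's extremum, which
recovers the full step for ramps up to one window long — the
lagged-difference extremum itself underestimates a ramp whose smoothing
span exceeds the lag.  Consecutive floors need landings of at least half
the smoothing window to resolve as separate events; a fully continuous
multi-floor climb merges (and, combined with an ambient temperature
step, is precisely the PAUSED condition).

## AQI, humidity and zones

The seven AQI classes partition [0, 500] contiguously with upper bounds
50, 100, 150, 200, 250, 350, 500.  The vendor's printed table overlaps at
"severely polluted"; the only contiguous reading (251–350) is used, and
the top class covers 351–500 so every value has exactly one class.

Reliability gating keeps samples with calibration status ≥ 2 (the
"calibration in progress" level at which field AQI became usable);
status ≥ 0 is the degenerate gate accepting everything.  Humidity
validity flags the inner channel from the first time it holds ≥ 95 %rh
for 60 s — a single spike does not invalidate.

Zone segmentation finds baseline shifts (≥ 3 °C within 60 s) in the outer
temperature and (≥ 50 AQI) in the *reliable* part of the AQI trace;
pre-calibration AQI can never create a boundary.  Boundaries closer than
one window merge (a shop door yields one boundary, not two).  Labels:
mean outer temperature ≥ 26 °C → indoor (exhale-heated microclimate
approaches 30 °C indoors); intermediate temperature with reliable mean
AQI ≥ 120 → transit; ≤ 24 °C → outdoor; intermediate temperature without
reliable AQI → unknown.  Temperature is primary evidence because it is
always available; AQI is secondary because it is gated.

## Filtration and power

PFE is the exact ratio formula per bin; it is scale-invariant in the
counts (consistent with validation showing concentration independence
within 1–5 × 10⁷ /m³).  Empty ambient bins give NaN with an `invalid`
flag; behind-mask counts above ambient give *negative* efficiencies kept
with a flag rather than clamped — a prepared mask out-measuring its
reference is information about measurement variation.  Bins with fewer
than 10 expected ambient counts over the sampled volume (duration ×
30 l/min by default) carry a `low_count` flag, since Poisson error
dominates there.

The power budget interprets the consumption table's time ratios as duty
fractions of a 1-second cycle (their products reproduce the printed
per-component consumption figures); average current is the duty-weighted
sum, 1.8662 mA for the as-built table, and endurance is capacity divided
by that — 96.45 h on 180 mAh.  One printed consumption cell (voltage
divider + ADC, 2.47 × 10⁻⁸ mA·s) appears truncated rather than rounded
from 1.10 × 10⁻⁸ × 2.25 = 2.475 × 10⁻⁸; the reproduction test allows
0.5 % to cover either convention.  No discharge-curve modelling: endurance
assumes nominal capacity at the average current.

## Problem sizes

Recovery suites run on deliberately compact sessions: 2-minute windows
for rate recovery (5 rates × 20 seeds × 2 channels), 15-minute scripted
walks for fusion, ~3-minute stair scripts (20 seeds) for altimetry, and a
35-minute session for the AQI/humidity validity windows.  These sizes
give counting granularities (0.5 breaths/min on 2-minute windows) well
inside the ±1 breath/min and 10 % height tolerances being checked, so
larger sessions would not change the verdicts.

## Known limitations

* Rates below ~6/min or above ~40/min are outside the detector defaults
  (window and refractory would need rescaling).
* Fused rates inherit stutter over-counting whenever the pressure source
  is active; the temperature source is immune by construction.
* Zone labels depend on the exhale-heated temperature model; masks with
  very different thermal coupling would need re-thresholding.
* The AQI fluctuation model is stationary; real urban plumes are not.
* Session CSV I/O assumes one fixed sample rate per file.
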