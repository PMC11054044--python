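"""Shared signal-processing primitives.

Everything downstream (breath detection, drift estimation, floor and zone
change-point detection) is built on three primitives: a centred moving mean
with shrinking edges, an ordinary-least-squares slope, and a baseline-shift
detector that compares the moving mean against itself one window earlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["moving_mean", "ols_slope", "BaselineShift", "baseline_shifts"]


def moving_mean(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving mean; the window shrinks near the edges.

    Sample ``i`` averages ``x[i - (w-1)//2 : i + w//2 + 1]`` clipped to the
    series, so the output has the same length as the input and edge samples
    average whatever part of the window exists.

    Parameters
    ----------
    x : ndarray
        Uniformly sampled series.
    window_samples : int
        Window length in samples, >= 2 and <= len(x).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    w = int(window_samples)
    if w < 2:
        raise ValidationError(f"moving-mean window must be >= 2 samples, got {w}")
    if w > n:
        raise ValidationError(
            f"moving-mean window ({w} samples) longer than series ({n} samples)"
        )
    left = (w - 1) // 2
    right = w // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def interior_slice(n: int, window_samples: int) -> slice:
    """Indices where the centred window of :func:`moving_mean` is full-width."""
    w = int(window_samples)
    return slice((w - 1) // 2, n - w // 2)


def ols_slope(y: np.ndarray, dt: float) -> float:
    """Least-squares slope of ``y`` against time, in units of y per second."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValidationError("slope needs at least two samples")
    t = np.arange(y.size) * dt
    t = t - t.mean()
    return float(t @ (y - y.mean()) / (t @ t))


@dataclass(frozen=True)
class BaselineShift:
    """One detected baseline shift.

    Attributes
    ----------
    time_s : float
        Time of the strongest shift within the detection run.
    delta : float
        Signed baseline change over the detection window (series units).
    start_s, end_s : float
        Extent of the above-threshold run.
    """

    time_s: float
    delta: float
    start_s: float
    end_s: float


def baseline_shifts(
    x: np.ndarray,
    sample_rate: float,
    threshold: float,
    window_s: float,
    smooth_s: float | None = None,
) -> list[BaselineShift]:
    """Detect shifts of the slow baseline of ``x`` by >= ``threshold``.

    The series is first smoothed with a centred moving mean of ``smooth_s``
    (default: half of ``window_s``) to remove oscillatory content, then the
    smoothed series is compared with itself ``window_s`` earlier; contiguous
    runs where the absolute difference meets ``threshold`` become one event
    each.  The event magnitude is measured between the smoothed plateaus on
    either side of the run's extremum (``smooth_s`` beyond the lag span), so
    a monotone step completed within the window recovers its full height
    even though smoothing widens the transition.

    Returns an empty list for a flat series; never raises on clean input.
    """
    x = np.asarray(x, dtype=float)
    fs = float(sample_rate)
    w = max(2, int(round(window_s * fs)))
    sm = max(2, int(round((window_s / 2.0 if smooth_s is None else smooth_s) * fs)))
    if x.size <= w + sm:
        return []
    mm = moving_mean(x, sm)
    d = np.full(x.size, 0.0)
    d[w:] = mm[w:] - mm[:-w]
    above = np.abs(d) >= threshold
    if not above.any():
        return []
    events: list[BaselineShift] = []
    idx = np.flatnonzero(above)
    run_start = idx[0]
    prev = idx[0]
    runs = []
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    n = x.size
    for i0, i1 in runs:
        seg = d[i0 : i1 + 1]
        k = i0 + int(np.argmax(np.abs(seg)))
        post = mm[min(k + sm, n - 1)]
        pre = mm[max(k - w - sm, 0)]
        events.append(
            BaselineShift(
                time_s=k / fs,
                delta=float(post - pre),
                start_s=i0 / fs,
                end_s=i1 / fs,
            )
        )
    return events
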