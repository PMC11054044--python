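"""Session CSV format: write and read dual-channel records.

Schema (version 1)
------------------
A UTF-8, comma-separated file, ``.`` decimal separator.  Header lines start
with ``#`` and carry key/value metadata (at minimum the schema tag and the
sample rate); the data section has the columns::

    time_s, side, temperature_c, pressure_pa, humidity_pct, gas_ohm, aqi, aqi_accuracy

``side`` is ``inner`` or ``outer``; the two AQI columns are empty on inner
rows (the index is only computed for ambient air).  Time is seconds from
session start; a wall-clock start, when known, lives in the header.  Rows
may be blocked by side or interleaved; time must be strictly increasing
within each side.  Numeric formatting preserves the sensor resolutions
(temperature and pressure to 2 decimals, humidity to 3), so a write->read
round trip is lossless at the stated resolutions.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, SessionParseError
from .record import DualChannelRecord, INNER_COLUMNS

SCHEMA = "masksignal-session v1"

_COLUMNS = (
    "time_s",
    "side",
    "temperature_c",
    "pressure_pa",
    "humidity_pct",
    "gas_ohm",
    "aqi",
    "aqi_accuracy",
)

_FORMATS = {
    "time_s": "{:.3f}",
    "temperature_c": "{:.2f}",
    "pressure_pa": "{:.2f}",
    "humidity_pct": "{:.3f}",
    "gas_ohm": "{:.1f}",
    "aqi": "{:.1f}",
}


def write_session(record: DualChannelRecord, path: str | Path) -> None:
    """Write ``record`` to ``path`` in the session CSV schema.

    Output bytes are deterministic for a fixed record.
    """
    buf = io.StringIO()
    buf.write(f"# {SCHEMA}\n")
    buf.write(f"# sample_rate_hz: {record.sample_rate:g}\n")
    for key in ("seed", "scenario"):
        if key in record.metadata:
            buf.write(f"# {key}: {record.metadata[key]}\n")
    buf.write(",".join(_COLUMNS) + "\n")
    for side_name, frame in (("inner", record.inner), ("outer", record.outer)):
        t = record.time
        cols = {c: frame[c].to_numpy() for c in frame.columns}
        for i in range(len(frame)):
            row = [_FORMATS["time_s"].format(t[i]), side_name]
            for c in INNER_COLUMNS:
                row.append(_FORMATS[c].format(cols[c][i]))
            if side_name == "outer":
                row.append(_FORMATS["aqi"].format(cols["aqi"][i]))
                row.append(str(int(cols["aqi_accuracy"][i])))
            else:
                row.extend(("", ""))
            buf.write(",".join(row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_session(path: str | Path) -> DualChannelRecord:
    """Read a session CSV into a :class:`DualChannelRecord`.

    Both sides are aligned to a common clock; samples missing from the
    uniform grid are flagged (not interpolated) in ``metadata['gaps']`` as
    per-side lists of gap positions (index of the sample *after* the gap).

    Raises
    ------
    SessionParseError
        Missing/unknown schema header, empty data section, malformed rows.
    AlignmentError
        Side sample rates disagree with the header rate, or the two sides
        cannot be placed on one clock.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines or SCHEMA not in lines[0]:
        raise SessionParseError(f"{path}: missing schema header '{SCHEMA}'")
    header: dict[str, str] = {}
    for ln in lines[1:]:
        if not ln.startswith("#"):
            break
        if ":" in ln:
            k, v = ln.lstrip("# ").split(":", 1)
            header[k.strip()] = v.strip()
    try:
        sample_rate = float(header["sample_rate_hz"])
    except (KeyError, ValueError):
        raise SessionParseError(f"{path}: header lacks a numeric sample_rate_hz")
    try:
        df = pd.read_csv(io.StringIO(text), comment="#")
    except Exception as exc:
        raise SessionParseError(f"{path}: {exc}") from exc
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise SessionParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise SessionParseError(f"{path}: empty data section")
    bad = ~df["side"].isin(("inner", "outer"))
    if bad.any():
        line = df.index[bad][0] + 2  # +1 header row, +1 one-based
        raise SessionParseError(f"{path}: invalid side value near data line {line}")

    dt = 1.0 / sample_rate
    sides: dict[str, pd.DataFrame] = {}
    gaps: dict[str, list[int]] = {}
    for side_name in ("inner", "outer"):
        part = df[df["side"] == side_name].reset_index(drop=True)
        if part.empty:
            raise SessionParseError(f"{path}: no rows for side {side_name!r}")
        tv = part["time_s"].to_numpy(dtype=float)
        if (np.diff(tv) <= 0).any():
            k = int(np.flatnonzero(np.diff(tv) <= 0)[0])
            raise SessionParseError(
                f"{path}: time not strictly increasing for side {side_name!r} "
                f"at sample {k + 1}"
            )
        steps = np.diff(tv)
        if steps.size:
            med = float(np.median(steps))
            if abs(med - dt) > 0.01 * dt:
                raise AlignmentError(
                    f"{path}: side {side_name!r} sample spacing {med:g}s "
                    f"disagrees with header rate {sample_rate:g} Hz"
                )
        gaps[side_name] = [int(i) + 1 for i in np.flatnonzero(steps > 1.5 * dt)]
        sides[side_name] = part
    t_in = sides["inner"]["time_s"].to_numpy(dtype=float)
    t_out = sides["outer"]["time_s"].to_numpy(dtype=float)
    if t_in.size != t_out.size or not np.allclose(t_in, t_out, atol=dt / 4):
        raise AlignmentError(f"{path}: inner and outer sides are on different clocks")

    inner = sides["inner"][list(INNER_COLUMNS)].astype(float).reset_index(drop=True)
    outer = sides["outer"][
        list(INNER_COLUMNS) + ["aqi", "aqi_accuracy"]
    ].reset_index(drop=True)
    outer["aqi"] = outer["aqi"].astype(float)
    outer["aqi_accuracy"] = outer["aqi_accuracy"].astype(int)
    outer[list(INNER_COLUMNS)] = outer[list(INNER_COLUMNS)].astype(float)
    meta: dict = {"gaps": gaps, "source_file": str(path)}
    if "seed" in header:
        try:
            meta["seed"] = int(header["seed"])
        except ValueError:
            pass
    if "scenario" in header:
        meta["scenario"] = header["scenario"]
    return DualChannelRecord(
        sample_rate=sample_rate, time=t_in, inner=inner, outer=outer, metadata=meta
    )
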