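"""CSV round-trip for sleep sessions.

The on-disk layout mirrors the collector's format: one row per 10 s sample
with columns ``timestamp, T1..Tn, H1..Hn, Tamb1, Hamb1, ...``. Timestamps
are emitted as epoch-style seconds; ISO-8601 strings are accepted on read.
The ground-truth posture schedule travels in an optional JSON sidecar
(list of ``{"start_s": ..., "posture": ...}`` plus the duration).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PostureSchedule, SensorArrayConfig, SleepSession

__all__ = ["write_session_csv", "read_session_csv", "write_truth_json", "read_truth_json"]

_FLOAT_FMT = "%.6f"


class SessionFormatError(ValueError):
    """Malformed session file (missing columns, bad values, bad ordering)."""


def _columns(n_sensors: int, ambient_channels: int) -> list[str]:
    cols = ["timestamp"]
    cols += [f"T{k}" for k in range(1, n_sensors + 1)]
    cols += [f"H{k}" for k in range(1, n_sensors + 1)]
    for k in range(1, ambient_channels + 1):
        cols += [f"Tamb{k}", f"Hamb{k}"]
    return cols


def write_session_csv(session: SleepSession, path: str | Path) -> Path:
    """Write a session; values rounded to 6 decimal places."""
    path = Path(path)
    n_sensors = session.humidity.shape[1]
    amb = session.ambient.reshape(session.n_samples, -1)
    data = np.column_stack(
        [session.timestamps, session.temperature, session.humidity, amb]
    )
    df = pd.DataFrame(data, columns=_columns(n_sensors, session.ambient.shape[1]))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_session_csv(
    path: str | Path,
    config: SensorArrayConfig | None = None,
    truth: PostureSchedule | None = None,
) -> SleepSession:
    """Read and validate a session CSV.

    Errors name the offending data row (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SessionFormatError(f"{path}: file is empty") from None
    if df.empty:
        raise SessionFormatError(f"{path}: no data rows")

    sensor_cols = sorted(
        (c for c in df.columns if c.startswith("H") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    n_sensors = len(sensor_cols)
    amb_cols = [c for c in df.columns if c.startswith(("Tamb", "Hamb"))]
    n_ambient = len(amb_cols) // 2
    expected = _columns(n_sensors, n_ambient)
    missing = [c for c in expected if c not in df.columns]
    if n_sensors == 0 or missing:
        raise SessionFormatError(f"{path}: missing columns {missing or ['H1..Hn']}")

    ts_raw = df["timestamp"]
    if ts_raw.dtype == object:  # ISO-8601 strings
        try:
            ts = pd.to_datetime(ts_raw).astype("int64").to_numpy() / 1e9
        except (ValueError, TypeError) as exc:
            raise SessionFormatError(f"{path}: unparseable timestamps: {exc}") from None
        ts = ts - ts[0]
    else:
        ts = ts_raw.to_numpy(dtype=float)
    bad = np.nonzero(np.diff(ts) <= 0)[0]
    if bad.size:
        raise SessionFormatError(
            f"{path}: non-monotone timestamp at row {int(bad[0]) + 2}"
        )

    hum = df[[f"H{k}" for k in range(1, n_sensors + 1)]].to_numpy(dtype=float)
    out_of_range = np.nonzero((hum < 0) | (hum > 100))[0]
    if out_of_range.size:
        raise SessionFormatError(
            f"{path}: humidity outside [0, 100] at row {int(out_of_range[0]) + 1}"
        )
    temp = df[[f"T{k}" for k in range(1, n_sensors + 1)]].to_numpy(dtype=float)
    amb = df[amb_cols].to_numpy(dtype=float).reshape(len(df), n_ambient, 2) if n_ambient else np.zeros((len(df), 0, 2))

    if config is None:
        period = float(ts[1] - ts[0]) if len(ts) >= 2 else 10.0
        config = SensorArrayConfig(
            n_sensors=n_sensors,
            sampling_period_s=period,
            ambient_channels=n_ambient,
        )
    return SleepSession(
        timestamps=ts,
        humidity=hum,
        temperature=temp,
        ambient=amb,
        config=config,
        truth=truth,
    )


def write_truth_json(schedule: PostureSchedule, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "duration_s": schedule.duration_s,
        "segments": [{"start_s": s, "posture": p} for s, p in schedule.segments],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_truth_json(path: str | Path) -> PostureSchedule:
    payload = json.loads(Path(path).read_text())
    segments = [(seg["start_s"], seg["posture"]) for seg in payload["segments"]]
    return PostureSchedule(segments, payload["duration_s"])
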