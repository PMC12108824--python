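"""Synthetic sleep sessions for a humidity-sensor pillow.

A linear array of combined temperature/humidity sensors (DHT22-class,
±2 %RH) is embedded across a pillow. While the head rests over a group of
sensors, trapped moisture drives local relative humidity up toward a
saturation plateau; sensors released by a posture change dry back down to
the room baseline. The generator reproduces that structure with a known
ground-truth posture schedule so every downstream stage (flux statistic,
change-point detection, image classification) can be validated exactly.

Signal model
------------
Each humidity channel follows a first-order relaxation toward a
posture-dependent contact level::

    h_k(t_i) = L_k(p_i) + (h_k(t_{i-1}) - L_k(p_i)) * exp(-dt / tau)

where ``L_k(p)`` is a bell-shaped contact profile centred under the head
position of posture ``p`` (left / supine / right) and ``tau`` is the
moisture time constant. Independent Gaussian sensor noise is added and the
result clipped to [0, 100] %RH. The two end sensors see the largest
left-vs-right level difference and respond with opposite signs on a
left<->right turn, the most posture-sensitive channels of the array.

Temperature channels drift slowly and monotonically (well under 1 °C/h)
with small noise: temperature carries far less posture information than
humidity, and the pipeline deliberately ignores it. Ambient channels are
slow AR(1) fluctuations around fixed room conditions and exist only to
exercise I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "POSTURES",
    "SensorArrayConfig",
    "PostureSchedule",
    "SleepSession",
    "simulate_session",
    "random_schedule",
]

#: Canonical label order (matches the y-axis convention right < supine < left).
POSTURES = ("right", "supine", "left")

#: Humidity of a sensor far from the head, %RH.
BASELINE_RH = 35.0
#: Humidity plateau directly under the head, %RH.
CONTACT_RH = 85.0
#: Width of the contact profile, in sensor pitches.
CONTACT_WIDTH = 1.5


@dataclass(frozen=True)
class SensorArrayConfig:
    """Geometry, sampling and noise of the pillow sensor array."""

    n_sensors: int = 7
    spacing_mm: float = 25.0
    sampling_period_s: float = 10.0
    noise_sd_rh: float = 0.5
    ambient_channels: int = 2
    #: First-order moisture relaxation time constant, seconds.
    time_constant_s: float = 120.0
    #: Monotone temperature drift, °C per hour (kept well below 1).
    temp_drift_c_per_h: float = 0.4

    def __post_init__(self) -> None:
        if self.n_sensors < 2:
            raise ValueError("n_sensors must be >= 2")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.sampling_period_s <= 0:
            raise ValueError("sampling_period_s must be positive")
        if self.noise_sd_rh < 0:
            raise ValueError("noise_sd_rh must be non-negative")
        if self.ambient_channels < 0:
            raise ValueError("ambient_channels must be non-negative")
        if self.time_constant_s <= 0:
            raise ValueError("time_constant_s must be positive")
        if not 0 <= self.temp_drift_c_per_h <= 1:
            raise ValueError("temp_drift_c_per_h must be in [0, 1] °C/h")


@dataclass(frozen=True)
class PostureSchedule:
    """Piecewise-constant ground-truth posture over a session.

    ``segments`` is an ordered list of ``(start_time_s, posture)`` pairs;
    the first must start at 0, starts must be strictly increasing and lie
    inside ``duration_s``, and consecutive segments must differ in posture.
    """

    segments: tuple[tuple[float, str], ...]
    duration_s: float

    def __init__(self, segments: Sequence[tuple[float, str]], duration_s: float):
        segments = tuple((float(s), str(p)) for s, p in segments)
        if not segments:
            raise ValueError("schedule needs at least one segment")
        if segments[0][0] != 0.0:
            raise ValueError("first segment must start at time 0")
        starts = [s for s, _ in segments]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        for _, p in segments:
            if p not in POSTURES:
                raise ValueError(f"unknown posture {p!r}; expected one of {POSTURES}")
        for (_, p0), (_, p1) in zip(segments, segments[1:]):
            if p0 == p1:
                raise ValueError("consecutive segments must have different postures")
        if duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if starts[-1] >= duration_s:
            raise ValueError("schedule extends beyond the session duration")
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "duration_s", float(duration_s))

    @property
    def transition_times(self) -> np.ndarray:
        """Times (s) of the posture changes, excluding the session start."""
        return np.array([s for s, _ in self.segments[1:]], dtype=float)

    def posture_at(self, times: np.ndarray) -> np.ndarray:
        """Posture label for each query time (right-open segments)."""
        times = np.asarray(times, dtype=float)
        starts = np.array([s for s, _ in self.segments])
        labels = np.array([p for _, p in self.segments], dtype=object)
        idx = np.searchsorted(starts, times, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("query time before session start")
        return labels[idx]


@dataclass
class SleepSession:
    """One night of multichannel pillow data at a fixed sampling period."""

    timestamps: np.ndarray  # (n,) seconds, equally spaced
    humidity: np.ndarray  # (n, n_sensors) %RH in [0, 100]
    temperature: np.ndarray  # (n, n_sensors) °C
    ambient: np.ndarray  # (n, ambient_channels, 2) = (temp °C, RH %)
    config: SensorArrayConfig = field(default_factory=SensorArrayConfig)
    truth: PostureSchedule | None = None

    def __post_init__(self) -> None:
        n = len(self.timestamps)
        if self.humidity.shape[0] != n or self.temperature.shape[0] != n:
            raise ValueError("channel matrices must share the time dimension")
        if self.ambient.shape[0] != n:
            raise ValueError("ambient matrix must share the time dimension")
        if n >= 2:
            steps = np.diff(self.timestamps)
            if not np.allclose(steps, steps[0]):
                raise ValueError("timestamps must be equally spaced")
        if np.any(self.humidity < 0) or np.any(self.humidity > 100):
            raise ValueError("humidity outside [0, 100] %RH")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def sampling_period_s(self) -> float:
        return float(self.config.sampling_period_s)


def contact_levels(config: SensorArrayConfig) -> dict[str, np.ndarray]:
    """Posture -> per-sensor steady-state humidity level (%RH).

    A Gaussian bell of width ``CONTACT_WIDTH`` sensor pitches is centred one
    pitch in from the left end (left posture), at the array centre (supine),
    or one pitch in from the right end (right posture). This loads roughly
    three adjacent sensors per posture on a 7-sensor array and gives the end
    sensors the largest left-vs-right contrast, with opposite signs.
    """
    n = config.n_sensors
    centers = {"left": 1.0, "supine": (n - 1) / 2.0, "right": float(n - 2)}
    k = np.arange(n, dtype=float)
    out = {}
    for posture, c in centers.items():
        bump = np.exp(-0.5 * ((k - c) / CONTACT_WIDTH) ** 2)
        out[posture] = BASELINE_RH + (CONTACT_RH - BASELINE_RH) * bump
    return out


def simulate_session(
    config: SensorArrayConfig,
    schedule: PostureSchedule,
    seed: int,
) -> SleepSession:
    """Simulate one session; bit-identical for identical inputs and seed."""
    rng = np.random.default_rng(seed)
    dt = config.sampling_period_s
    n = int(round(schedule.duration_s / dt))
    if n < 1:
        raise ValueError("session shorter than one sampling period")
    t = np.arange(n) * dt

    levels = contact_levels(config)
    postures = schedule.posture_at(t)
    target = np.stack([levels[p] for p in postures])  # (n, n_sensors)

    decay = np.exp(-dt / config.time_constant_s)
    h = np.empty_like(target)
    h[0] = target[0]  # start in steady state for the initial posture
    for i in range(1, n):
        h[i] = target[i] + (h[i - 1] - target[i]) * decay
    if config.noise_sd_rh > 0:
        h = h + rng.normal(0.0, config.noise_sd_rh, size=h.shape)
    h = np.clip(h, 0.0, 100.0)

    drift = config.temp_drift_c_per_h * (t / 3600.0)
    temp = 33.0 + drift[:, None] + np.zeros((1, config.n_sensors))
    if config.noise_sd_rh > 0:
        temp = temp + rng.normal(0.0, 0.05, size=temp.shape)

    amb = np.empty((n, config.ambient_channels, 2))
    if config.ambient_channels:
        means = np.array([24.0, 45.0])  # room temperature °C, room RH %
        sds = np.array([0.05, 0.2])
        phi = 0.995
        amb[0] = means
        eps = rng.normal(0.0, 1.0, size=(n, config.ambient_channels, 2)) * sds
        for i in range(1, n):
            amb[i] = means + phi * (amb[i - 1] - means) + eps[i]

    return SleepSession(
        timestamps=t,
        humidity=h,
        temperature=temp,
        ambient=amb,
        config=config,
        truth=schedule,
    )


def random_schedule(
    duration_s: float = 4 * 3600.0,
    n_transitions: int | tuple[int, int] = (6, 20),
    min_gap_s: float = 600.0,
    sampling_period_s: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> PostureSchedule:
    """Draw a posture schedule with a minimum dwell time per posture.

    Gaps between transitions are the minimum dwell plus a Dirichlet share of
    the leftover duration, snapped to the sampling grid, so any feasible
    transition count is generated directly (no rejection sampling). Postures
    form a random walk over {right, supine, left} with no self-transitions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(n_transitions, tuple):
        lo, hi = n_transitions
        k = int(rng.integers(lo, hi + 1))
    else:
        k = int(n_transitions)
    if k < 0:
        raise ValueError("n_transitions must be non-negative")
    leftover = duration_s - (k + 1) * min_gap_s
    if leftover < 0:
        raise ValueError("duration too short for this many transitions")
    gaps = min_gap_s + rng.dirichlet(np.ones(k + 1)) * leftover
    times = np.round(np.cumsum(gaps)[:-1] / sampling_period_s) * sampling_period_s

    postures = [POSTURES[rng.integers(len(POSTURES))]]
    for _ in range(k):
        choices = [p for p in POSTURES if p != postures[-1]]
        postures.append(choices[rng.integers(len(choices))])
    segments = [(0.0, postures[0])] + [
        (float(ts), p) for ts, p in zip(times, postures[1:])
    ]
    return PostureSchedule(segments, duration_s)
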