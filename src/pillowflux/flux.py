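"""The humidity-flux statistic: per-window change aggregated across sensors.

A posture change disturbs several humidity channels at once. Rather than
tracking channels individually, the pipeline collapses them into a single
non-negative "flux" series that is large exactly while the head is moving:

* ``squared_change_sum`` — per timestamp, the sum over sensors of the
  squared first difference. Squaring prevents simultaneous rises and falls
  (the signature of a left<->right turn) from cancelling.
* ``windowed_std_flux`` — per window, the sum over sensors of the
  population standard deviation of the window's samples (divisor N). The
  default window is 1 min, i.e. at least six samples at the 10 s period.

Flux values are attributed to the trailing window's last sample; the
residual detection latency is handled by the change-point module's lag
correction. Threshold flags reproduce the simple exceedance rule (e.g.
0.43 on the normalized squared-change sum) used as a first-pass indicator
before full segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import SleepSession

__all__ = [
    "FluxSeries",
    "FluxEvent",
    "SquaredChangeFlux",
    "WindowedStdFlux",
    "squared_change_sum",
    "windowed_std_flux",
    "threshold_flags",
]


@dataclass
class FluxSeries:
    """Aggregated change statistic, one value per window or timestamp."""

    values: np.ndarray
    kind: str  # "squared_change_sum" | "std_sum"
    window_s: float
    sampling_period_s: float
    normalized: bool
    #: Trailing-window length in samples (1 for the squared-change sum).
    window_samples: int = 1
    #: Timestamp (s) each value is attributed to (window's last sample).
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("flux values must be non-negative")
        if self.normalized and len(self.values) and not np.isclose(self.values.max(), 1.0):
            raise ValueError("normalized flux must have max 1")


@dataclass
class FluxEvent:
    """A contiguous run of flux samples above threshold."""

    start: int
    peak: int
    end: int  # inclusive index of the run's last sample


def _maybe_normalize(values: np.ndarray, normalize: bool) -> tuple[np.ndarray, bool]:
    if not normalize:
        return values, False
    lo, hi = values.min(), values.max()
    if hi == lo:
        # Constant (typically all-zero) flux carries no events; leave as is.
        return values, False
    return (values - lo) / (hi - lo), True


class SquaredChangeFlux(TransformerMixin, BaseEstimator):
    """Sum over sensors of squared one-step humidity differences."""

    def __init__(self, sensors=None, normalize: bool = True):
        self.sensors = sensors
        self.normalize = normalize

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        H = _humidity_matrix(X, self.sensors)
        if H.shape[0] < 2:
            raise ValueError("need at least two time points")
        d = np.diff(H, axis=0)
        vals = np.concatenate([[0.0], (d * d).sum(axis=1)])
        vals, _ = _maybe_normalize(vals, self.normalize)
        return vals


class WindowedStdFlux(TransformerMixin, BaseEstimator):
    """Sum over sensors of per-window population standard deviations.

    ``mode="sliding"`` (default) recomputes the statistic for every
    trailing window with 1-sample stride, using partial windows at the
    series start; ``mode="tiled"`` partitions the session into disjoint
    subintervals and yields one value per subinterval.
    """

    def __init__(
        self,
        sensors=None,
        window_s: float = 60.0,
        min_points: int = 6,
        mode: str = "sliding",
        normalize: bool = True,
    ):
        self.sensors = sensors
        self.window_s = window_s
        self.min_points = min_points
        self.mode = mode
        self.normalize = normalize

    def _window_samples(self, sampling_period_s: float) -> int:
        w = int(round(self.window_s / sampling_period_s))
        if w < self.min_points:
            raise ValueError(
                f"window of {self.window_s} s holds {w} samples; "
                f"need at least {self.min_points}"
            )
        return w

    def fit(self, X, y=None):
        return self

    def transform(self, X, sampling_period_s: float | None = None) -> np.ndarray:
        H = _humidity_matrix(X, self.sensors)
        period = _period(X, sampling_period_s)
        w = self._window_samples(period)
        if self.mode == "sliding":
            vals = _sliding_std_sum(H, w)
        elif self.mode == "tiled":
            n_windows = H.shape[0] // w
            if n_windows == 0:
                raise ValueError("session shorter than one window")
            trimmed = H[: n_windows * w].reshape(n_windows, w, H.shape[1])
            vals = trimmed.std(axis=1, ddof=0).sum(axis=1)
        else:
            raise ValueError("mode must be 'sliding' or 'tiled'")
        vals, _ = _maybe_normalize(vals, self.normalize)
        return vals


def _sliding_std_sum(H: np.ndarray, w: int) -> np.ndarray:
    """Trailing-window population std summed over sensors, partial start."""
    n = H.shape[0]
    out = np.empty(n)
    head = min(w - 1, n)
    for i in range(head):  # partial windows
        out[i] = H[: i + 1].std(axis=0, ddof=0).sum()
    if n >= w:
        win = sliding_window_view(H, w, axis=0)  # (n-w+1, sensors, w)
        out[w - 1 :] = win.std(axis=-1, ddof=0).sum(axis=1)
    return out


def _humidity_matrix(X, sensors) -> np.ndarray:
    if isinstance(X, SleepSession):
        H = X.humidity
    else:
        H = np.asarray(X, dtype=float)
        if H.ndim == 1:
            H = H[:, None]
    if sensors is not None:
        idx = np.asarray(list(sensors), dtype=int)
        if idx.size == 0:
            raise ValueError("empty sensor set")
        H = H[:, idx - 1]  # sensors are 1-based, as printed on the pillow
    return H


def _period(X, sampling_period_s) -> float:
    if sampling_period_s is not None:
        return float(sampling_period_s)
    if isinstance(X, SleepSession):
        return X.sampling_period_s
    return 10.0


def squared_change_sum(
    session: SleepSession, sensors=None, normalize: bool = True
) -> FluxSeries:
    """Squared-change flux of a session (thin wrapper)."""
    vals = SquaredChangeFlux(sensors, normalize).transform(session)
    return FluxSeries(
        values=vals,
        kind="squared_change_sum",
        window_s=session.sampling_period_s,
        sampling_period_s=session.sampling_period_s,
        normalized=normalize and vals.max() == 1.0,
        window_samples=1,
        timestamps=session.timestamps,
    )


def windowed_std_flux(
    session: SleepSession,
    sensors=None,
    window_s: float = 60.0,
    min_points: int = 6,
    mode: str = "sliding",
    normalize: bool = True,
) -> FluxSeries:
    """Std-sum flux of a session (thin wrapper)."""
    est = WindowedStdFlux(sensors, window_s, min_points, mode, normalize)
    vals = est.transform(session)
    w = est._window_samples(session.sampling_period_s)
    if mode == "sliding":
        ts = session.timestamps
    else:
        ts = session.timestamps[w - 1 :: w][: len(vals)]
    return FluxSeries(
        values=vals,
        kind="std_sum",
        window_s=window_s,
        sampling_period_s=session.sampling_period_s,
        normalized=normalize and (len(vals) == 0 or vals.max() == 1.0),
        window_samples=w,
        timestamps=ts,
    )


def threshold_flags(flux: FluxSeries, threshold: float):
    """Indices above threshold, plus contiguous runs merged into events.

    Returns ``(flagged_indices, events)`` where each event records the run's
    start, peak (argmax within the run) and inclusive end index.
    """
    if flux.normalized and not 0 <= threshold <= 1:
        warnings.warn(
            f"threshold {threshold} outside [0, 1] on a normalized series",
            stacklevel=2,
        )
    above = flux.values > threshold
    flagged = np.nonzero(above)[0]
    events: list[FluxEvent] = []
    if flagged.size:
        breaks = np.nonzero(np.diff(flagged) > 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [flagged.size - 1]])
        for s, e in zip(starts, ends):
            run = flagged[s : e + 1]
            peak = run[np.argmax(flux.values[run])]
            events.append(FluxEvent(int(run[0]), int(peak), int(run[-1])))
    return flagged, events
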