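"""Smoothing, normalization and per-sensor error/summary statistics.

Raw humidity channels are noisy at the DHT22 level; a short moving average
suppresses sensor noise while keeping the abrupt level shifts that mark a
posture change. Normalization to [0, 1] puts every channel (and the flux
statistic downstream) on one scale so thresholds and segmentation penalties
are comparable across sensors and subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import SleepSession

__all__ = [
    "SmoothingConfig",
    "SmoothedSeries",
    "RollingSmoother",
    "rolling_smooth",
    "min_max_normalize",
    "error_stats",
    "channel_summary",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Moving-average window, expressed in seconds of signal.

    The window length in samples is ``max(1, round(window_s / period))``; at
    the collector's 10 s transmission period the nominal 10 s window is a
    single sample (identity), so longer windows must be configured
    explicitly when smoothing is wanted.
    """

    window_s: float = 10.0
    alignment: str = "trailing"

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.alignment not in ("trailing", "centered"):
            raise ValueError("alignment must be 'trailing' or 'centered'")

    def window_samples(self, sampling_period_s: float) -> int:
        return max(1, int(round(self.window_s / sampling_period_s)))


@dataclass
class SmoothedSeries:
    values: np.ndarray
    source: str
    config: SmoothingConfig


class RollingSmoother(TransformerMixin, BaseEstimator):
    """Moving-average smoother for one or many channels.

    Leading positions with fewer than ``window`` available samples use the
    mean of the partial window, so output length equals input length and
    the first flux values downstream remain defined.
    """

    def __init__(
        self,
        window_s: float = 10.0,
        sampling_period_s: float = 10.0,
        alignment: str = "trailing",
    ):
        self.window_s = window_s
        self.sampling_period_s = sampling_period_s
        self.alignment = alignment

    def fit(self, X, y=None):
        SmoothingConfig(self.window_s, self.alignment)  # validates
        self.window_samples_ = SmoothingConfig(
            self.window_s, self.alignment
        ).window_samples(self.sampling_period_s)
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot smooth an empty series")
        squeeze = X.ndim == 1
        frame = pd.DataFrame(X.reshape(len(X), -1))
        roll = frame.rolling(
            self.window_samples_,
            min_periods=1,
            center=(self.alignment == "centered"),
        ).mean()
        out = roll.to_numpy()
        return out[:, 0] if squeeze else out


def rolling_smooth(
    series,
    config: SmoothingConfig = SmoothingConfig(),
    sampling_period_s: float = 10.0,
    source: str = "",
) -> SmoothedSeries:
    """Moving average of one channel (thin wrapper over RollingSmoother)."""
    values = RollingSmoother(
        config.window_s, sampling_period_s, config.alignment
    ).transform(np.asarray(series, dtype=float))
    return SmoothedSeries(values=values, source=source, config=config)


def min_max_normalize(series) -> np.ndarray:
    """Affine map of a series onto [0, 1]; rejects constant input."""
    x = np.asarray(series, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant series: min-max scale undefined")
    return (x - lo) / (hi - lo)


def error_stats(per_sensor_values):
    """Mean, absolute error and relative error (%) across sensors.

    At one timestamp, the absolute error of sensor k is its deviation from
    the cross-sensor mean, and the relative error expresses that deviation
    as a percentage of the mean.
    """
    x = np.asarray(per_sensor_values, dtype=float)
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean: relative error undefined")
    ae = np.abs(x - mean)
    re = ae / mean * 100.0
    return mean, ae, re


def channel_summary(session: SleepSession) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) per humidity channel."""
    if session.n_samples == 0:
        raise ValueError("empty session")
    q = np.percentile(session.humidity, [0, 25, 50, 75, 100], axis=0)
    return pd.DataFrame(
        q.T,
        columns=["min", "q1", "median", "q3", "max"],
        index=[f"H{k}" for k in range(1, session.humidity.shape[1] + 1)],
    )
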