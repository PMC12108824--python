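import numpy as np
import pytest

from pillowflux.simulate import (
    PostureSchedule,
    SensorArrayConfig,
    SleepSession,
    simulate_session,
)


@pytest.fixture(scope="session")
def default_config():
    return SensorArrayConfig()


@pytest.fixture(scope="session")
def short_schedule():
    """One hour, two posture changes, 10-min dwells."""
    return PostureSchedule(
        [(0.0, "left"), (1200.0, "supine"), (2400.0, "right")], 3600.0
    )


@pytest.fixture(scope="session")
def short_session(default_config, short_schedule):
    return simulate_session(default_config, short_schedule, seed=7)


@pytest.fixture(scope="session")
def noise_free_session(short_schedule):
    cfg = SensorArrayConfig(noise_sd_rh=0.0)
    return simulate_session(cfg, short_schedule, seed=7)


def make_session(humidity, dt=10.0, truth=None):
    """Wrap a raw humidity matrix in a SleepSession (constant temperature)."""
    humidity = np.asarray(humidity, dtype=float)
    n, k = humidity.shape
    cfg = SensorArrayConfig(n_sensors=max(k, 2), sampling_period_s=dt, ambient_channels=0)
    return SleepSession(
        timestamps=np.arange(n) * dt,
        humidity=humidity,
        temperature=np.full((n, k), 33.0),
        ambient=np.zeros((n, 0, 2)),
        config=cfg,
        truth=truth,
    )
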