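import numpy as np
import pytest

from pillowflux.simulate import (
    PostureSchedule,
    SensorArrayConfig,
    contact_levels,
    random_schedule,
    simulate_session,
)


class TestScheduleValidation:
    def test_first_segment_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at time 0"):
            PostureSchedule([(10.0, "left")], 100.0)

    def test_consecutive_postures_must_differ(self):
        with pytest.raises(ValueError, match="different postures"):
            PostureSchedule([(0.0, "left"), (50.0, "left")], 100.0)

    def test_start_times_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            PostureSchedule([(0.0, "left"), (50.0, "supine"), (50.0, "right")], 100.0)

    def test_schedule_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="beyond the session duration"):
            PostureSchedule([(0.0, "left"), (200.0, "supine")], 100.0)

    def test_unknown_posture_rejected(self):
        with pytest.raises(ValueError, match="unknown posture"):
            PostureSchedule([(0.0, "prone")], 100.0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sensors": 1},
            {"sampling_period_s": 0},
            {"noise_sd_rh": -0.1},
            {"time_constant_s": 0.0},
            {"time_constant_s": -5.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SensorArrayConfig(**kwargs)


class TestSimulation:
    def test_seeded_determinism(self, default_config, short_schedule):
        a = simulate_session(default_config, short_schedule, seed=3)
        b = simulate_session(default_config, short_schedule, seed=3)
        assert np.array_equal(a.humidity, b.humidity)
        assert np.array_equal(a.temperature, b.temperature)
        assert np.array_equal(a.ambient, b.ambient)

    def test_different_seeds_differ(self, default_config, short_schedule):
        a = simulate_session(default_config, short_schedule, seed=3)
        b = simulate_session(default_config, short_schedule, seed=4)
        assert not np.array_equal(a.humidity, b.humidity)

    def test_humidity_bounded_even_at_high_noise(self, short_schedule):
        cfg = SensorArrayConfig(noise_sd_rh=30.0)
        s = simulate_session(cfg, short_schedule, seed=0)
        assert s.humidity.min() >= 0.0 and s.humidity.max() <= 100.0

    def test_single_posture_noise_free_is_steady(self):
        """A single supine segment starts in steady state: channels sit at
        their posture-specific levels and there is nothing to detect."""
        cfg = SensorArrayConfig(noise_sd_rh=0.0)
        sched = PostureSchedule([(0.0, "supine")], 3600.0)
        s = simulate_session(cfg, sched, seed=0)
        levels = contact_levels(cfg)["supine"]
        assert np.allclose(s.humidity, levels[None, :])

    def test_end_sensors_move_oppositely_on_left_to_right_turn(self):
        """After a left->right turn the leftmost sensor dries (humidity
        strictly falls) while the rightmost wets (strictly rises)."""
        cfg = SensorArrayConfig(noise_sd_rh=0.0)
        sched = PostureSchedule([(0.0, "left"), (3600.0, "right")], 2 * 3600.0)
        s = simulate_session(cfg, sched, seed=0)
        window = (s.timestamps > 3600.0) & (s.timestamps <= 3600.0 + 600.0)
        h1 = s.humidity[window, 0]
        h7 = s.humidity[window, -1]
        assert np.all(np.diff(h1) < 0)
        assert np.all(np.diff(h7) > 0)

    def test_every_transition_shifts_some_sensor_level(self):
        """Noise-free detectability: each true transition changes the mean
        level of at least one channel."""
        cfg = SensorArrayConfig(noise_sd_rh=0.0)
        rng = np.random.default_rng(11)
        for _ in range(5):
            sched = random_schedule(7200.0, (2, 4), 600.0, seed=rng)
            s = simulate_session(cfg, sched, seed=1)
            for t in sched.transition_times:
                before = (s.timestamps >= t - 300) & (s.timestamps < t)
                after = (s.timestamps >= t + 300) & (s.timestamps < t + 600)
                delta = np.abs(
                    s.humidity[after].mean(axis=0) - s.humidity[before].mean(axis=0)
                )
                assert delta.max() > 1.0

    def test_temperature_varies_far_less_than_humidity(self, short_session):
        """Temperature drifts slowly; humidity swings with posture."""
        t_range = np.ptp(short_session.temperature, axis=0).max()
        h_range = np.ptp(short_session.humidity, axis=0).max()
        assert t_range < 1.0 < h_range

    def test_truth_attached(self, short_session, short_schedule):
        assert short_session.truth is short_schedule


class TestRandomSchedule:
    def test_transition_count_and_min_gap(self):
        sched = random_schedule(4 * 3600.0, (6, 20), 600.0, seed=2)
        times = np.concatenate([[0.0], sched.transition_times, [sched.duration_s]])
        assert 6 <= len(sched.transition_times) <= 20
        assert np.diff(times).min() >= 600.0 - 10.0  # grid snapping slack

    def test_infeasible_count_rejected(self):
        with pytest.raises(ValueError, match="duration too short"):
            random_schedule(3600.0, 20, 600.0, seed=0)

    def test_deterministic_given_seed(self):
        a = random_schedule(seed=9)
        b = random_schedule(seed=9)
        assert a.segments == b.segments
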