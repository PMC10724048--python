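"""Generator tests: task-geometry timing, 1/f background, effect injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from gaitersp.config import ConfigurationError, SimulationConfig
from gaitersp.simulate import (inject_effects, sample_trial_timing, simulate_cohort,
                               simulate_subject, synthesize_background)
from tests.conftest import tiny_config


def narrow_speed_config(**overrides):
    """All speeds pinned to ~1.0 m/s so event intervals are predictable."""
    speed = {g: {c: (1.0, 1e-6) for c in ("no_adjustment", "preset", "online")}
             for g in ("PD", "NC")}
    return tiny_config(speed=speed, **overrides)


class TestTrialTiming:
    def test_preset_crossing_interval_is_obstacle_distance(self, rng):
        # obstacle fixed 2.5 m beyond the laser beam
        timing = sample_trial_timing(narrow_speed_config(), "NC", "preset", rng)
        ev = timing.events
        assert ev["crossing"] - ev["approach"] == pytest.approx(2.5, abs=1e-4)
        assert timing.obstacle_distance == 2.5

    def test_online_crossing_interval_from_either_distance(self, rng):
        cfg = narrow_speed_config()
        intervals = set()
        for _ in range(40):
            t = sample_trial_timing(cfg, "NC", "online", rng)
            intervals.add(round(t.events["crossing"] - t.events["approach"], 3))
        assert intervals == {1.6, 3.1}

    def test_full_path_duration(self, rng):
        timing = sample_trial_timing(narrow_speed_config(), "PD", "no_adjustment", rng)
        ev = timing.events
        assert ev["stop"] - ev["start"] == pytest.approx(6.0, abs=1e-4)
        assert "crossing" not in ev

    def test_intervals_consistent_with_sampled_speed(self, rng):
        cfg = tiny_config()
        for cond in ("preset", "online"):
            t = sample_trial_timing(cfg, "PD", cond, rng)
            d = t.obstacle_distance
            assert t.events["crossing"] - t.events["approach"] == pytest.approx(
                d / t.speed, abs=1e-12)
            assert t.events["stop"] == pytest.approx(6.0 / t.speed, abs=1e-12)

    def test_speed_truncated_at_floor(self, rng):
        speed = {g: {c: (0.35, 0.2) for c in ("no_adjustment", "preset", "online")}
                 for g in ("PD", "NC")}
        cfg = tiny_config(speed=speed)
        draws = [sample_trial_timing(cfg, "PD", "preset", rng).speed for _ in range(500)]
        assert min(draws) >= cfg.speed_floor

    def test_sampled_speed_mean_recovers_configured_mean(self, rng):
        speed = {g: {c: (1.0, 0.1) for c in ("no_adjustment", "preset", "online")}
                 for g in ("PD", "NC")}
        cfg = tiny_config(speed=speed)
        n = 2000
        draws = np.array([sample_trial_timing(cfg, "NC", "preset", rng).speed
                          for _ in range(n)])
        se = 0.1 / np.sqrt(n)
        assert abs(draws.mean() - 1.0) < 2 * se + 1e-4  # truncation shift is ~1e-20 here

    def test_invalid_condition_and_missing_speed_raise(self, rng):
        cfg = tiny_config()
        with pytest.raises(ConfigurationError):
            sample_trial_timing(cfg, "PD", "sideways", rng)

    def test_nonpositive_speed_parameters_rejected(self):
        speed = {g: {c: (0.0, 0.1) for c in ("no_adjustment", "preset", "online")}
                 for g in ("PD", "NC")}
        with pytest.raises(ConfigurationError):
            tiny_config(speed=speed)


class TestBackground:
    @staticmethod
    def fitted_slope(x, fs):
        f, pxx = sps.welch(x, fs=fs, nperseg=4 * int(fs))
        sel = (f >= 1.0) & (f <= 40.0)
        return np.polyfit(np.log10(f[sel]), np.log10(pxx[:, sel].mean(axis=0)), 1)[0]

    def test_white_noise_has_flat_psd(self, rng):
        x = synthesize_background(4, 70 * 250, 250.0, exponent=0.0, scale=10.0, rng=rng)
        assert abs(self.fitted_slope(x, 250.0)) < 0.1

    def test_pink_noise_slope_near_minus_one(self, rng):
        x = synthesize_background(4, 70 * 250, 250.0, exponent=1.0, scale=10.0, rng=rng)
        assert abs(self.fitted_slope(x, 250.0) + 1.0) < 0.15

    def test_zero_scale_gives_exact_zeros(self, rng):
        x = synthesize_background(3, 1000, 128.0, exponent=1.0, scale=0.0, rng=rng)
        assert (x == 0).all()

    def test_rms_matches_scale(self, rng):
        x = synthesize_background(3, 60 * 128, 128.0, exponent=1.0, scale=7.5, rng=rng)
        assert x.std(axis=1) == pytest.approx([7.5] * 3, rel=1e-6)

    def test_negative_exponent_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            synthesize_background(1, 1000, 128.0, exponent=-0.5, scale=1.0, rng=rng)


def _one_trial_events(cfg, condition, rng, start=10.0):
    timing = sample_trial_timing(cfg, "NC", condition, rng)
    rows = [{"subject_id": "NC01", "group": "NC", "trial_id": 0, "block": 1,
             "condition": condition, "event_name": k, "onset": start + v}
            for k, v in timing.events.items()]
    return pd.DataFrame(rows), timing


class TestInjectEffects:
    def test_null_configuration_is_identity(self, rng):
        cfg = tiny_config(theta_burst={"amplitude": 0.0}, beta_suppression=0.0,
                          beta_rebound=0.0, theta_resetting=0.0,
                          gait_artifact_amplitude=0.0)
        events, _ = _one_trial_events(cfg, "online", rng)
        sig = rng.standard_normal((cfg.n_channels, int(30 * cfg.sampling_rate)))
        out = inject_effects(sig, events, "PD", cfg, rng)
        assert np.array_equal(out, sig)

    @staticmethod
    def _band_var(sig, fs, band, t0, t1):
        sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, sig, axis=1)
        return x[:, int(t0 * fs):int(t1 * fs)].var()

    def test_theta_burst_raises_band_variance_by_predicted_ratio(self, rng):
        cfg = tiny_config(beta_suppression=0.0, beta_rebound=0.0, theta_resetting=0.0,
                          gait_artifact_amplitude=0.0)
        A, dur = cfg.theta_burst.amplitude, cfg.theta_burst.duration_s
        fs = cfg.sampling_rate
        v_burst, v_pre = [], []
        for _ in range(50):
            events, timing = _one_trial_events(cfg, "online", rng)
            approach = float(events.loc[events.event_name == "approach", "onset"].iloc[0])
            sig = synthesize_background(3, int(40 * fs), fs, 1.0, 15.0, rng)
            out = inject_effects(sig, events, "NC", cfg, rng)
            v_burst.append(self._band_var(out, fs, (4, 7), approach, approach + dur))
            v_pre.append(self._band_var(out, fs, (4, 7), approach - dur - 1.0,
                                        approach - 1.0))
        # Hann-windowed sinusoid adds A^2 * E[hann^2] * E[sin^2] = 0.1875 A^2
        expected = 1.0 + 0.1875 * A**2 / np.mean(v_pre)
        assert np.mean(v_burst) / np.mean(v_pre) == pytest.approx(expected, rel=0.15)

    def test_beta_rebound_variance_ratio_matches_gain(self, rng):
        cfg = tiny_config(theta_burst={"amplitude": 0.0}, beta_suppression=0.0,
                          theta_resetting=0.0, gait_artifact_amplitude=0.0,
                          beta_rebound=0.4)
        fs = cfg.sampling_rate
        post, pre = [], []
        for _ in range(50):
            events, _ = _one_trial_events(cfg, "preset", rng)
            crossing = float(events.loc[events.event_name == "crossing", "onset"].iloc[0])
            sig = synthesize_background(3, int(40 * fs), fs, 1.0, 15.0, rng)
            out = inject_effects(sig, events, "NC", cfg, rng)
            post.append(self._band_var(out, fs, (13, 35), crossing, crossing + 0.6))
            pre.append(self._band_var(out, fs, (13, 35), crossing - 0.7, crossing - 0.1))
        assert np.mean(post) / np.mean(pre) == pytest.approx(1.4**2, rel=0.10)

    def test_pd_attenuation_scales_theta_burst(self, rng):
        cfg = tiny_config(beta_suppression=0.0, beta_rebound=0.0, theta_resetting=0.0,
                          gait_artifact_amplitude=0.0, noise_scale=0.0,
                          attenuation={"theta_burst": 0.5})
        events, _ = _one_trial_events(cfg, "online", rng)
        n = int(40 * cfg.sampling_rate)
        nc = inject_effects(np.zeros((cfg.n_channels, n)), events, "NC", cfg,
                            np.random.default_rng(3))
        pd_ = inject_effects(np.zeros((cfg.n_channels, n)), events, "PD", cfg,
                             np.random.default_rng(3))
        assert np.abs(pd_).max() == pytest.approx(0.5 * np.abs(nc).max(), rel=1e-9)

    def test_obstacle_trial_without_crossing_rejected(self, rng):
        cfg = tiny_config()
        events, _ = _one_trial_events(cfg, "preset", rng)
        events = events[events.event_name != "crossing"]
        sig = rng.standard_normal((cfg.n_channels, int(30 * cfg.sampling_rate)))
        with pytest.raises(ValueError, match="crossing"):
            inject_effects(sig, events, "NC", cfg, rng)

    def test_effect_interval_outside_recording_names_trial(self, rng):
        cfg = tiny_config()
        events, _ = _one_trial_events(cfg, "preset", rng, start=1.0)
        sig = rng.standard_normal((cfg.n_channels, int(3 * cfg.sampling_rate)))
        with pytest.raises(ValueError, match="trial 0"):
            inject_effects(sig, events, "NC", cfg, rng)


class TestCohort:
    def test_same_seed_reproduces_bytes(self):
        a = simulate_cohort(tiny_config(seed=123))
        b = simulate_cohort(tiny_config(seed=123))
        pd.testing.assert_frame_equal(a.events, b.events)
        for sa, sb in zip(a.sessions, b.sessions):
            assert np.array_equal(sa.signal, sb.signal)

    def test_different_seed_differs(self):
        a = simulate_cohort(tiny_config(seed=1))
        b = simulate_cohort(tiny_config(seed=2))
        assert not np.array_equal(a.sessions[0].signal, b.sessions[0].signal)

    def test_event_order_within_every_trial(self, tiny_cohort):
        order = {"start": 0, "approach": 1, "crossing": 2, "stop": 3}
        for (_, _), trial in tiny_cohort.events.groupby(["subject_id", "trial_id"]):
            t = trial.sort_values("onset")
            ranks = [order[e] for e in t.event_name]
            assert ranks == sorted(ranks)
            assert t["onset"].is_monotonic_increasing

    def test_no_adjustment_trials_lack_crossing(self, tiny_cohort):
        free = tiny_cohort.events[tiny_cohort.events.condition == "no_adjustment"]
        assert "crossing" not in set(free.event_name)

    def test_trial_count_and_blocks(self):
        session, events = simulate_subject(
            tiny_config(n_trials=160, n_blocks=4), "NC", "NC01",
            np.random.SeedSequence(5))
        assert events["trial_id"].nunique() == 160
        assert sorted(events["block"].unique()) == [1, 2, 3, 4]
        counts = events.drop_duplicates("trial_id")["condition"].value_counts()
        assert counts.max() - counts.min() <= 1  # near-equal allocation

    def test_inter_trial_gap_at_least_two_seconds(self, tiny_cohort):
        ev = tiny_cohort.events
        for _, sub in ev.groupby("subject_id"):
            stops = sub[sub.event_name == "stop"].sort_values("trial_id")["onset"].to_numpy()
            starts = sub[sub.event_name == "start"].sort_values("trial_id")["onset"].to_numpy()
            assert (starts[1:] - stops[:-1] >= 2.0 - 1e-9).all()
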