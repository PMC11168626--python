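"""Filtering, differentiation, movement segmentation, metrics, outliers."""

import numpy as np
import pandas as pd
import pytest

from reachvigor import synthetic as syn
from reachvigor.kinematics import (
    Trajectory,
    detect_onset_offset,
    differentiate,
    filter_outliers,
    fivepoint_derivative,
    lowpass_filter,
    radial_velocity,
    trial_metrics,
    trials_to_frame,
)

FS = 200.0


def _traj(x, y, onset=0.0):
    t = np.arange(len(x)) / FS
    return Trajectory(time=t, x=np.asarray(x, float), y=np.asarray(y, float),
                      target_onset=onset)


def _sine_traj(freq, n=1000, amp=0.01):
    t = np.arange(n) / FS
    return _traj(amp * np.sin(2 * np.pi * freq * t), np.zeros(n))


def _minjerk_traj(duration, direction_deg=45.0, start_time=0.5, dist=0.10,
                  hold=0.5, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    th = np.radians(direction_deg)
    n_pre = int(round(start_time * FS))
    _, mx, my = syn.minimum_jerk((0, 0), (dist * np.cos(th), dist * np.sin(th)),
                                 duration, FS)
    n_post = int(round(hold * FS))
    x = np.concatenate([np.zeros(n_pre), mx, np.full(n_post, mx[-1])])
    y = np.concatenate([np.zeros(n_pre), my, np.full(n_post, my[-1])])
    if noise_sd:
        x = x + rng.normal(0, noise_sd, len(x))
        y = y + rng.normal(0, noise_sd, len(y))
    return _traj(x, y, onset=0.2)


class TestFilter:
    def test_constant_trace_unchanged(self):
        traj = _traj(np.full(400, 0.03), np.full(400, -0.01))
        f = lowpass_filter(traj)
        assert np.allclose(f.x, 0.03, atol=1e-12)
        assert np.allclose(f.y, -0.01, atol=1e-12)

    def test_passband_and_stopband(self):
        slow = lowpass_filter(_sine_traj(1.0))
        fast = lowpass_filter(_sine_traj(50.0))
        # compare away from the edges
        sl = slice(200, 800)
        assert np.max(np.abs(slow.x[sl])) > 0.99 * 0.01   # <1 % attenuation
        assert np.max(np.abs(fast.x[sl])) < 0.01 * 0.01   # >99 % attenuation

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            lowpass_filter(_traj(np.zeros(10), np.zeros(10)))


class TestDifferentiate:
    def test_linear_ramp_exact(self):
        t = np.arange(100) / FS
        d = fivepoint_derivative(0.37 * t, 1 / FS)
        assert np.allclose(d, 0.37, atol=1e-10)

    def test_quartic_exact_in_interior(self):
        t = np.arange(100) / FS
        y = t**4 - 2 * t**3 + 0.5 * t**2
        expected = 4 * t**3 - 6 * t**2 + t
        d = fivepoint_derivative(y, 1 / FS)
        assert np.allclose(d, expected, atol=1e-9)

    def test_sinusoid_truncation_error_bound(self):
        w = 2 * np.pi * 2.0
        t = np.arange(400) / FS
        d = fivepoint_derivative(np.sin(w * t), 1 / FS)
        err = np.max(np.abs(d - w * np.cos(w * t)))
        assert err < (1 / FS) ** 4 * w**5  # O(h^4) truncation

    def test_second_order_is_repeated_first(self):
        t = np.arange(50) / FS
        y = np.sin(3 * t)
        assert np.allclose(
            differentiate(y, 1 / FS, order=2),
            fivepoint_derivative(fivepoint_derivative(y, 1 / FS), 1 / FS),
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fivepoint_derivative(np.zeros(4), 1 / FS)


class TestRadialVelocity:
    def test_pure_radial_reach_equals_speed(self):
        traj = _minjerk_traj(0.8)
        rv = radial_velocity(traj, (0.0, 0.0))
        vx = fivepoint_derivative(traj.x, traj.dt)
        vy = fivepoint_derivative(traj.y, traj.dt)
        speed = np.hypot(vx, vy)
        sl = slice(110, 250)  # inside the outward movement
        assert np.allclose(rv[sl], speed[sl], atol=1e-9)

    def test_circular_motion_is_zero(self):
        t = np.arange(400) / FS
        traj = _traj(0.05 * np.cos(t), 0.05 * np.sin(t))
        rv = radial_velocity(traj, (0.0, 0.0))
        assert np.max(np.abs(rv)) < 1e-9

    def test_matches_numeric_distance_derivative(self):
        traj = _minjerk_traj(0.7, direction_deg=135.0)
        home = (0.01, -0.02)
        rv = radial_velocity(traj, home)
        dist = np.hypot(traj.x - home[0], traj.y - home[1])
        assert np.allclose(rv, fivepoint_derivative(dist, traj.dt), atol=1e-12)


class TestOnsetOffset:
    def test_stationary_trace_raises(self):
        traj = _traj(np.zeros(400), np.zeros(400))
        with pytest.raises(ValueError, match="no movement"):
            detect_onset_offset(traj)

    @pytest.mark.parametrize("duration", [0.3, 0.7, 1.2])
    @pytest.mark.parametrize("direction", [45.0, 225.0])
    def test_minjerk_onset_offset_within_25ms(self, duration, direction):
        start = 0.5
        traj = _minjerk_traj(duration, direction_deg=direction, start_time=start)
        onset, offset = detect_onset_offset(traj)
        assert abs(traj.time[onset] - start) <= 0.025
        assert abs(traj.time[offset] - (start + duration)) <= 0.025

    def test_duration_robust_to_measurement_noise(self):
        # encoder-level position noise; larger noise lifts the filtered
        # acceleration variability above the published settle threshold
        clean = _minjerk_traj(0.8)
        on0, off0 = detect_onset_offset(lowpass_filter(clean))
        noisy = _minjerk_traj(0.8, noise_sd=1e-5, seed=3)
        on1, off1 = detect_onset_offset(lowpass_filter(noisy))
        assert abs((off1 - on1) - (off0 - on0)) <= 4  # within 20 ms

    def test_onset_before_peak_offset_after(self):
        traj = _minjerk_traj(0.6)
        onset, offset = detect_onset_offset(traj)
        vx = fivepoint_derivative(traj.x, traj.dt)
        vy = fivepoint_derivative(traj.y, traj.dt)
        peak = int(np.argmax(np.hypot(vx, vy)))
        assert onset < peak < offset


class TestTrialMetrics:
    def test_ideal_reach_has_zero_errors(self):
        traj = _minjerk_traj(0.8, direction_deg=45.0)
        m = trial_metrics(traj, (0, 0), 45.0)
        assert m.endpoint_error_m < 1e-3
        assert abs(m.angular_error_deg) < 0.5
        assert m.t_r_s == pytest.approx(0.3, abs=0.025)
        assert m.peak_vel_mps == pytest.approx(1.875 * 0.10 / 0.8, rel=0.02)

    def test_offaxis_endpoint_angular_error(self):
        # endpoint at 10 cm, 3 degrees counterclockwise of the 45-degree ray
        traj = _minjerk_traj(0.8, direction_deg=48.0)
        m = trial_metrics(traj, (0, 0), 45.0)
        assert m.angular_error_deg == pytest.approx(3.0, abs=0.3)

    def test_experiment4_duration_to_max_excursion(self):
        traj = _minjerk_traj(0.8, direction_deg=45.0)
        m4 = trial_metrics(traj, (0, 0), 45.0, experiment=4)
        m2 = trial_metrics(traj, (0, 0), 45.0, experiment=2)
        assert m4.t_m_s <= m2.t_m_s
        assert m4.max_excursion_m == pytest.approx(0.10, abs=1e-3)

    def test_batch_durations_match_generator(self):
        durations = (0.3, 0.6, 0.9, 1.2)
        rows = []
        for d in durations:
            for direction in (45.0, 135.0, 225.0, 315.0):
                traj = _minjerk_traj(d, direction_deg=direction)
                rows.append(trial_metrics(traj, (0, 0), direction))
        df = trials_to_frame(rows)
        for d, grp in df.groupby(np.repeat(durations, 4)):
            # onset/offset share the ground truth within the 25 ms tolerance
            # of the variability-threshold segmentation
            assert np.allclose(grp["t_m_s"], d, atol=0.05)


class TestOutliers:
    def _clean_frame(self, n=40):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "subject_id": 0,
                "added_mass_kg": 0.0,
                "experiment": 2,
                "t_m_s": rng.normal(0.8, 0.03, n),
                "t_r_s": rng.normal(0.18, 0.01, n),
                "reaction_velocity_mps": rng.normal(0.01, 0.002, n),
                "angular_error_deg": rng.normal(0, 1.5, n),
                "endpoint_error_m": rng.normal(0.005, 0.001, n),
                "max_excursion_m": rng.normal(0.104, 0.003, n),
            }
        )

    def test_exp1_short_duration_removed(self):
        df = self._clean_frame()
        df.loc[0, "t_m_s"] = 0.15
        kept, removed, log = filter_outliers(df, "exp1")
        assert 0 in removed.index
        assert "duration" in log.set_index("index").loc[0, "reason"]

    def test_exp1_rules_each_trigger(self):
        df = self._clean_frame(8)
        df.loc[1, "endpoint_error_m"] = 0.12
        df.loc[2, "t_r_s"] = 0.6
        df.loc[3, "angular_error_deg"] = -60.0
        kept, removed, _ = filter_outliers(df, "exp1")
        assert set(removed.index) == {1, 2, 3}

    def test_identical_trials_never_removed_by_iqr(self):
        df = self._clean_frame(12)
        for c in ("t_m_s", "t_r_s", "reaction_velocity_mps", "angular_error_deg"):
            df[c] = df[c].iloc[0]
        kept, removed, _ = filter_outliers(df, "exp234")
        assert removed.empty

    def test_planted_gross_outliers_caught(self):
        rng = np.random.default_rng(7)
        frames = []
        for s in range(4):
            f = self._clean_frame(200)
            f["subject_id"] = s
            frames.append(f)
        df = pd.concat(frames, ignore_index=True)
        planted = rng.choice(len(df), size=int(0.05 * len(df)), replace=False)
        df.loc[planted, "t_m_s"] = rng.uniform(3.0, 5.0, len(planted))
        kept, removed, _ = filter_outliers(df, "exp234")
        caught = np.isin(planted, removed.index).mean()
        clean_removed = (len(removed) - np.isin(planted, removed.index).sum()) / (
            len(df) - len(planted)
        )
        assert caught >= 0.95
        assert clean_removed <= 0.10

    def test_excursion_rule_only_for_stop_experiments(self):
        df = self._clean_frame(12)
        df.loc[5, "max_excursion_m"] = 0.20
        kept, removed, _ = filter_outliers(df, "exp234")
        assert 5 in removed.index
        df4 = df.copy()
        df4["experiment"] = 4
        kept4, removed4, _ = filter_outliers(df4, "exp234")
        assert 5 not in removed4.index

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            kept, removed, log = filter_outliers(pd.DataFrame(), "exp1")
        assert kept.empty and removed.empty
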