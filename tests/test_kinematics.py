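"""Filtering, event detection, steady-state selection and angle extraction."""

import numpy as np
import pytest

from gaitresp import kinematics as kin
from gaitresp.synthetic import generate_trial
from gaitresp.types import GaitError, GaitEvents, MarkerTrajectorySet, TrialRejected

from conftest import make_profile


def _single_marker_trial(arr, fs=300.0, label="sacrum"):
    return MarkerTrajectorySet("t", fs, {label: arr})


class TestInterpolateGaps:
    def test_no_gaps_is_identity(self, clean_trial):
        traj, _ = clean_trial
        out = kin.interpolate_gaps(traj)
        for label in traj.markers:
            np.testing.assert_array_equal(out.markers[label],
                                          traj.markers[label])

    def test_linear_ramp_filled_exactly(self):
        arr = np.column_stack([np.arange(100.0)] * 3)
        arr[40:43] = np.nan
        out = kin.interpolate_gaps(_single_marker_trial(arr))
        np.testing.assert_allclose(out.markers["sacrum"][:, 0],
                                   np.arange(100.0), atol=1e-12)

    def test_long_gap_rejects_trial(self):
        arr = np.column_stack([np.arange(300.0)] * 3)
        arr[100:160] = np.nan  # 0.2 s at 300 Hz
        with pytest.raises(TrialRejected):
            kin.interpolate_gaps(_single_marker_trial(arr))


class TestZeroLagLowpass:
    FS = 300.0

    def test_constant_series_unchanged(self):
        x = np.full(1000, 3.7)
        np.testing.assert_allclose(kin.zero_lag_lowpass(x, self.FS), x,
                                   atol=1e-9)

    def test_passband_sinusoid_amplitude_preserved(self):
        t = np.arange(3000) / self.FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = kin.zero_lag_lowpass(x, self.FS)
        mid = slice(500, 2500)
        assert abs(np.ptp(y[mid]) / np.ptp(x[mid]) - 1.0) < 0.01

    def test_cutoff_gain_is_squared_half_power(self):
        # forward-backward application squares the single-pass magnitude,
        # so the 6 Hz component comes through at 0.5 amplitude
        t = np.arange(6000) / self.FS
        x = np.sin(2 * np.pi * 6.0 * t)
        y = kin.zero_lag_lowpass(x, self.FS)
        mid = slice(1000, 5000)
        assert abs(np.ptp(y[mid]) / np.ptp(x[mid]) - 0.5) < 0.01

    def test_zero_phase_shift(self):
        t = np.arange(3000) / self.FS
        x = np.sin(2 * np.pi * 2.0 * t)
        y = kin.zero_lag_lowpass(x, self.FS)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[500:2500], np.roll(y, k)[500:2500]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_short_series_rejected(self):
        with pytest.raises(GaitError):
            kin.zero_lag_lowpass(np.ones(20), self.FS)

    def test_nyquist_precondition(self):
        with pytest.raises(GaitError):
            kin.zero_lag_lowpass(np.ones(1000), 10.0, cutoff=6.0)


class TestEventDetection:
    def test_noise_free_events_within_3_frames(self, clean_trial):
        traj, truth = clean_trial
        filt = kin.filter_trajectories(traj)
        ev = kin.detect_gait_events(filt)
        for side in ("left", "right"):
            for t in truth.heel_strikes[side]:
                assert np.abs(ev.heel_strikes[side] - t).min() <= 3
            for t in truth.toe_offs[side]:
                assert np.abs(ev.toe_offs[side] - t).min() <= 3

    @pytest.mark.parametrize("seed", range(12))
    def test_noisy_events_within_6_frames(self, profile, seed):
        traj, truth = generate_trial(profile, 8, noise_sd=1.0, seed=seed)
        ev = kin.detect_gait_events(kin.filter_trajectories(traj))
        for side in ("left", "right"):
            for t in truth.heel_strikes[side]:
                assert np.abs(ev.heel_strikes[side] - t).min() <= 6
            for t in truth.toe_offs[side]:
                assert np.abs(ev.toe_offs[side] - t).min() <= 6

    def test_reversed_walking_direction_same_events(self, clean_trial):
        traj, _ = clean_trial
        filt = kin.filter_trajectories(traj)
        flipped = filt.copy()
        for arr in flipped.markers.values():
            arr[:, 1] *= -1.0
        ev = kin.detect_gait_events(filt)
        ev_flip = kin.detect_gait_events(flipped)
        for side in ("left", "right"):
            np.testing.assert_array_equal(ev.heel_strikes[side],
                                          ev_flip.heel_strikes[side])
            np.testing.assert_array_equal(ev.toe_offs[side],
                                          ev_flip.toe_offs[side])

    def test_alternation_invariant_on_accepted_trials(self, profile):
        for seed in range(5):
            traj, _ = generate_trial(profile, 6, noise_sd=1.5, seed=100 + seed)
            ev = kin.detect_gait_events(kin.filter_trajectories(traj))
            ev.validate()  # raises on any ordering violation

    def test_too_few_strides_rejected(self):
        # flat trajectories produce no usable peaks
        arr = np.column_stack([np.zeros(2000)] * 3)
        markers = {m: arr.copy() for m in
                   ("sacrum", "l_heel", "r_heel", "l_toe", "r_toe")}
        markers["sacrum"][:, 1] = np.linspace(0, 4000, 2000)
        with pytest.raises(TrialRejected):
            kin.detect_gait_events(MarkerTrajectorySet("t", 300.0, markers))


class TestSteadyStateSelection:
    @staticmethod
    def _events(n_windows: int, offset=0) -> GaitEvents:
        hs = {s: np.arange(n_windows + 1) * 100 + offset + (0 if s == "left" else 50)
              for s in ("left", "right")}
        to = {s: hs[s][:-1] + 63 for s in ("left", "right")}
        return GaitEvents(hs, to)

    def test_paper_counting_twenty_windows(self):
        trials = [self._events(7) for _ in range(6)]
        retained = kin.select_steady_state(trials)
        assert len(retained) == 5  # first trial dropped
        assert sum(len(w) for w in retained.values()) == 20

    def test_central_pair_tie_broken_later(self):
        # 9 windows -> 5 usable after trimming two per end; the central pair
        # of five is items 2,3 counting from the trimmed start
        trials = [self._events(9) for _ in range(6)]
        retained = kin.select_steady_state(trials)
        windows = next(iter(retained.values()))
        lefts = [w for w in windows if w.side == "left"]
        assert [w.start for w in lefts] == [400, 500]

    def test_fewer_than_six_trials_raises(self):
        with pytest.raises(GaitError):
            kin.select_steady_state([self._events(7) for _ in range(5)])

    def test_short_trial_excluded(self):
        trials = [self._events(7) for _ in range(6)]
        trials[3] = self._events(5)  # only 1 usable window after trimming
        retained = kin.select_steady_state(trials)
        assert len(retained) == 4
        assert "trial3" not in retained


class TestAngles:
    def test_static_pose_constant_angles(self, clean_trial):
        traj, _ = clean_trial
        frozen = traj.copy()
        drift = np.linspace(0, 1000, traj.n_frames)  # rigid forward glide
        for arr in frozen.markers.values():
            arr[:] = arr[100]  # hold one posture for the whole trial
            arr[:, 1] += drift
        for joint, side in (("hip", "left"), ("knee", "right"), ("ankle", "left")):
            series = kin.joint_angle_series(frozen, joint, side)
            assert np.ptp(series.angles_deg) < 1e-6

    def test_degenerate_segment_raises(self, clean_trial):
        traj, _ = clean_trial
        broken = traj.copy()
        broken.markers["l_knee"][:] = broken.markers["l_asis"]
        with pytest.raises(GaitError):
            kin.joint_angle_series(broken, "hip", "left")

    def test_trunk_transverse_rom_matches_oscillation(self):
        profile = make_profile(trunk_rom_transverse=7.0)
        traj, truth = generate_trial(profile, 8, noise_sd=0.0, seed=3)
        series = kin.joint_angle_series(traj, "trunk", plane="transverse")
        windows = [w for tid, ws in kin.select_steady_state(
            [truth] * 6, [f"t{i}" for i in range(6)]).items() for w in ws]
        assert kin.range_of_motion(series, windows) == pytest.approx(7.0, abs=0.2)


class TestRangeOfMotion:
    def test_constant_series_zero(self):
        s = kin.JointAngleSeries("hip", "left", "sagittal", np.full(500, 12.0), 300.0)
        assert kin.range_of_motion(s) == 0.0

    def test_sinusoid_gives_twice_amplitude(self):
        t = np.linspace(0, 4 * np.pi, 2000)
        s = kin.JointAngleSeries("knee", "left", "sagittal", 7.5 * np.sin(t), 300.0)
        assert kin.range_of_motion(s) == pytest.approx(15.0, abs=1e-3)

    def test_windowed_rom_bounded_by_full(self, clean_trial):
        traj, truth = clean_trial
        series = kin.joint_angle_series(traj, "hip", "left")
        windows = kin.step_windows(truth, "left")[:2]
        assert kin.range_of_motion(series, windows) <= kin.range_of_motion(series)

    def test_filter_idempotence_on_rom(self, clean_trial):
        traj, truth = clean_trial
        once = kin.filter_trajectories(traj)
        twice = kin.filter_trajectories(once)
        w = kin.step_windows(truth, "left")[2:4]
        for t in ("hip", "knee", "ankle"):
            r1 = kin.range_of_motion(kin.joint_angle_series(once, t, "left"), w)
            r2 = kin.range_of_motion(kin.joint_angle_series(twice, t, "left"), w)
            assert abs(r1 - r2) < 0.1

    def test_empty_window_list_raises(self, clean_trial):
        traj, _ = clean_trial
        series = kin.joint_angle_series(traj, "hip", "left")
        with pytest.raises(GaitError):
            kin.range_of_motion(series, [])
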