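"""Forward models: trajectories, spike trains, photometry, avoidance."""

import numpy as np
import pytest

from incerta import DegenerateInputError
from incerta import behavior as B
from incerta import kinematics as K
from incerta import synth
from incerta import units as U


class TestTurnSchedule:
    def test_overlapping_intervals_rejected(self):
        with pytest.raises(DegenerateInputError, match="overlap"):
            synth.TurnSchedule([1.0, 1.3], [20.0, 20.0], [0.5, 0.5])

    def test_random_schedule_has_both_directions(self):
        s = synth.TurnSchedule.random(300.0, seed=0)
        assert (s.amplitudes_deg > 0).any() and (s.amplitudes_deg < 0).any()


class TestTrajectory:
    def test_empty_schedule_static_markers(self):
        sched = synth.TurnSchedule([], [], [])
        track, true_angle = synth.gen_head_trajectory(sched, duration=5.0,
                                                      noise_sd=0.0, seed=0)
        assert np.ptp(track.nose, axis=0) == pytest.approx([0.0, 0.0])
        assert np.ptp(true_angle) == 0.0

    def test_single_turn_integrates_to_amplitude(self):
        sched = synth.TurnSchedule([1.0], [15.0], [0.5])
        track, _ = synth.gen_head_trajectory(sched, duration=4.0,
                                             noise_sd=0.0, seed=0)
        ang = K.head_midline_angle(K.calibrate(track))
        assert ang[-1] - ang[0] == pytest.approx(15.0, abs=1e-9)

    def test_total_angle_invariant_to_frame_rate(self):
        sched = synth.TurnSchedule([1.0, 3.0], [30.0, -20.0], [0.5, 0.5])
        out = []
        for fps in (30.0, 100.0):
            track, _ = synth.gen_head_trajectory(sched, fps=fps, duration=6.0,
                                                 noise_sd=0.0, seed=0)
            ang = K.head_midline_angle(K.calibrate(track))
            out.append(ang[-1] - ang[0])
        assert out[0] == pytest.approx(out[1], abs=1e-9)

    def test_inter_marker_distance_constant(self):
        sched = synth.TurnSchedule.random(60.0, seed=5)
        track, _ = synth.gen_head_trajectory(sched, duration=60.0,
                                             noise_sd=1.0, seed=5)
        d = np.hypot(*(track.nose - track.ears).T)
        assert np.ptp(d) == pytest.approx(0.0, abs=1e-9)

    def test_fps_outside_tracked_range_rejected(self):
        sched = synth.TurnSchedule([], [], [])
        with pytest.raises(DegenerateInputError):
            synth.gen_head_trajectory(sched, fps=10.0, duration=5.0)

    def test_deterministic_under_seed(self):
        sched = synth.TurnSchedule.random(30.0, seed=9)
        a, _ = synth.gen_head_trajectory(sched, duration=30.0, noise_sd=2.0,
                                         seed=9)
        b, _ = synth.gen_head_trajectory(sched, duration=30.0, noise_sd=2.0,
                                         seed=9)
        assert np.array_equal(a.nose, b.nose)


class TestSpikeTrains:
    def test_homogeneous_poisson_count(self):
        # gain 0, 10 spikes/s, 100 s -> count within 3 SD of 1000
        t = np.arange(0, 100, 0.02)
        prof = synth.ClassProfile("Class1b", 10.0, 0.0)
        tr = synth.gen_spike_train(prof, t, np.zeros_like(t), seed=0)
        assert abs(len(tr) - 1000) < 3 * np.sqrt(1000)

    def test_movement_coupled_rate_correlates_with_speed(self, speed_profile,
                                                         class_profiles):
        t, speed, _ = speed_profile
        tr = synth.gen_spike_train(class_profiles["Class1b"], t, speed, seed=1)
        r, slope = U.rate_speed_correlation(tr, t, speed)
        assert r > 0.3 and slope > 0

    def test_suppressed_class_dips_during_bouts(self, speed_profile,
                                                class_profiles):
        t, speed, mask = speed_profile
        tr = synth.gen_spike_train(class_profiles["Class2a"], t, speed, seed=2)
        dt = t[1] - t[0]
        idx = np.searchsorted(t, tr.spike_times) - 1
        in_rate = np.isin(idx, np.flatnonzero(mask)).sum() / (mask.sum() * dt)
        out_rate = (~np.isin(idx, np.flatnonzero(mask))).sum() / ((~mask).sum() * dt)
        assert in_rate < out_rate

    def test_negative_speed_rejected(self, class_profiles):
        with pytest.raises(DegenerateInputError):
            synth.gen_spike_train(class_profiles["Class1a"],
                                  np.arange(3.0), np.array([0.0, -1.0, 0.0]))

    def test_coupling_gain_recovered_by_regression(self, speed_profile):
        """Empirical rate-vs-speed slope recovers the generator's
        coupling within 10% at 600 s (oracle: the latent linear rate)."""
        t, speed, _ = synth.gen_speed_profile(600.0, seed=13)
        prof = synth.ClassProfile("Class1b", 8.0, 1.5)
        rel_err = []
        for seed in range(5):
            tr = synth.gen_spike_train(prof, t, speed, seed=seed)
            _, slope = U.rate_speed_correlation(tr, t, speed)
            rel_err.append(abs(slope - prof.coupling_gain) / prof.coupling_gain)
        assert np.median(rel_err) < 0.10

    def test_deterministic_under_seed(self, speed_profile, class_profiles):
        t, speed, _ = speed_profile
        a = synth.gen_spike_train(class_profiles["Class1a"], t, speed, seed=3)
        b = synth.gen_spike_train(class_profiles["Class1a"], t, speed, seed=3)
        assert np.array_equal(a.spike_times, b.spike_times)


class TestPhotometryGen:
    def test_zero_activity_channels_affine_related(self):
        t = np.arange(0, 60, 0.01)
        truth = synth.make_photometry_truth(t, np.zeros_like(t),
                                            artifact_amp=0.1, seed=0)
        raw = synth.gen_photometry(truth, seed=0, noise_sd=1e-4)
        r = np.corrcoef(raw.f_signal, raw.f_control)[0, 1]
        assert r > 0.999

    def test_kernel_delay_appears_in_cross_correlation(self):
        t, speed, _ = synth.gen_speed_profile(120.0, seed=1)
        truth = synth.make_photometry_truth(t, speed, kernel_delay=0.3,
                                            artifact_amp=0.0, seed=1)
        drive = np.interp(truth.t, t, speed)
        a = truth.activity - truth.activity.mean()
        d = drive - drive.mean()
        lags = np.arange(0, 100)            # 0..1 s at 100 Hz
        cc = [np.dot(a[k:], d[:len(d) - k] if k else d) for k in lags]
        # activity must lag the drive by at least the kernel onset delay
        assert lags[int(np.argmax(cc))] / 100.0 >= 0.3

    def test_zero_artifact_control_channel_is_baseline_plus_noise(self):
        t = np.arange(0, 30, 0.01)
        truth = synth.make_photometry_truth(t, np.zeros_like(t),
                                            artifact_amp=0.0, seed=2)
        raw = synth.gen_photometry(truth, seed=2, baseline=100.0,
                                   noise_sd=0.2)
        g2 = truth.channel_gains[1]
        assert raw.f_control.mean() == pytest.approx(100.0 * g2, rel=1e-3)
        assert raw.f_control.std() == pytest.approx(0.2, rel=0.1)

    def test_negative_gain_rejected(self):
        t = np.arange(0, 30, 0.01)
        truth = synth.make_photometry_truth(t, np.zeros_like(t), seed=0,
                                            channel_gains=(-1.0, 0.8))
        with pytest.raises(DegenerateInputError):
            synth.gen_photometry(truth, seed=0)


class TestAvoidanceGen:
    def test_all_fast_latencies_all_avoids(self):
        trials, truth = synth.gen_avoidance_session(
            "AA1", n_trials=30, latency_law={"CS1": (2.0, 0.5)}, seed=0)
        lat = trials.df["response_latency"].to_numpy()
        if np.all(lat < 7.0):
            assert all(o == "avoid" for o in truth)
        assert (np.asarray(truth) == "avoid").mean() > 0.9

    def test_latency_law_ordering_under_aa4(self):
        trials, _ = synth.gen_avoidance_session("AA4", n_trials=90, seed=1)
        lat = B.latency_by_cs(trials, seed=1)
        s = lat["summary"]
        assert s["CS1"]["mean"] < s["CS3"]["mean"]

    def test_intertrial_intervals_in_range(self):
        trials, _ = synth.gen_avoidance_session("AA2", n_trials=40, seed=2)
        iti = trials.df["intertrial_interval"].to_numpy()
        assert np.all((iti >= 25.0) & (iti <= 45.0))

    def test_unknown_procedure_rejected(self):
        with pytest.raises(DegenerateInputError):
            synth.gen_avoidance_session("AA9", n_trials=5)

    def test_deterministic_under_seed(self):
        a, ta = synth.gen_avoidance_session("AA3", n_trials=25, seed=7)
        b, tb = synth.gen_avoidance_session("AA3", n_trials=25, seed=7)
        assert ta == tb
        assert a.df.drop(columns="itc_times").equals(
            b.df.drop(columns="itc_times"))
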