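import numpy as np
import pytest

from incerta import kinematics as K
from incerta import synth


@pytest.fixture(scope="session")
def speed_profile():
    """300 s of bout-structured movement speed at 50 Hz."""
    return synth.gen_speed_profile(300.0, fs=50.0, seed=11)


@pytest.fixture(scope="session")
def class_profiles():
    return synth.default_class_profiles()


@pytest.fixture(scope="session")
def exploratory_kin():
    """Kinematics of a 300-s noisy exploratory trajectory (known schedule)."""
    sched = synth.TurnSchedule.random(300.0, seed=21)
    track, true_angle = synth.gen_head_trajectory(
        sched, duration=300.0, noise_sd=0.5, seed=21)
    kin = K.compute_kinematics(K.calibrate(track))
    return sched, track, true_angle, kin


def straight_track(n=100, fps=50.0, step=(0.0, 0.0), angle=0.0,
                   dist_cm=2.0, px_per_cm=1.0):
    """Track with a fixed head angle and constant ears-marker steps (cm)."""
    t = np.arange(n) / fps
    ears = np.cumsum(np.tile(np.asarray(step, float), (n, 1)), axis=0)
    th = np.radians(angle)
    nose = ears + dist_cm * np.array([np.cos(th), np.sin(th)])
    return K.MarkerTrack(t=t, nose=nose, ears=ears, fps=fps,
                         px_per_cm=px_per_cm, calibrated=True)
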