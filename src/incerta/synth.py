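"""Synthetic data with known ground truth for every pipeline input.

The generators emulate the statistical structure the analysis chain
assumes, so that each stage can be validated against a stored truth:

* head-marker trajectories whose midline angle integrates a schedule of
  discrete turns (raised-cosine angular-velocity profile within a turn),
* spike trains from an inhomogeneous Poisson process whose rate is
  linearly coupled to movement speed, with four class profiles
  (Class1a/1b strongly movement-activated with high/low baseline rate,
  Class2a mildly suppressed, Class2b weakly activated),
* two-channel photometry in which a calcium-kernel convolution of the
  movement drive enters only the signal channel while a shared
  multiplicative motion artifact enters both (the rationale for the
  isosbestic control channel),
* signaled active-avoidance sessions (procedures AA1–AA4) with per-CS
  avoidance intervals, drawn response latencies and intertrial crossings.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior import PROCEDURES, TrialTable
from .errors import DegenerateInputError
from .kinematics import MarkerTrack
from .photometry import PhotometryRaw
from .units import SpikeTrain

__all__ = [
    "TurnSchedule", "ClassProfile", "PhotometryTruth",
    "default_class_profiles", "gen_head_trajectory", "gen_speed_profile",
    "gen_spike_train", "make_photometry_truth", "gen_photometry",
    "gen_avoidance_session",
]


# ---------------------------------------------------------------- schedules

@dataclass
class TurnSchedule:
    """Planted discrete head turns.

    Positive amplitude = contraversive by the package-wide convention
    (per-animal sign resolved downstream by ``contraversive_sign``).
    """

    event_times: np.ndarray    # s, strictly increasing turn onsets
    amplitudes_deg: np.ndarray # signed, |amplitude| > 0
    durations: np.ndarray      # s, > 0

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        self.amplitudes_deg = np.asarray(self.amplitudes_deg, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        n = len(self.event_times)
        if not (len(self.amplitudes_deg) == len(self.durations) == n):
            raise DegenerateInputError("schedule fields must have equal length")
        if n:
            if not np.all(np.diff(self.event_times) > 0):
                raise DegenerateInputError("event_times must be strictly increasing")
            if np.any(self.amplitudes_deg == 0):
                raise DegenerateInputError("turn amplitudes must be nonzero")
            if np.any(self.durations <= 0):
                raise DegenerateInputError("turn durations must be positive")
            ends = self.event_times + self.durations
            if np.any(ends[:-1] > self.event_times[1:]):
                raise DegenerateInputError("overlapping turn intervals")

    def __len__(self) -> int:
        return len(self.event_times)

    @classmethod
    def random(cls, duration: float, rate_hz: float = 0.1,
               amp_range: tuple[float, float] = (15.0, 60.0),
               turn_s: tuple[float, float] = (0.3, 0.8),
               min_gap: float = 1.0, p_same_direction: float = 0.0,
               seed: int = 0) -> "TurnSchedule":
        """Poisson-like schedule of exploratory turns of both directions.

        Successive turns alternate direction by default (head orientation
        is mean-reverting during exploration, so a turn one way is
        typically followed by a turn back); ``p_same_direction`` > 0
        allows occasional same-direction runs.
        """
        rng = np.random.default_rng(seed)
        times, amps, durs = [], [], []
        t = rng.uniform(1.0, 1.0 + 1.0 / rate_hz)
        sign = float(rng.choice([-1.0, 1.0]))
        while t < duration - 2.0:
            d = rng.uniform(*turn_s)
            times.append(t)
            amps.append(rng.uniform(*amp_range) * sign)
            durs.append(d)
            if rng.random() >= p_same_direction:
                sign = -sign
            t += d + min_gap + rng.exponential(1.0 / rate_hz)
        return cls(np.array(times), np.array(amps), np.array(durs))


@dataclass(frozen=True)
class ClassProfile:
    """Linear rate–speed coupling profile of one unit class."""

    label: str                 # Class1a | Class1b | Class2a | Class2b
    baseline_rate: float       # spikes/s, >= 0
    coupling_gain: float       # (spikes/s) per (cm/s), signed

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise DegenerateInputError("baseline_rate must be >= 0")


def default_class_profiles() -> dict[str, ClassProfile]:
    """Default four-class parameters.

    Chosen to reproduce the ordinal relations of the recorded population
    (Class1a fires faster than Class1b; both strongly movement-activated;
    Class2a mildly suppressed during movement; Class2b weakly activated),
    not any particular session's absolute rates.
    """
    return {
        "Class1a": ClassProfile("Class1a", 20.0, +1.5),
        "Class1b": ClassProfile("Class1b", 8.0, +1.5),
        "Class2a": ClassProfile("Class2a", 8.0, -0.6),
        "Class2b": ClassProfile("Class2b", 6.0, +0.2),
    }


# ------------------------------------------------------------- trajectories

def _angle_from_schedule(t: np.ndarray, schedule: TurnSchedule,
                         start_angle: float = 0.0) -> np.ndarray:
    """Midline angle integrating each turn's raised-cosine velocity profile.

    Within a turn of amplitude A and duration D starting at t0, the angular
    velocity is A/D·(1 − cos 2πu), u = (t−t0)/D, whose integral is
    A·(u − sin 2πu / 2π): smooth onset/offset and exact terminal amplitude.
    """
    ang = np.full_like(t, start_angle, dtype=float)
    for t0, amp, dur in zip(schedule.event_times, schedule.amplitudes_deg,
                            schedule.durations):
        u = np.clip((t - t0) / dur, 0.0, 1.0)
        ang += amp * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
    return ang


def gen_head_trajectory(schedule: TurnSchedule, fps: float = 50.0,
                        duration: float = 60.0, noise_sd: float = 0.0,
                        seed: int = 0, px_per_cm: float = 20.0,
                        marker_dist_cm: float = 1.5,
                        start_angle: float = 0.0,
                        center_px: tuple[float, float] = (320.0, 240.0),
                        ) -> tuple[MarkerTrack, np.ndarray]:
    """Two-marker track whose midline angle follows the turn schedule.

    The ears marker sits at a fixed arena position; the nose marker sits
    ``marker_dist_cm`` away along the midline, so the inter-marker distance
    is constant. ``noise_sd`` (deg) is white angular jitter on the midline.
    Returns the uncalibrated pixel-coordinate track together with the
    noise-free ground-truth angle series.
    """
    if not (30.0 <= fps <= 100.0):
        raise DegenerateInputError("fps must lie in the tracked range 30-100")
    if duration <= 0:
        raise DegenerateInputError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    true_angle = _angle_from_schedule(t, schedule, start_angle)
    ang = true_angle + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    th = np.radians(ang)
    ears = np.broadcast_to(np.asarray(center_px, float), (n, 2)).copy()
    nose = ears + marker_dist_cm * px_per_cm * np.stack(
        [np.cos(th), np.sin(th)], axis=1)
    track = MarkerTrack(t=t, nose=nose, ears=ears, fps=fps,
                        px_per_cm=px_per_cm, calibrated=False)
    return track, true_angle


def gen_speed_profile(duration: float, fs: float = 50.0,
                      bout_rate_hz: float = 0.12,
                      bout_amp: tuple[float, float] = (5.0, 20.0),
                      bout_s: tuple[float, float] = (0.4, 1.5),
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Movement-speed trace built from raised-cosine bouts.

    Convenience forward model for the spike/photometry generators when a
    full marker track is not needed. Returns ``(t, speed, bout_mask)``
    where ``bout_mask`` is True inside planted movement bouts.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    speed = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    tt = rng.uniform(1.0, 1.0 + 1.0 / bout_rate_hz)
    while tt < duration - 2.0:
        d = rng.uniform(*bout_s)
        a = rng.uniform(*bout_amp)
        u = np.clip((t - tt) / d, 0.0, 1.0)
        speed += a * 0.5 * (1 - np.cos(2 * np.pi * u))
        mask |= (t >= tt) & (t < tt + d)
        tt += d + rng.exponential(1.0 / bout_rate_hz)
    return t, speed, mask


# -------------------------------------------------------------- spike trains

def gen_spike_train(profile: ClassProfile, t: np.ndarray, speed: np.ndarray,
                    seed: int = 0, unit_id: str | None = None,
                    stim_times: np.ndarray | None = None,
                    stim_gain: float = 0.0, stim_dur: float = 0.05,
                    ) -> SpikeTrain:
    """Inhomogeneous Poisson spike train coupled to movement speed.

    The rate on a 1-ms grid is ``max(0, baseline + gain·speed(t))``; an
    optional stimulus-locked rectangular rate bump of ``stim_gain``
    spikes/s for ``stim_dur`` s after each stimulus models a sensory
    response. Spikes are drawn per 1-ms bin (Bernoulli thinning of the
    Poisson process) and jittered uniformly within the bin.
    """
    if np.any(np.asarray(speed) < 0):
        raise DegenerateInputError("speed must be nonnegative")
    rng = np.random.default_rng(seed)
    dt = 1e-3
    grid = np.arange(t[0], t[-1], dt)
    rate = profile.baseline_rate + profile.coupling_gain * np.interp(
        grid, t, speed)
    if stim_times is not None and stim_gain != 0.0:
        for s in np.asarray(stim_times, dtype=float):
            rate[(grid >= s) & (grid < s + stim_dur)] += stim_gain
    rate = np.maximum(rate, 0.0)
    fire = rng.random(len(grid)) < rate * dt
    times = grid[fire] + rng.uniform(0.0, dt, int(fire.sum()))
    return SpikeTrain(unit_id=unit_id or f"{profile.label}-s{seed}",
                      spike_times=np.sort(times))


# --------------------------------------------------------------- photometry

@dataclass
class PhotometryTruth:
    """Latent quantities behind a simulated photometry session.

    ``activity`` (calcium-kernel-filtered movement drive) enters only the
    465-driven channel; ``artifact`` (shared slow multiplicative
    fluctuation, the motion/bleaching component) enters both channels.
    """

    t: np.ndarray
    activity: np.ndarray       # a.u., >= 0
    artifact: np.ndarray       # unitless multiplicative fluctuation
    kernel_delay: float        # s, onset delay of the calcium kernel
    kernel_tau: float          # s, decay time constant
    channel_gains: tuple[float, float] = (1.0, 0.8)


def make_photometry_truth(t: np.ndarray, speed: np.ndarray,
                          fs: float = 100.0, kernel_tau: float = 0.5,
                          kernel_delay: float = 0.1,
                          artifact_amp: float = 0.05,
                          artifact_tau: float = 2.0,
                          channel_gains: tuple[float, float] = (1.0, 0.8),
                          seed: int = 0) -> PhotometryTruth:
    """Latent activity and shared artifact at the 100-Hz effective rate.

    Activity = speed drive convolved with a delayed single-exponential
    calcium kernel (GCaMP-like, τ = 0.5 s default), peak-normalized.
    Artifact = slow Gaussian-filtered noise of SD ``artifact_amp``.
    """
    rng = np.random.default_rng(seed)
    n = int(round((t[-1] - t[0]) * fs)) + 1
    tt = t[0] + np.arange(n) / fs
    drive = np.interp(tt, t, speed)
    k_t = np.arange(0.0, kernel_delay + 6 * kernel_tau, 1.0 / fs)
    kernel = np.where(k_t >= kernel_delay,
                      np.exp(-(k_t - kernel_delay) / kernel_tau), 0.0)
    activity = np.convolve(drive, kernel)[:n] / fs
    peak = activity.max()
    if peak > 0:
        activity = activity / peak
    if artifact_amp > 0:
        art = gaussian_filter1d(rng.normal(0.0, 1.0, n), artifact_tau * fs)
        sd = art.std()
        art = artifact_amp * art / sd if sd > 0 else np.zeros(n)
    else:
        art = np.zeros(n)
    return PhotometryTruth(t=tt, activity=activity, artifact=art,
                           kernel_delay=kernel_delay, kernel_tau=kernel_tau,
                           channel_gains=channel_gains)


def gen_photometry(truth: PhotometryTruth, seed: int = 0,
                   baseline: float = 100.0, activity_scale: float = 0.10,
                   noise_sd: float = 0.2) -> PhotometryRaw:
    """Two-channel samples from the latent truth.

    465 channel: gain₁·(baseline + scale·activity)·(1 + artifact) + noise;
    405 channel: gain₂·baseline·(1 + artifact) + noise. ``activity_scale``
    is the fluorescence excursion of a unit activity peak relative to
    baseline = 1.
    """
    g1, g2 = truth.channel_gains
    if g1 <= 0 or g2 <= 0:
        raise DegenerateInputError("channel gains must be positive")
    rng = np.random.default_rng(seed)
    n = len(truth.t)
    f465 = (g1 * (baseline + activity_scale * baseline * truth.activity)
            * (1.0 + truth.artifact) + rng.normal(0.0, noise_sd, n))
    f405 = (g2 * baseline * (1.0 + truth.artifact)
            + rng.normal(0.0, noise_sd, n))
    return PhotometryRaw(t=truth.t, f_signal=f465, f_control=f405)


# ----------------------------------------------------------------- behavior

#: default per-CS latency laws (normal mean/sd, s), chosen so that shorter
#: avoidance intervals drive faster responses, as trained animals do
_DEFAULT_LAWS = {
    "AA1": {"CS1": (3.0, 1.5)},
    "AA2": {"CS1": (4.0, 1.5)},
    "AA3": {"CS1": (3.0, 1.5), "CS2": (None, None)},   # CS2 is passive
    "AA4": {"CS1": (2.0, 0.8), "CS2": (3.5, 1.2), "CS3": (6.0, 2.0)},
}


def gen_avoidance_session(procedure: str, n_trials: int = 50,
                          latency_law: dict[str, tuple[float, float]] | None = None,
                          seed: int = 0, p_shuttle_passive: float = 0.15,
                          itc_rate_hz: float | None = None,
                          ) -> tuple[TrialTable, list[str]]:
    """Simulate one avoidance session; returns the table and truth labels.

    Trials cycle randomly over the procedure's CSs. The response latency is
    drawn from the per-CS law (normal, truncated at 0.3 s); a draw beyond
    the CS's avoidance interval means the animal failed to avoid and
    escapes shortly after US onset. For the passive CS of AA3, shuttling
    occurs with probability ``p_shuttle_passive``. Intertrial intervals are
    uniform on 25–45 s; ITCs are a Poisson count within each interval
    (rate lowered 10× under ITC-punishing procedures AA2/AA4).
    """
    if procedure not in PROCEDURES:
        raise DegenerateInputError(f"unknown procedure {procedure!r}")
    spec = PROCEDURES[procedure]
    laws = dict(_DEFAULT_LAWS[procedure])
    if latency_law:
        laws.update(latency_law)
    if itc_rate_hz is None:
        itc_rate_hz = 0.005 if procedure in ("AA2", "AA4") else 0.02
    rng = np.random.default_rng(seed)
    cs_ids = sorted(spec.keys())
    rows, truth = [], []
    t_clock = 0.0
    for k in range(n_trials):
        cs = cs_ids[int(rng.integers(len(cs_ids)))]
        st = spec[cs]
        iti = float(rng.uniform(25.0, 45.0))
        n_itc = int(rng.poisson(itc_rate_hz * iti))
        itc_times = np.sort(rng.uniform(t_clock, t_clock + iti, n_itc))
        t_clock += iti
        onset = t_clock
        if st.passive_cs:
            if rng.random() < p_shuttle_passive:
                latency = float(rng.uniform(0.3, st.avoidance_interval))
                label = "passive_fail"
                t_clock = onset + latency
            else:
                latency = np.nan
                label = "passive_avoid"
                t_clock = onset + st.avoidance_interval
        else:
            mu, sd = laws[cs]
            latency = max(0.3, float(rng.normal(mu, sd)))
            if latency <= st.avoidance_interval:
                label = "avoid"
            else:
                label = "escape"
                latency = st.avoidance_interval + 0.3 + float(rng.exponential(0.7))
            t_clock = onset + latency
        rows.append(dict(trial=k, cs_id=cs, cs_onset=onset,
                         avoidance_interval=st.avoidance_interval,
                         response_latency=latency,
                         itc_times=list(np.round(itc_times, 6)),
                         intertrial_interval=iti))
        truth.append(label)
    return TrialTable.from_records(rows, procedure=procedure), truth
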