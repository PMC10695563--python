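"""Detection and categorization of spontaneous movement events.

A point of a uniformly sampled continuous measure (head angle for turns,
a speed component for movement peaks) is an event iff it is the extremum
among all points within ±half_window (0.5 s default) around it. For head
angle, the local change in angle at the extremum must additionally exceed
a turn threshold (10° default); its sign gives the turning direction. For
speed, maxima must exceed a minimum prominence over the preceding trough.

Detected events are then sorted by the timing of previous events into the
three categories used for triggered averaging:

* ``all`` — every detected peak,
* ``onset_isolated`` — peaks with no detected peak within an exclusion
  interval before them (movement onsets from immobility),
* ``fixed_interval`` — a greedy left-to-right subsample keeping events at
  least a fixed interval apart (movement increases from ongoing movement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d

from .errors import DegenerateInputError

__all__ = ["EventSet", "detect_peaks", "categorize_peaks"]

_DIRECTIONS = ("ipsiversive", "contraversive", "none")


@dataclass
class EventSet:
    """Detected events with amplitudes, directions and category flags."""

    times: np.ndarray                       # s, strictly increasing
    indices: np.ndarray                     # frame index of each event
    amplitudes: np.ndarray                  # deg (turns) or cm/s (speed peaks)
    direction: np.ndarray                   # 'ipsiversive'/'contraversive'/'none'
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.direction = np.asarray(self.direction, dtype=object)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise DegenerateInputError("event times must be strictly increasing")
        if "all" not in self.flags:
            self.flags["all"] = np.ones(len(self.times), dtype=bool)

    def __len__(self) -> int:
        return len(self.times)

    def select(self, flag: str) -> "EventSet":
        """Subset of events carrying a category flag."""
        m = self.flags[flag]
        return EventSet(self.times[m], self.indices[m], self.amplitudes[m],
                        self.direction[m],
                        {k: v[m] for k, v in self.flags.items()})


def _extrema_scan(x: np.ndarray, w: int, kind: str) -> np.ndarray:
    """Windowed strict-extremum scan (earliest sample wins ties).

    A point is kept iff it strictly exceeds every earlier sample and is at
    least every later sample within ±w samples, so a plateau of equal
    values yields only its earliest sample. The centered maximum filter
    prunes the candidate set before the exact (rare) neighbourhood check.
    """
    sign = 1.0 if kind == "max" else -1.0
    y = sign * np.asarray(x, dtype=float)
    # window max over [i-w, i+w] via a single centered filter
    win = maximum_filter1d(y, size=2 * w + 1, mode="constant", cval=-np.inf)
    cand = np.flatnonzero(y == win)
    out = []
    for i in cand:
        lo = max(0, i - w)
        before = y[lo:i]
        after = y[i + 1:i + w + 1]
        if before.size and before.max() >= y[i]:
            continue                       # an earlier equal/greater point
        if after.size and after.max() > y[i]:
            continue
        out.append(i)
    return np.asarray(out, dtype=int)


def detect_peaks(
    series: np.ndarray,
    fps: float,
    half_window: float = 0.5,
    kind: str = "turn",
    turn_threshold: float = 10.0,
    min_prominence: float = 2.0,
    contraversive_sign: float = 1.0,
) -> EventSet:
    """Detect turns (on head angle) or movement peaks (on a speed series).

    Parameters
    ----------
    series:
        Uniformly sampled measure: unwrapped head angle in degrees
        (``kind='turn'``) or a nonnegative speed in cm/s (``kind='speed'``).
    fps:
        Sampling rate of the series (frames/s).
    half_window:
        A point is an event iff it is the extremum among all points within
        this many seconds before and after it.
    turn_threshold:
        Turns only: minimum |angle change| (deg) at the extremum, measured
        from the nearest preceding local extremum of opposite sense.
    min_prominence:
        Speed peaks only: minimum rise (cm/s) over the preceding trough.
    contraversive_sign:
        Sign of the angle change labelled 'contraversive' (per-animal,
        set by the recorded side).
    """
    series = np.asarray(series, dtype=float)
    w = int(round(half_window * fps))
    if w < 2:
        raise DegenerateInputError("half_window must span at least 2 frames")
    t = np.arange(len(series)) / fps
    if len(series) < 2 * w + 1:
        warnings.warn("series shorter than detection window; no events",
                      stacklevel=2)
        return EventSet(np.array([]), np.array([], int), np.array([]),
                        np.array([], object))

    if kind == "turn":
        imax = _extrema_scan(series, w, "max")
        imin = _extrema_scan(series, w, "min")
        ext = np.sort(np.concatenate([imax, imin]))
        idx, amps = [], []
        # amplitude of each extremum = angle change from the preceding
        # extremum (series start if none); under strict max/min alternation
        # this is the change from the nearest opposite-sense extremum, and
        # it never double-counts adjacent same-sense noise extrema
        ref = series[0]
        for i in ext:
            amp = series[i] - ref
            if abs(amp) > turn_threshold:
                idx.append(i)
                amps.append(amp)
            ref = series[i]
        idx = np.asarray(idx, dtype=int)
        amps = np.asarray(amps, dtype=float)
        direction = np.where(np.sign(amps) == np.sign(contraversive_sign),
                             "contraversive", "ipsiversive").astype(object)
    elif kind == "speed":
        imax = _extrema_scan(series, w, "max")
        idx, amps = [], []
        for i in imax:
            start = max(0, i - 4 * w)
            trough = series[start:i].min() if i > start else series[i]
            if series[i] - trough >= min_prominence:
                idx.append(i)
                amps.append(series[i])
        idx = np.asarray(idx, dtype=int)
        amps = np.asarray(amps, dtype=float)
        direction = np.full(len(idx), "none", dtype=object)
    else:
        raise ValueError(f"unknown kind {kind!r}")

    return EventSet(t[idx], idx, amps, direction)


def categorize_peaks(events: EventSet, exclusion_s: float = 3.0,
                     fixed_interval_s: float = 5.0) -> EventSet:
    """Attach ``onset_isolated`` and ``fixed_interval`` category flags.

    ``onset_isolated``: no prior detected event within ``exclusion_s``.
    ``fixed_interval``: greedy left-to-right selection keeping events at
    least ``fixed_interval_s`` apart (first event always kept). Both are
    subsets of ``all``.
    """
    t = events.times
    n = len(t)
    isolated = np.ones(n, dtype=bool)
    if n > 1:
        isolated[1:] = np.diff(t) > exclusion_s
    fixed = np.zeros(n, dtype=bool)
    last = -np.inf
    for i in range(n):
        if t[i] - last >= fixed_interval_s:
            fixed[i] = True
            last = t[i]
    flags = dict(events.flags)
    flags["onset_isolated"] = isolated
    flags["fixed_interval"] = fixed
    return EventSet(events.times, events.indices, events.amplitudes,
                    events.direction, flags)
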