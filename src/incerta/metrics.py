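"""Event-triggered extraction and the scalar trace measures.

Continuous measures (Z-scored ΔF/F, speed components, head-angle bias) are
extracted around events onto a common relative-time grid; per-event areas
(trapezoidal integral over a window), peak amplitude from a pre-event
baseline and time-to-peak quantify the triggered responses; the per-lag
Pearson cross-correlation relates pairs of continuous variables; the
direction contrast compares event-triggered areas between ipsiversive and
contraversive movements with the pooled bootstrap test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError
from .events import EventSet
from .resampling import bootstrap_diff

logger = logging.getLogger(__name__)

__all__ = ["TriggeredStack", "extract_triggered", "area_measure",
           "peak_and_latency", "cross_correlation", "direction_contrast"]


@dataclass
class TriggeredStack:
    """Event-aligned snippets of one continuous measure on a common grid."""

    time: np.ndarray        # s relative to the event, common to all rows
    snippets: np.ndarray    # (n_events, n_samples)
    event_times: np.ndarray # absolute event times of the retained rows
    labels: np.ndarray | None = None   # optional per-event labels
    n_dropped: int = 0      # edge events without full support

    def __len__(self) -> int:
        return self.snippets.shape[0]

    def mean(self) -> np.ndarray:
        return self.snippets.mean(axis=0)

    def sem(self) -> np.ndarray:
        n = self.snippets.shape[0]
        return self.snippets.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 \
            else np.zeros_like(self.time)


def extract_triggered(t: np.ndarray, x: np.ndarray,
                      events: EventSet | np.ndarray,
                      window: tuple[float, float] = (-3.0, 3.0),
                      fs_out: float | None = None,
                      labels: np.ndarray | None = None) -> TriggeredStack:
    """Time-extract a continuous measure around events.

    Snippets are linearly interpolated onto a common relative-time grid
    (native sampling rate by default; ``fs_out`` to mix sources recorded
    at different rates). Events whose window exceeds the series support
    are dropped and counted.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    ev = events.times if isinstance(events, EventSet) else np.asarray(events, float)
    if ev.ndim == 0:
        ev = ev.reshape(1)
    pre, post = window
    if post <= pre:
        raise DegenerateInputError("empty window")
    if fs_out is None:
        fs_out = (len(t) - 1) / (t[-1] - t[0])
    taxis = np.arange(pre, post + 0.5 / fs_out, 1.0 / fs_out)
    ok = (ev + pre >= t[0]) & (ev + post <= t[-1])
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("extract_triggered: dropped %d edge event(s)", n_dropped)
    ev_ok = ev[ok]
    if ev_ok.size == 0:
        raise DegenerateInputError("no usable events within series support")
    sample_at = ev_ok[:, None] + taxis[None, :]
    snippets = np.interp(sample_at.ravel(), t, x).reshape(sample_at.shape)
    lab = None
    if labels is not None:
        lab = np.asarray(labels, dtype=object)[ok]
    return TriggeredStack(time=taxis, snippets=snippets, event_times=ev_ok,
                          labels=lab, n_dropped=n_dropped)


def _integrate_rows(time: np.ndarray, rows: np.ndarray,
                    a: float, b: float) -> np.ndarray:
    """Trapezoidal integral of each row over [a, b].

    The endpoints are linearly interpolated onto the grid, so areas are
    exactly additive over adjacent windows: [a,b] + [b,c] = [a,c].
    """
    if a >= b:
        raise DegenerateInputError("window must have positive length")
    if a < time[0] - 1e-9 or b > time[-1] + 1e-9:
        raise DegenerateInputError("window outside snippet support")
    inner = time[(time > a) & (time < b)]
    grid = np.concatenate([[a], inner, [b]])
    vals = np.vstack([np.interp(grid, time, r) for r in rows])
    return np.trapezoid(vals, grid, axis=1)


def area_measure(stack: TriggeredStack,
                 window: tuple[float, float]) -> np.ndarray:
    """Per-event trapezoidal area over ``window`` (measure × s)."""
    return _integrate_rows(stack.time, stack.snippets, *window)


def peak_and_latency(stack: TriggeredStack,
                     window: tuple[float, float],
                     baseline: tuple[float, float] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-event extremum from baseline and its time-to-peak.

    The baseline mean (pre-event window; 0 if ``baseline`` is None) is
    subtracted from each snippet; within ``window`` the sample of largest
    absolute deviation is the peak (signed value returned). Ties and flat
    snippets resolve to the earliest sample, so a flat snippet reports
    peak 0 at the window start.
    """
    time = stack.time
    a, b = window
    if baseline is not None:
        if baseline[1] > a:
            raise DegenerateInputError("baseline must precede the window")
        bm = (time >= baseline[0]) & (time < baseline[1])
        if not bm.any():
            raise DegenerateInputError("baseline window outside support")
        base = stack.snippets[:, bm].mean(axis=1, keepdims=True)
    else:
        base = 0.0
    wm = (time >= a) & (time <= b)
    if not wm.any():
        raise DegenerateInputError("window outside snippet support")
    dev = stack.snippets[:, wm] - base
    i = np.argmax(np.abs(dev), axis=1)       # first occurrence on ties
    peaks = dev[np.arange(dev.shape[0]), i]
    lats = time[wm][i]
    return peaks, lats


def cross_correlation(x: np.ndarray, y: np.ndarray, fs: float,
                      max_lag: float = 3.0
                      ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-lag Pearson correlation between two co-sampled series.

    For each integer-sample lag in ±``max_lag``, the correlation is
    computed on the overlapping support (not FFT convolution), matching a
    "correlation" axis normalization: r ∈ [−1, 1] at every lag. Positive
    peak lag means ``y`` follows ``x``.

    Returns ``(lags_s, r, peak_lag_s, peak_r)`` where the peak is the lag
    of maximum |r| (earliest on ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise DegenerateInputError("series lengths differ")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input")
    k_max = int(round(max_lag * fs))
    if k_max >= len(x) - 2:
        raise DegenerateInputError("max_lag too long for the series")
    lags = np.arange(-k_max, k_max + 1)
    r = np.empty(lags.size)
    for j, k in enumerate(lags):
        if k >= 0:
            a, b = x[:len(x) - k], y[k:]
        else:
            a, b = x[-k:], y[:len(y) + k]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            r[j] = 0.0
        else:
            r[j] = stats.pearsonr(a, b).statistic
    i = int(np.argmax(np.abs(r)))
    return lags / fs, r, float(lags[i] / fs), float(r[i])


def direction_contrast(stack_ipsi: TriggeredStack,
                       stack_contra: TriggeredStack,
                       window: tuple[float, float] = (-3.0, 3.0),
                       n_resamples: int = 2000,
                       seed: int = 0) -> tuple[float, float]:
    """Ipsiversive-vs-contraversive contrast of triggered areas.

    Per-event areas over ``window`` on each side; returns the difference
    of means (ipsi − contra) and the pooled-bootstrap two-sided p-value.
    Requires at least 10 events per side.
    """
    if len(stack_ipsi) < 10 or len(stack_contra) < 10:
        raise DegenerateInputError("need at least 10 events per side")
    a = area_measure(stack_ipsi, window)
    b = area_measure(stack_contra, window)
    diff = float(a.mean() - b.mean())
    if np.array_equal(a, b):
        return 0.0, 1.0
    p = bootstrap_diff(a, b, n_resamples=n_resamples, seed=seed)
    return diff, float(p)
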