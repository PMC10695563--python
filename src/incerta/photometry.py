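"""Two-channel fiber-photometry processing: demultiplexing, isosbestic
baseline fitting, ΔF/F and Z-scoring.

Acquisition alternates two excitation LEDs within each 10-ms cycle (100 Hz
effective rate): the 465-nm pulse drives the calcium-dependent emission
(*F*, sampled at the end of the pulse) and the 405-nm pulse drives a
calcium-independent control emission that carries the same motion and
bleaching artifacts. The control channel is scaled to the signal channel
by a linear fit; the fitted values are the baseline *F*₀, and

    ΔF/F = (F − F₀) / F₀

is then converted to Z-scores over a normalization epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, SchemaError

logger = logging.getLogger(__name__)

__all__ = ["PulseLayout", "PhotometryRaw", "DffSeries",
           "demultiplex", "fit_isosbestic", "compute_dff_z", "process"]


@dataclass(frozen=True)
class PulseLayout:
    """Per-cycle excitation timing (seconds from cycle start).

    Default: 10-ms cycle; 465 nm on for the first 3 ms; after a 2-ms gap
    the 405 nm pulse is on for 3 ms. Each channel is measured at the end
    of its pulse.
    """

    cycle_s: float = 0.010
    signal_on: tuple[float, float] = (0.0, 0.003)
    control_on: tuple[float, float] = (0.005, 0.008)


@dataclass
class PhotometryRaw:
    """Demultiplexed per-cycle samples of the two emission channels."""

    t: np.ndarray          # s, one per cycle (100 Hz effective)
    f_signal: np.ndarray   # 465-driven emission, a.u.
    f_control: np.ndarray  # 405-driven emission, a.u.

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_signal = np.asarray(self.f_signal, dtype=float)
        self.f_control = np.asarray(self.f_control, dtype=float)
        if not (len(self.t) == len(self.f_signal) == len(self.f_control)):
            raise SchemaError("photometry channel lengths differ")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise SchemaError(f"timestamps not strictly increasing at row {bad}")
        if not (np.isfinite(self.f_signal).all()
                and np.isfinite(self.f_control).all()):
            raise SchemaError("non-finite photometry values")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class DffSeries:
    """Fitted baseline, fractional fluorescence change and its Z-score."""

    t: np.ndarray
    f_o: np.ndarray        # fitted baseline per sample, a.u.
    dff: np.ndarray        # (F − F₀)/F₀, unitless (nan where masked)
    z: np.ndarray          # Z-scored dff over the normalization epoch
    fit_slope: float = np.nan
    fit_intercept: float = np.nan


def demultiplex(samples: np.ndarray, sample_rate_hz: float,
                layout: PulseLayout = PulseLayout(),
                t0: float = 0.0) -> PhotometryRaw:
    """Split an interleaved high-rate acquisition into the two channels.

    ``samples`` is the raw photodetector stream acquired at
    ``sample_rate_hz`` (5–20 kHz typically). Each channel's per-cycle value
    is the sample at the end of its excitation pulse. A truncated final
    cycle is dropped (count logged).
    """
    samples = np.asarray(samples, dtype=float)
    if sample_rate_hz * layout.cycle_s < 2:
        raise DegenerateInputError("sample rate too low for the pulse layout")
    per_cycle = sample_rate_hz * layout.cycle_s
    n_cycles = int(np.floor(len(samples) / per_cycle))
    dropped = len(samples) - int(np.floor(n_cycles * per_cycle))
    if dropped:
        logger.info("demultiplex: dropped %d trailing samples "
                    "(truncated final cycle)", dropped)
    if n_cycles == 0:
        raise DegenerateInputError("acquisition shorter than one cycle")
    cyc = np.arange(n_cycles)
    # index of the last sample within each pulse window
    i_sig = np.floor(cyc * per_cycle
                     + layout.signal_on[1] * sample_rate_hz).astype(int) - 1
    i_ctl = np.floor(cyc * per_cycle
                     + layout.control_on[1] * sample_rate_hz).astype(int) - 1
    i_sig = np.clip(i_sig, 0, len(samples) - 1)
    i_ctl = np.clip(i_ctl, 0, len(samples) - 1)
    t = t0 + cyc * layout.cycle_s
    return PhotometryRaw(t=t, f_signal=samples[i_sig], f_control=samples[i_ctl])


def fit_isosbestic(raw: PhotometryRaw,
                   fit_epoch: tuple[float, float] | None = None,
                   intercept: bool = True) -> tuple[np.ndarray, float, float]:
    """Scale the control channel to the signal channel by a linear fit.

    Ordinary least squares of ``f_signal`` on ``f_control`` over
    ``fit_epoch`` (whole session by default); the fitted values evaluated
    on the full session are the baseline F₀. ``intercept=False`` restricts
    the fit to a pure scaling (slope only).

    Returns ``(f_o, slope, intercept)``.
    """
    if fit_epoch is None:
        m = np.ones(len(raw), dtype=bool)
    else:
        m = (raw.t >= fit_epoch[0]) & (raw.t <= fit_epoch[1])
    if m.sum() < 100:
        raise DegenerateInputError("fewer than 100 samples in fit epoch")
    x, y = raw.f_control[m], raw.f_signal[m]
    if np.ptp(x) == 0:
        raise DegenerateInputError("control channel has zero variance")
    if intercept:
        slope, icpt = np.polyfit(x, y, 1)
    else:
        slope = float(x @ y / (x @ x))
        icpt = 0.0
    f_o = slope * raw.f_control + icpt
    return f_o, float(slope), float(icpt)


def compute_dff_z(raw: PhotometryRaw, f_o: np.ndarray,
                  z_epoch: tuple[float, float] | None = None) -> DffSeries:
    """ΔF/F = (F − F₀)/F₀ and its Z-score over ``z_epoch``.

    Samples with F₀ ≤ 0 are masked (NaN) and excluded from normalization;
    an all-masked trace or a zero-SD ΔF/F is an error.
    """
    f_o = np.asarray(f_o, dtype=float)
    bad = ~(f_o > 0)
    if bad.all():
        raise DegenerateInputError("baseline non-positive everywhere")
    if bad.any():
        logger.warning("compute_dff_z: masking %d samples with F0 <= 0",
                       int(bad.sum()))
    dff = np.where(bad, np.nan, (raw.f_signal - f_o) / np.where(bad, 1.0, f_o))
    if z_epoch is None:
        em = np.ones(len(raw), dtype=bool)
    else:
        em = (raw.t >= z_epoch[0]) & (raw.t <= z_epoch[1])
    ref = dff[em & ~bad]
    if ref.size < 2:
        raise DegenerateInputError("normalization epoch empty after masking")
    mu, sd = float(ref.mean()), float(ref.std(ddof=0))
    if sd == 0:
        raise DegenerateInputError("zero-variance dF/F; Z-score undefined")
    return DffSeries(t=raw.t, f_o=f_o, dff=dff, z=(dff - mu) / sd)


def process(raw: PhotometryRaw,
            fit_epoch: tuple[float, float] | None = None,
            z_epoch: tuple[float, float] | None = None,
            intercept: bool = True) -> DffSeries:
    """Full chain: isosbestic fit → ΔF/F → Z-score."""
    f_o, slope, icpt = fit_isosbestic(raw, fit_epoch, intercept)
    out = compute_dff_z(raw, f_o, z_epoch)
    out.fit_slope, out.fit_intercept = slope, icpt
    return out
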