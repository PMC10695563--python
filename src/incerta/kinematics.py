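"""Head-kinematics decomposition from two-marker video tracking.

Two colored markers — one over the nose, one between the ears — define the
*head midline*. From their per-frame pixel coordinates this module derives
the instantaneous movement measures used throughout the analysis chain:

* ``rotational`` speed: the frame-to-frame change of the midline angle,
  converted to a rim speed (cm/s) by multiplying the arc angle (radians)
  by a radius,
* ``linear`` / ``sideways`` speed: the ears-marker displacement projected
  onto / orthogonal to the head midline (cosine / sine of the angle between
  displacement and midline),
* ``translational`` = |linear| + |sideways|,
* ``overall`` = rotational + translational,
* head-angle ``bias``: accumulated signed change of the midline angle,
  zeroed at a reference frame (direction of turning).

All speeds are per-frame quantities in cm/s; the first frame of every
difference-based series is 0 by convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateInputError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerTrack",
    "KinematicsSeries",
    "calibrate",
    "uncalibrate",
    "head_midline_angle",
    "rotational_speed",
    "linear_and_sideways_speed",
    "head_bias",
    "compute_kinematics",
]


@dataclass
class MarkerTrack:
    """Per-frame nose/ears marker coordinates with timing and calibration.

    Coordinates are in pixels until :func:`calibrate` is applied, after
    which they are in cm and ``calibrated`` is True.
    """

    t: np.ndarray                 # s, strictly increasing, one per frame
    nose: np.ndarray              # (n, 2)
    ears: np.ndarray              # (n, 2)
    fps: float
    px_per_cm: float = 1.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.nose = np.asarray(self.nose, dtype=float).reshape(-1, 2)
        self.ears = np.asarray(self.ears, dtype=float).reshape(-1, 2)
        if not (len(self.t) == len(self.nose) == len(self.ears)):
            raise SchemaError("t, nose and ears must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise SchemaError(f"timestamps not strictly increasing at row {bad}")
        if self.px_per_cm <= 0:
            raise SchemaError("px_per_cm must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class KinematicsSeries:
    """Per-frame speed components and head orientation.

    ``linear_signed`` / ``sideways_signed`` keep the direction of the
    projection (forward vs backward, left vs right); the exported speed
    series ``linear``/``sideways`` are their magnitudes, so the identities
    ``translational == linear + sideways`` and
    ``overall == rotational + translational`` hold exactly at every frame.
    """

    t: np.ndarray
    fps: float
    head_angle: np.ndarray        # deg, unwrapped
    rotational: np.ndarray        # cm/s, >= 0
    linear_signed: np.ndarray     # cm/s, signed
    sideways_signed: np.ndarray   # cm/s, signed
    linear: np.ndarray = field(init=False)
    sideways: np.ndarray = field(init=False)
    translational: np.ndarray = field(init=False)
    overall: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.linear = np.abs(self.linear_signed)
        self.sideways = np.abs(self.sideways_signed)
        self.translational = self.linear + self.sideways
        self.overall = self.rotational + self.translational


def calibrate(track: MarkerTrack, px_per_cm: float | None = None) -> MarkerTrack:
    """Convert pixel coordinates to cm. Calibrating twice is an error."""
    if track.calibrated:
        raise DegenerateInputError("track is already calibrated")
    s = track.px_per_cm if px_per_cm is None else px_per_cm
    if s <= 0:
        raise SchemaError("px_per_cm must be positive")
    return replace(track, nose=track.nose / s, ears=track.ears / s,
                   px_per_cm=s, calibrated=True)


def uncalibrate(track: MarkerTrack) -> MarkerTrack:
    """Inverse of :func:`calibrate` (restores pixel coordinates)."""
    if not track.calibrated:
        raise DegenerateInputError("track is not calibrated")
    s = track.px_per_cm
    return replace(track, nose=track.nose * s, ears=track.ears * s,
                   calibrated=False)


def head_midline_angle(track: MarkerTrack) -> np.ndarray:
    """Orientation (deg) of the ears→nose vector, unwrapped across ±180°.

    Counter-clockwise positive; nose on the +x side of the ears is 0°.
    Frames where the two markers coincide are flagged, linearly
    interpolated from the neighbouring frames, and a warning is logged.
    """
    v = track.nose - track.ears
    coincident = np.hypot(v[:, 0], v[:, 1]) == 0.0
    if coincident.all():
        raise DegenerateInputError("markers coincide in every frame")
    ang = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    if coincident.any():
        n_bad = int(coincident.sum())
        warnings.warn(f"{n_bad} frame(s) with coincident markers interpolated",
                      stacklevel=2)
        logger.warning("interpolating %d coincident-marker frames", n_bad)
        good = ~coincident
        ang[coincident] = np.interp(track.t[coincident], track.t[good], ang[good])
    return np.degrees(np.unwrap(np.radians(ang)))


def rotational_speed(angles: np.ndarray, radius: float, fps: float) -> np.ndarray:
    """Rim speed (cm/s) of the head rotation.

    Per frame: |Δangle| in radians × radius (cm) × fps. The first frame
    is 0. Invariant to the frame rate for a fixed underlying rotation.
    """
    if radius <= 0:
        raise DegenerateInputError("radius must be positive")
    angles = np.asarray(angles, dtype=float)
    out = np.zeros_like(angles)
    out[1:] = np.abs(np.diff(np.radians(angles))) * radius * fps
    return out


def linear_and_sideways_speed(
    track: MarkerTrack, angles: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Signed linear (along-midline) and sideways (orthogonal) speeds, cm/s.

    The ears-marker displacement between succeeding frames is projected on
    the head midline of the earlier frame: linear = d·cos(φ)·fps and
    sideways = d·sin(φ)·fps, φ being the angle between the displacement
    vector and the midline. Zero displacement gives 0 for both (φ is
    undefined there; 0 by convention). Requires a calibrated track.
    """
    if not track.calibrated:
        raise DegenerateInputError("track must be calibrated to cm first")
    if angles is None:
        angles = head_midline_angle(track)
    d = np.diff(track.ears, axis=0)                      # cm per frame
    th = np.radians(angles[:-1])
    mid = np.stack([np.cos(th), np.sin(th)], axis=1)     # unit midline vector
    lin = np.zeros(len(track))
    side = np.zeros(len(track))
    lin[1:] = (d * mid).sum(axis=1) * track.fps
    side[1:] = (d[:, 1] * mid[:, 0] - d[:, 0] * mid[:, 1]) * track.fps
    return lin, side


def head_bias(angles: np.ndarray, zero_frame: int = 0) -> np.ndarray:
    """Accumulated signed change in head angle (deg), zeroed at a frame.

    Equivalent to the cumulative sum of per-frame Δangle, offset so the
    value at ``zero_frame`` is 0 (telescoping sum of an unwrapped series).
    """
    angles = np.asarray(angles, dtype=float)
    if not (-len(angles) <= zero_frame < len(angles)):
        raise IndexError(f"zero_frame {zero_frame} out of range")
    return angles - angles[zero_frame]


def default_radius(track: MarkerTrack) -> float:
    """Half the mean nose–ears distance (cm), the default rotation radius."""
    d = np.hypot(*(track.nose - track.ears).T)
    r = float(d.mean()) / 2.0
    if not track.calibrated:
        r /= track.px_per_cm
    if r <= 0:
        raise DegenerateInputError("markers coincide; radius undefined")
    return r


def compute_kinematics(track: MarkerTrack, radius: float | None = None,
                       smooth_boxcar: int = 0) -> KinematicsSeries:
    """Full decomposition of a marker track into speed components.

    ``radius`` defaults to half the session-mean inter-marker distance.
    ``smooth_boxcar`` (frames) optionally boxcar-smooths each speed series;
    off (0) by default.
    """
    if not track.calibrated:
        track = calibrate(track)
    if radius is None:
        radius = default_radius(track)
    ang = head_midline_angle(track)
    rot = rotational_speed(ang, radius, track.fps)
    lin, side = linear_and_sideways_speed(track, ang)
    if smooth_boxcar and smooth_boxcar > 1:
        k = np.ones(smooth_boxcar) / smooth_boxcar
        rot = np.convolve(rot, k, mode="same")
        lin = np.convolve(lin, k, mode="same")
        side = np.convolve(side, k, mode="same")
    return KinematicsSeries(t=track.t, fps=track.fps, head_angle=ang,
                            rotational=rot, linear_signed=lin,
                            sideways_signed=side)
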