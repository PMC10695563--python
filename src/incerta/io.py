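"""File formats: CSV tables for continuous data, JSON for discrete data.

CSV files are header-keyed (column order is irrelevant) and carry a JSON
metadata sidecar ``<stem>.meta.json`` for scalar attributes (fps,
calibration, procedure ...). Round trips are lossless to 6 decimal digits.
Schema violations raise :class:`~incerta.errors.SchemaError` naming the
offending field or row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .behavior import TrialTable
from .errors import SchemaError
from .events import EventSet
from .kinematics import MarkerTrack
from .photometry import PhotometryRaw
from .units import SpikeTrain

__all__ = [
    "write_marker_track", "read_marker_track",
    "write_photometry", "read_photometry",
    "write_spike_trains", "read_spike_trains",
    "write_trial_table", "read_trial_table",
    "write_event_set", "read_event_set",
    "write_results", "read_results",
]

_PRECISION = 6

MARKER_COLUMNS = ("t", "nose_x", "nose_y", "ears_x", "ears_y")
PHOTOMETRY_COLUMNS = ("t", "f_signal", "f_control")


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...],
                     what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _require_monotone(t: np.ndarray, what: str) -> None:
    if len(t) > 1:
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise SchemaError(
                f"{what}: timestamps not strictly increasing at row "
                f"{int(bad[0]) + 1}")


def _round(x: Any) -> Any:
    if isinstance(x, (np.floating, float)):
        return round(float(x), _PRECISION)
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, np.ndarray):
        return np.round(x, _PRECISION).tolist()
    if isinstance(x, dict):
        return {k: _round(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v) for v in x]
    if isinstance(x, np.bool_):
        return bool(x)
    return x


# -------------------------------------------------------------- MarkerTrack

def write_marker_track(track: MarkerTrack, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "t": track.t,
        "nose_x": track.nose[:, 0], "nose_y": track.nose[:, 1],
        "ears_x": track.ears[:, 0], "ears_y": track.ears[:, 1],
    })
    df.round(_PRECISION).to_csv(path, index=False)
    meta = {"fps": track.fps, "px_per_cm": track.px_per_cm,
            "calibrated": track.calibrated}
    _meta_path(path).write_text(json.dumps(_round(meta), indent=1))
    return path


def read_marker_track(path: str | Path) -> MarkerTrack:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, MARKER_COLUMNS, "marker track")
    t = df["t"].to_numpy(dtype=float)
    _require_monotone(t, "marker track")
    mp = _meta_path(path)
    meta = json.loads(mp.read_text()) if mp.exists() else {}
    return MarkerTrack(
        t=t,
        nose=df[["nose_x", "nose_y"]].to_numpy(dtype=float),
        ears=df[["ears_x", "ears_y"]].to_numpy(dtype=float),
        fps=float(meta.get("fps", 1.0 / np.median(np.diff(t)))),
        px_per_cm=float(meta.get("px_per_cm", 1.0)),
        calibrated=bool(meta.get("calibrated", False)),
    )


# ------------------------------------------------------------ PhotometryRaw

def write_photometry(raw: PhotometryRaw, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"t": raw.t, "f_signal": raw.f_signal,
                  "f_control": raw.f_control}
                 ).round(_PRECISION).to_csv(path, index=False)
    return path


def read_photometry(path: str | Path) -> PhotometryRaw:
    df = pd.read_csv(path)
    _require_columns(df, PHOTOMETRY_COLUMNS, "photometry")
    t = df["t"].to_numpy(dtype=float)
    _require_monotone(t, "photometry")
    return PhotometryRaw(t=t,
                         f_signal=df["f_signal"].to_numpy(dtype=float),
                         f_control=df["f_control"].to_numpy(dtype=float))


# -------------------------------------------------------------- SpikeTrains

def write_spike_trains(trains: list[SpikeTrain], path: str | Path) -> Path:
    path = Path(path)
    payload = [{"unit_id": tr.unit_id,
                "spike_times": _round(tr.spike_times),
                "depth_um": tr.depth_um} for tr in trains]
    path.write_text(json.dumps(payload))
    return path


def read_spike_trains(path: str | Path) -> list[SpikeTrain]:
    payload = json.loads(Path(path).read_text())
    out = []
    for i, rec in enumerate(payload):
        if "unit_id" not in rec or "spike_times" not in rec:
            raise SchemaError(f"spike train record {i}: missing "
                              "'unit_id' or 'spike_times'")
        st = np.asarray(rec["spike_times"], dtype=float)
        if st.size and np.any(np.diff(st) < 0):
            raise SchemaError(f"spike train {rec['unit_id']}: "
                              "times not sorted")
        out.append(SpikeTrain(unit_id=str(rec["unit_id"]), spike_times=st,
                              depth_um=rec.get("depth_um")))
    return out


# --------------------------------------------------------------- TrialTable

def write_trial_table(trials: TrialTable, path: str | Path,
                      ground_truth: list[str] | None = None) -> Path:
    path = Path(path)
    payload = {"procedure": trials.procedure,
               "trials": _round(trials.df.to_dict(orient="records"))}
    path.write_text(json.dumps(payload))
    if ground_truth is not None:
        _meta_path(path).write_text(
            json.dumps({"true_outcomes": list(ground_truth)}))
    return path


def read_trial_table(path: str | Path) -> TrialTable:
    payload = json.loads(Path(path).read_text())
    if "procedure" not in payload or "trials" not in payload:
        raise SchemaError("trial table: missing 'procedure' or 'trials'")
    df = pd.DataFrame(payload["trials"])
    if "response_latency" in df.columns:
        df["response_latency"] = df["response_latency"].astype(float)
    return TrialTable(df, procedure=payload["procedure"])


def read_ground_truth(path: str | Path) -> list[str]:
    mp = _meta_path(Path(path))
    if not mp.exists():
        raise SchemaError(f"no ground-truth sidecar {mp}")
    return json.loads(mp.read_text())["true_outcomes"]


# ----------------------------------------------------------------- EventSet

def write_event_set(events: EventSet, path: str | Path) -> Path:
    path = Path(path)
    payload = {"times": _round(events.times),
               "indices": events.indices.tolist(),
               "amplitudes": _round(events.amplitudes),
               "direction": events.direction.tolist(),
               "flags": {k: v.tolist() for k, v in events.flags.items()}}
    path.write_text(json.dumps(payload))
    return path


def read_event_set(path: str | Path) -> EventSet:
    payload = json.loads(Path(path).read_text())
    for key in ("times", "indices", "amplitudes", "direction"):
        if key not in payload:
            raise SchemaError(f"event set: missing '{key}'")
    return EventSet(
        times=np.asarray(payload["times"], dtype=float),
        indices=np.asarray(payload["indices"], dtype=int),
        amplitudes=np.asarray(payload["amplitudes"], dtype=float),
        direction=np.asarray(payload["direction"], dtype=object),
        flags={k: np.asarray(v, dtype=bool)
               for k, v in payload.get("flags", {}).items()},
    )


# ------------------------------------------------------------------ results

def write_results(results: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_round(results), indent=1, allow_nan=True))
    return path


def read_results(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
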