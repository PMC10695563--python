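"""Scoring of signaled active-avoidance sessions (procedures AA1–AA4).

A trial presents an auditory conditioned stimulus (CS) for an *avoidance
interval*; shuttling to the other compartment within that interval is an
**avoid** (the CS ends, no harm). Failing to avoid triggers the
unconditioned stimulus (foot-shock + white noise) for up to a 10-s escape
interval, and the ensuing shuttle is an **escape**. Procedures:

* AA1 — single CS (8 kHz), 7-s avoidance interval, intertrial crossings
  (ITCs) have no consequence.
* AA2 — as AA1 but ITCs are punished (unsignaled passive avoidance
  between trials).
* AA3 — CS discrimination: CS1 (8 kHz) drives active avoidance, CS2
  (4 kHz) requires *signaled passive avoidance* — shuttling during the
  CS2 avoidance interval is an error and is punished.
* AA4 — three CSs (8/10/12 kHz) signal avoidance intervals of 4, 7 and
  15 s; ITCs are punished. Trained animals scale their response latency
  to the signaled interval.

Performance variables: % avoids per CS, avoidance latency (mean response
latency over successful avoid trials only) and the ITC count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, SchemaError

__all__ = ["StimulusSpec", "TrialTable", "PROCEDURES",
           "score_trial", "score_session", "latency_by_cs"]


@dataclass(frozen=True)
class StimulusSpec:
    """One CS of a procedure: tone parameters and trial contingencies."""

    cs_id: str
    frequency_khz: float
    spl_db: float
    avoidance_interval: float      # s, one of {4, 7, 15}
    punish_itc: bool = False
    passive_cs: bool = False

    def __post_init__(self) -> None:
        if self.avoidance_interval not in (4.0, 7.0, 15.0):
            raise SchemaError("avoidance_interval must be 4, 7 or 15 s")
        if self.frequency_khz <= 0:
            raise SchemaError("frequency must be positive")


#: CS roster per procedure (tone frequency kHz, SPL dB, interval s)
PROCEDURES: dict[str, dict[str, StimulusSpec]] = {
    "AA1": {"CS1": StimulusSpec("CS1", 8.0, 85.0, 7.0)},
    "AA2": {"CS1": StimulusSpec("CS1", 8.0, 85.0, 7.0, punish_itc=True)},
    "AA3": {"CS1": StimulusSpec("CS1", 8.0, 85.0, 7.0),
            "CS2": StimulusSpec("CS2", 4.0, 70.0, 7.0, passive_cs=True)},
    "AA4": {"CS1": StimulusSpec("CS1", 8.0, 81.0, 4.0, punish_itc=True),
            "CS2": StimulusSpec("CS2", 10.0, 82.0, 7.0, punish_itc=True),
            "CS3": StimulusSpec("CS3", 12.0, 82.0, 15.0, punish_itc=True)},
}

_COLUMNS = ("trial", "cs_id", "cs_onset", "avoidance_interval",
            "response_latency", "itc_times", "intertrial_interval")


@dataclass
class TrialTable:
    """Per-trial observables of one avoidance session."""

    df: pd.DataFrame
    procedure: str = "AA1"

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"trial table missing column(s) {missing}")
        if self.procedure not in PROCEDURES:
            raise SchemaError(f"unknown procedure {self.procedure!r}")
        onsets = self.df["cs_onset"].to_numpy(dtype=float)
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
            raise SchemaError(f"cs_onset not strictly increasing at row {bad}")
        known = set(PROCEDURES[self.procedure])
        unknown = set(self.df["cs_id"]) - known
        if unknown:
            raise SchemaError(f"unknown cs_id(s) {sorted(unknown)} "
                              f"for procedure {self.procedure}")

    @classmethod
    def from_records(cls, rows: list[dict[str, Any]],
                     procedure: str = "AA1") -> "TrialTable":
        return cls(pd.DataFrame(rows, columns=list(_COLUMNS)), procedure)

    def __len__(self) -> int:
        return len(self.df)


def score_trial(cs: StimulusSpec, response_latency: float) -> str:
    """Outcome of one trial from its response latency.

    Active CS: a response within the avoidance interval is an ``avoid``,
    later is an ``escape``. Passive CS (AA3-CS2): any shuttle during the
    avoidance interval is a ``passive_fail``; withholding for the full
    interval is a ``passive_avoid``.
    """
    responded = np.isfinite(response_latency)
    if cs.passive_cs:
        if responded and response_latency <= cs.avoidance_interval:
            return "passive_fail"
        return "passive_avoid"
    if not responded:
        raise DegenerateInputError(
            f"active CS {cs.cs_id}: a response latency is required "
            "(the US forces an escape)")
    return "avoid" if response_latency <= cs.avoidance_interval else "escape"


def score_session(trials: TrialTable,
                  procedure: str | None = None) -> dict[str, Any]:
    """Per-CS performance summary of one session.

    Returns outcomes per trial plus, per CS: trial count, % avoids
    (% passive avoids for a passive CS), mean avoidance latency over avoid
    trials only, and the session ITC total.
    """
    proc = procedure or trials.procedure
    if proc not in PROCEDURES:
        raise SchemaError(f"unknown procedure {proc!r}")
    spec = PROCEDURES[proc]
    df = trials.df
    outcomes = [
        score_trial(spec[row.cs_id], row.response_latency)
        for row in df.itertuples()
    ]
    per_cs: dict[str, dict[str, Any]] = {}
    for cs_id, st in spec.items():
        m = (df["cs_id"] == cs_id).to_numpy()
        n = int(m.sum())
        if n == 0:
            per_cs[cs_id] = {"n_trials": 0}
            continue
        out = np.asarray(outcomes, dtype=object)[m]
        lat = df.loc[m, "response_latency"].to_numpy(dtype=float)
        if st.passive_cs:
            n_ok = int((out == "passive_avoid").sum())
            per_cs[cs_id] = {
                "n_trials": n,
                "pct_passive_avoids": 100.0 * n_ok / n,
                "n_passive_fails": n - n_ok,
            }
        else:
            avoid = out == "avoid"
            n_avoid = int(avoid.sum())
            per_cs[cs_id] = {
                "n_trials": n,
                "n_avoids": n_avoid,
                "n_escapes": n - n_avoid,
                "pct_avoids": 100.0 * n_avoid / n,
                "avoidance_latency": (float(lat[avoid].mean())
                                      if n_avoid else np.nan),
            }
    n_itc = int(df["itc_times"].map(len).sum())
    return {"procedure": proc, "outcomes": outcomes, "per_cs": per_cs,
            "n_itc": n_itc}


def latency_by_cs(trials: TrialTable, n_resamples: int = 2000,
                  seed: int = 0) -> dict[str, Any]:
    """Per-CS avoidance-latency distributions with pairwise bootstrap tests.

    Only successful avoid trials enter the latency distributions (escape
    latencies are forced by the US). With a single CS the contrasts are
    skipped; empty CS cells are reported as missing.
    """
    from .resampling import bootstrap_diff

    proc = trials.procedure
    spec = PROCEDURES[proc]
    df = trials.df
    lats: dict[str, np.ndarray] = {}
    for cs_id, st in spec.items():
        if st.passive_cs:
            continue
        m = (df["cs_id"] == cs_id).to_numpy()
        lat = df.loc[m, "response_latency"].to_numpy(dtype=float)
        ok = np.isfinite(lat) & (lat <= st.avoidance_interval)
        lats[cs_id] = lat[ok]
    summary = {cs: {"n": int(v.size),
                    "mean": float(v.mean()) if v.size else np.nan,
                    "median": float(np.median(v)) if v.size else np.nan}
               for cs, v in lats.items()}
    contrasts: dict[str, float] = {}
    ids = [c for c in sorted(lats) if lats[c].size >= 3]
    if len(ids) >= 2:
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                contrasts[f"{a}-vs-{b}"] = bootstrap_diff(
                    lats[a], lats[b], n_resamples=n_resamples, seed=seed)
    missing = [c for c in lats if lats[c].size == 0]
    return {"latencies": lats, "summary": summary,
            "contrasts": contrasts, "missing": missing}
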