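"""Single-unit analysis: movement-aligned PSTHs, rate–speed coupling,
sensory responses, and the four-class PCA classification.

Units recorded in the zona incerta fall into two major groups by their
peri-movement firing: Class1 activates robustly during movement and splits
by baseline rate into Class1a (high) and Class1b (low); Class2 splits by
the sign of its peri-movement modulation into Class2a (mildly suppressed)
and Class2b (weakly activated). The classifier reproduces that two-step
logic: PCA on baseline-normalized PSTHs, a 2-means split of the PC scores
into movement-activated vs not, then the two within-group splits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import DegenerateInputError
from .events import EventSet

logger = logging.getLogger(__name__)

__all__ = ["SpikeTrain", "PSTHMatrix", "UnitClass", "build_psth",
           "classify_units", "rate_speed_correlation", "sensory_response"]

CLASS_LABELS = ("Class1a", "Class1b", "Class2a", "Class2b")


@dataclass
class SpikeTrain:
    """Spike times (s) of one well-isolated unit."""

    unit_id: str
    spike_times: np.ndarray
    depth_um: float | None = None
    t_start: float | None = None   # recording support, if known
    t_stop: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(self.spike_times < 0):
                raise DegenerateInputError("negative spike times")
            if np.any(np.diff(self.spike_times) < 0):
                raise DegenerateInputError("spike times must be sorted")

    def __len__(self) -> int:
        return len(self.spike_times)

    def mean_rate(self, t0: float, t1: float) -> float:
        """Mean firing rate (spikes/s) in [t0, t1)."""
        if t1 <= t0:
            raise DegenerateInputError("empty rate interval")
        n = np.count_nonzero((self.spike_times >= t0) & (self.spike_times < t1))
        return n / (t1 - t0)


@dataclass
class PSTHMatrix:
    """Event-aligned mean firing rates, units × bins (spikes/s)."""

    rates: np.ndarray          # (n_units, n_bins)
    bin_width: float           # s
    window: tuple[float, float]  # (pre, post) s around the event, pre < 0
    unit_ids: list[str]
    n_events: np.ndarray       # events actually used per unit

    @property
    def bin_centers(self) -> np.ndarray:
        pre, post = self.window
        n_bins = self.rates.shape[1]
        return pre + (np.arange(n_bins) + 0.5) * self.bin_width

    def __post_init__(self) -> None:
        pre, post = self.window
        expect = int(round((post - pre) / self.bin_width))
        if self.rates.shape[1] != expect:
            raise DegenerateInputError("bin count inconsistent with window")
        if np.any(self.rates < 0):
            raise DegenerateInputError("negative PSTH rates")


@dataclass
class UnitClass:
    """Classification result for one unit."""

    unit_id: str
    label: str
    pc_scores: np.ndarray
    baseline_rate: float       # spikes/s
    movement_modulation: float # peri-event minus baseline rate, spikes/s


def build_psth(trains: list[SpikeTrain], events: EventSet | np.ndarray,
               window: tuple[float, float] = (-3.0, 3.0),
               bin_width: float = 0.1) -> PSTHMatrix:
    """Per-unit mean firing rate per bin across events.

    ``window`` is (pre, post) around each event time (pre < 0 <= post).
    A unit's usable events are those whose window lies within its recording
    support (``t_start``/``t_stop`` when recorded; otherwise every event is
    assumed covered). Units with zero usable events are excluded and
    logged; silent units contribute an all-zero row.
    """
    ev = events.times if isinstance(events, EventSet) else np.asarray(events, float)
    if ev.size == 0:
        raise DegenerateInputError("empty event set")
    pre, post = window
    if not (pre < 0.0 <= post):
        raise DegenerateInputError("window must cover time zero")
    n_bins = int(round((post - pre) / bin_width))
    edges = pre + np.arange(n_bins + 1) * bin_width
    rows, ids, counts = [], [], []
    for tr in trains:
        if tr.t_start is not None and tr.t_stop is not None:
            usable = ev[(ev + pre >= tr.t_start) & (ev + post <= tr.t_stop)]
        else:
            usable = ev
        if usable.size == 0:
            logger.warning("unit %s: no events within support; excluded",
                           tr.unit_id)
            continue
        # spike times relative to every usable event
        rel = tr.spike_times[None, :] - usable[:, None]
        rel = rel[(rel >= pre) & (rel < post)]
        hist, _ = np.histogram(rel, bins=edges)
        rows.append(hist / (usable.size * bin_width))
        ids.append(tr.unit_id)
        counts.append(usable.size)
    if not rows:
        raise DegenerateInputError("no unit has events within support")
    return PSTHMatrix(rates=np.asarray(rows), bin_width=bin_width,
                      window=window, unit_ids=ids,
                      n_events=np.asarray(counts))


def _two_means_1d(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """2-cluster 1-D k-means; returns boolean mask of the high cluster."""
    km = KMeans(n_clusters=2, n_init=50, random_state=seed)
    lab = km.fit_predict(values.reshape(-1, 1))
    hi = int(np.argmax(km.cluster_centers_.ravel()))
    return lab == hi


def classify_units(psths: PSTHMatrix,
                   baseline_window: tuple[float, float] = (-3.0, -1.0),
                   peri_window: tuple[float, float] = (-0.5, 0.5),
                   n_components: int = 5,
                   variance_target: float = 0.80,
                   seed: int = 0) -> list[UnitClass]:
    """Two-step four-class assignment from movement-aligned PSTHs.

    Step 1: each PSTH is baseline-subtracted and scaled by its own SD,
    PCA retains the leading components explaining ≥ ``variance_target`` of
    the variance (capped at ``n_components``), and a 2-means split of the
    scores separates movement-activated units (Class1: higher peri-event
    than baseline rate) from the rest (Class2).

    Step 2: Class1 splits into 1a/1b by a 2-means threshold on log
    baseline rate; Class2 splits into 2a/2b by the sign of the raw
    peri-event rate modulation (suppressed vs weakly activated).
    """
    R = psths.rates
    n_units = R.shape[0]
    if n_units < 8:
        raise DegenerateInputError("need at least 8 units to classify")
    centers = psths.bin_centers
    base_m = (centers >= baseline_window[0]) & (centers < baseline_window[1])
    peri_m = (centers >= peri_window[0]) & (centers < peri_window[1])
    if not base_m.any() or not peri_m.any():
        raise DegenerateInputError("baseline/peri window outside PSTH grid")
    baseline = R[:, base_m].mean(axis=1)
    peri = R[:, peri_m].mean(axis=1)
    modulation = peri - baseline

    # baseline z-score per unit: movement modulation in units of each
    # unit's own baseline variability (invariant to a common rescaling)
    base_sd = R[:, base_m].std(axis=1, ddof=0)
    if np.all(R.std(axis=1) == 0):
        raise DegenerateInputError(
            "all PSTHs are flat; no movement structure to classify")
    floor = np.median(base_sd[base_sd > 0]) * 0.1 if np.any(base_sd > 0) else 1.0
    norm = (R - baseline[:, None]) / np.maximum(base_sd, floor)[:, None]

    k = min(n_components, n_units - 1, norm.shape[1])
    pca = PCA(n_components=k, random_state=seed)
    scores = pca.fit_transform(norm)
    evr = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(evr, variance_target) + 1)
    keep = min(keep, k)
    if keep < 1:
        raise DegenerateInputError("degenerate PCA on PSTH matrix")
    if evr[keep - 1] < variance_target:
        warnings.warn(f"retained {keep} PCs explain only {evr[keep-1]:.0%} "
                      "of variance", stacklevel=2)
    scores = scores[:, :keep]

    km = KMeans(n_clusters=2, n_init=50, random_state=seed)
    lab = km.fit_predict(scores)
    if len(np.unique(lab)) < 2:
        raise DegenerateInputError("units form a single cluster; "
                                   "classification refused")
    # normalized peri-event elevation decides which cluster is Class1
    norm_peri = norm[:, peri_m].mean(axis=1)
    class1 = lab == int(np.argmax([norm_peri[lab == c].mean() for c in (0, 1)]))

    labels = np.empty(n_units, dtype=object)
    if class1.sum() == 1:
        # a lone movement-activated unit: rate threshold from the whole
        # population instead of a within-group split
        i = int(np.flatnonzero(class1)[0])
        labels[i] = ("Class1a" if baseline[i] >= np.median(baseline)
                     else "Class1b")
    elif class1.any():
        hi = _two_means_1d(np.log10(baseline[class1] + 0.1), seed=seed)
        labels[np.flatnonzero(class1)[hi]] = "Class1a"
        labels[np.flatnonzero(class1)[~hi]] = "Class1b"
    if (~class1).any():
        idx2 = np.flatnonzero(~class1)
        labels[idx2[modulation[idx2] < 0]] = "Class2a"
        labels[idx2[modulation[idx2] >= 0]] = "Class2b"

    return [UnitClass(unit_id=psths.unit_ids[i], label=labels[i],
                      pc_scores=scores[i], baseline_rate=float(baseline[i]),
                      movement_modulation=float(modulation[i]))
            for i in range(n_units)]


def rate_speed_correlation(train: SpikeTrain, t: np.ndarray,
                           speed: np.ndarray,
                           integrate_window: float = 0.2
                           ) -> tuple[float, float]:
    """Linear fit between firing rate and movement speed.

    Both variables are averaged in nonoverlapping windows (200 ms default):
    spike counts per window / window length vs mean speed. Returns Pearson
    r and the least-squares slope ((spikes/s) per (cm/s)).
    """
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    lo = max(t[0], train.spike_times[0] if len(train) else t[0])
    hi = min(t[-1], train.spike_times[-1] if len(train) else t[-1])
    if hi - lo < 10 * integrate_window:
        raise DegenerateInputError("fewer than 10 windows of common support")
    edges = np.arange(lo, hi, integrate_window)
    if len(edges) < 11:
        raise DegenerateInputError("fewer than 10 windows of common support")
    counts, _ = np.histogram(train.spike_times, bins=edges)
    rate = counts / integrate_window
    m = (t >= lo) & (t < edges[-1])
    which = np.clip(np.digitize(t[m], edges) - 1, 0, len(edges) - 2)
    cnt = np.bincount(which, minlength=len(edges) - 1)
    good = cnt > 0
    sp = np.bincount(which, weights=speed[m], minlength=len(edges) - 1)
    sp = sp[good] / cnt[good]
    rate = rate[good]
    if np.ptp(sp) == 0:
        raise DegenerateInputError("constant speed; correlation undefined")
    if np.ptp(rate) == 0:
        raise DegenerateInputError("constant rate; correlation undefined")
    fit = stats.linregress(sp, rate)
    return float(fit.rvalue), float(fit.slope)


@dataclass
class SensoryResponse:
    """Evoked rate change of one unit with its bootstrap CI."""

    unit_id: str
    evoked: float            # mean response-window minus baseline rate
    ci: tuple[float, float]  # bootstrap 95% CI of the difference
    responsive: bool         # CI excludes 0


def sensory_response(train: SpikeTrain, stim_times: np.ndarray,
                     response_window: tuple[float, float] = (0.0, 1.5),
                     baseline_window: tuple[float, float] = (-1.5, 0.0),
                     n_boot: int = 2000, seed: int = 0) -> SensoryResponse:
    """Stimulus-evoked firing-rate change with a bootstrap CI.

    Per stimulus: rate in the response window minus rate in the baseline
    window; the unit is *responsive* when the 95% percentile-bootstrap CI
    of the mean difference excludes 0.
    """
    stim = np.asarray(stim_times, dtype=float)
    if stim.size < 10:
        raise DegenerateInputError("need at least 10 stimuli")
    b0, b1 = baseline_window
    r0, r1 = response_window
    if b1 > r0:
        raise DegenerateInputError("baseline window overlaps response window")
    st = train.spike_times
    diffs = np.empty(stim.size)
    for i, s in enumerate(stim):
        n_r = np.count_nonzero((st >= s + r0) & (st < s + r1))
        n_b = np.count_nonzero((st >= s + b0) & (st < s + b1))
        diffs[i] = n_r / (r1 - r0) - n_b / (b1 - b0)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, stim.size, size=(n_boot, stim.size))
    boot = diffs[idx].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    evoked = float(diffs.mean())
    # tolerance guards against CI bounds that are zero up to rounding
    eps = 1e-9 * max(1.0, float(np.abs(diffs).max(initial=0.0)))
    responsive = bool(lo > eps or hi < -eps)
    return SensoryResponse(unit_id=train.unit_id, evoked=evoked,
                           ci=(float(lo), float(hi)), responsive=responsive)
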