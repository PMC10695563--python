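"""Resampling statistics: pooled bootstrap difference test and the
shuffle-control for windowed correlations.

The bootstrap difference test pools the two samples (ignoring group
membership), resamples groups of the original sizes with replacement
1000–10,000 times, and reports the probability that a mean difference at
least as large as the observed one arises by chance (two-sided, on the
absolute difference, with add-one Monte-Carlo smoothing so p is never 0).

The shuffle control recomputes a windowed correlation after permuting one
variable's windowed values, giving a null band against which the observed
correlation is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = ["bootstrap_diff", "windowed_pairs", "shuffle_control",
           "ShuffleResult"]


def bootstrap_diff(a, b, n_resamples: int = 2000, seed: int = 0,
                   return_null: bool = False):
    """Two-sided pooled-bootstrap p-value for a difference in means.

    Values from both groups are pooled irrespective of group, resampled
    with replacement into groups of the original sizes, and the p-value is
    the fraction of resamples whose absolute mean difference is at least
    the observed one, smoothed as (k+1)/(n+1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("empty sample")
    if a.size < 3 or b.size < 3:
        raise DegenerateInputError("need at least 3 values per group")
    if not (1000 <= n_resamples <= 10000):
        raise DegenerateInputError("n_resamples must lie in [1000, 10000]")
    rng = np.random.default_rng(seed)
    observed = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    draws = pool[idx]
    null = np.abs(draws[:, :na].mean(axis=1) - draws[:, na:].mean(axis=1))
    k = int((null >= observed - 1e-12).sum())
    p = (k + 1) / (n_resamples + 1)
    return (p, null) if return_null else p


def windowed_pairs(t: np.ndarray, x: np.ndarray, y: np.ndarray,
                   integrate_window: float = 0.2
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Average two co-sampled series in nonoverlapping time windows.

    The windowed means (200-ms default) are the inputs to the linear-fit
    correlations used throughout: they remove sampling-rate dependence and
    within-window autocorrelation.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(t) == len(x) == len(y)):
        raise DegenerateInputError("series lengths differ")
    edges = np.arange(t[0], t[-1] + 1e-12, integrate_window)
    if len(edges) < 2:
        raise DegenerateInputError("support shorter than one window")
    which = np.digitize(t, edges) - 1
    nw = len(edges) - 1
    which = np.clip(which, 0, nw - 1)
    counts = np.bincount(which, minlength=nw)
    good = counts > 0
    xs = np.bincount(which, weights=x, minlength=nw)[good] / counts[good]
    ys = np.bincount(which, weights=y, minlength=nw)[good] / counts[good]
    if xs.size < 10:
        raise DegenerateInputError("fewer than 10 windows in common support")
    return xs, ys


@dataclass
class ShuffleResult:
    """Observed windowed correlation against its shuffle-null band."""

    observed_r: float
    null_r: np.ndarray
    lo: float               # 2.5th percentile of the null
    hi: float               # 97.5th percentile of the null

    @property
    def outside_band(self) -> bool:
        return not (self.lo <= self.observed_r <= self.hi)


def shuffle_control(t, x, y, integrate_window: float = 0.2,
                    n_shuffles: int = 1000, seed: int = 0) -> ShuffleResult:
    """Windowed Pearson correlation with a permutation null.

    ``x`` and ``y`` are averaged in nonoverlapping windows; the null is
    built by permuting one variable's windowed values, destroying the
    temporal pairing while keeping both marginals.
    """
    xs, ys = windowed_pairs(t, x, y, integrate_window)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateInputError("zero-variance windowed series")
    rng = np.random.default_rng(seed)
    observed = float(stats.pearsonr(xs, ys).statistic)
    nw = xs.size
    xs_c = xs - xs.mean()
    ys_c = ys - ys.mean()
    denom = np.sqrt((xs_c @ xs_c) * (ys_c @ ys_c))
    perm = np.argsort(rng.random((n_shuffles, nw)), axis=1)
    null = (ys_c[perm] @ xs_c) / denom
    lo, hi = np.percentile(null, [2.5, 97.5])
    return ShuffleResult(observed_r=observed, null_r=null,
                         lo=float(lo), hi=float(hi))
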