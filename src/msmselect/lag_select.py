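"""Markov lag-time selection from the convergence of t2(tau).

The usual visual criterion — plot the implied timescales against the lag and
pick the smallest lag at which t2 has flattened — is codified as a gradient
threshold: for each bootstrap replicate the log-log gradient |d ln t2 / d ln
tau| is evaluated on the lag grid by central differences (one-sided at the
ends), the per-lag median over replicates is taken per trial, and the selected
lag tau* is the smallest grid lag at which the maximum of these medians over
all trials is below the threshold eps and stays below it for every larger
grid lag.  Absence of such a lag is a valid, flagged outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LagGrid", "timescale_gradient", "select_lag"]


@dataclass(frozen=True)
class LagGrid:
    """Increasing lag grid plus the dimensionless convergence threshold."""

    lags: tuple = (1, 11, 21, 31, 41, 51, 61, 71, 81, 91, 101)
    threshold: float = 0.1

    def __post_init__(self):
        lags = tuple(int(x) for x in self.lags)
        if len(lags) < 3:
            raise ValueError("need at least 3 lags")
        if any(b <= a for a, b in zip(lags, lags[1:])) or lags[0] <= 0:
            raise ValueError("lags must be strictly increasing and positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        object.__setattr__(self, "lags", lags)


def timescale_gradient(t2_curves: np.ndarray, lags) -> np.ndarray:
    """|d ln t2 / d ln tau| per replicate and lag, then the per-lag median.

    ``t2_curves`` is (replicates, lags) — bootstrap replicates of the t2
    curve; a 1-D array is treated as a single replicate.  NaN t2 values
    propagate to NaN gradients; the median ignores them.  Returns the per-lag
    median gradient (length = number of lags).
    """
    t2 = np.atleast_2d(np.asarray(t2_curves, dtype=float))
    lags = np.asarray(lags, dtype=float)
    if t2.shape[1] != lags.size:
        raise ValueError("curve length must match the lag grid")
    valid_cols = np.isfinite(t2).any(axis=0)
    if valid_cols.sum() < 2:
        raise ValueError("need at least 2 lags with valid t2")
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.log(t2)
    x = np.log(lags)
    grads = np.full_like(t2, np.nan)
    n = lags.size
    for j in range(n):
        if j == 0:
            grads[:, j] = (y[:, 1] - y[:, 0]) / (x[1] - x[0])
        elif j == n - 1:
            grads[:, j] = (y[:, -1] - y[:, -2]) / (x[-1] - x[-2])
        else:
            grads[:, j] = (y[:, j + 1] - y[:, j - 1]) / (x[j + 1] - x[j - 1])
    grads = np.abs(grads)
    with np.errstate(all="ignore"):
        return np.nanmedian(grads, axis=0)


def select_lag(gradients: np.ndarray, grid: LagGrid) -> int | None:
    """Smallest grid lag at which the max-over-trials median gradient is and
    remains below the threshold; None when never satisfied.

    ``gradients`` is (trials, lags) of per-trial median gradients (1-D for a
    single trial).  Lags where every trial is NaN never qualify.
    """
    g = np.atleast_2d(np.asarray(gradients, dtype=float))
    lags = np.asarray(grid.lags)
    if g.shape[1] != lags.size:
        raise ValueError("gradient table must match the lag grid")
    if g.shape[0] < 1:
        raise ValueError("need gradients for at least one trial")
    with np.errstate(all="ignore"):
        worst = np.nanmax(g, axis=0)
    ok = np.isfinite(worst) & (worst <= grid.threshold)
    # persistence: qualifies only if every larger lag also qualifies
    persistent = np.logical_and.accumulate(ok[::-1])[::-1]
    hits = np.flatnonzero(persistent)
    if hits.size == 0:
        return None
    return int(lags[hits[0]])
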