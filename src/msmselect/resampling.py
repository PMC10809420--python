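"""Subtrajectory bootstrap.

Uncertainty for every model observable is estimated the same way: trajectories
are split into contiguous, non-overlapping, equal-length subtrajectories
(treated as exchangeable independent units), N_b bootstrap data sets of the
same size are drawn with replacement, the estimator is applied to each, and
the point estimate / error bars are read off as the median and the 2.5% /
97.5% quantiles.  Replicate failures (estimators may legitimately fail on a
resample, e.g. disconnected count matrices) are counted, never fatal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = ["BootstrapPlan", "BootstrapSummary", "split_subtrajectories", "bootstrap_observable"]


@dataclass(frozen=True)
class BootstrapPlan:
    subtrajectory_length: int
    n_boot: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_boot < 2:
            raise ValueError("need at least 2 bootstrap samples")
        if self.subtrajectory_length < 2:
            raise ValueError("subtrajectory length must be >= 2")


@dataclass(frozen=True)
class BootstrapSummary:
    median: float
    ci_low: float
    ci_high: float
    n_valid: int

    def __post_init__(self):
        if self.n_valid > 0 and not (self.ci_low <= self.median <= self.ci_high):
            raise ValueError("quantiles out of order")


def split_subtrajectories(trajs: Sequence[np.ndarray], length: int) -> list[np.ndarray]:
    """Contiguous non-overlapping blocks of exactly ``length`` frames; trailing
    remainders shorter than ``length`` are dropped."""
    if length < 2:
        raise ValueError("length must be >= 2")
    out: list[np.ndarray] = []
    for t in trajs:
        t = np.asarray(t)
        n_blocks = len(t) // length
        for b in range(n_blocks):
            out.append(t[b * length:(b + 1) * length])
    if not out:
        raise ValueError("no trajectory contains a complete block")
    return out


def _as_mapping(value) -> Mapping[str, float]:
    if isinstance(value, Mapping):
        return value
    return {"value": float(value)}


def bootstrap_observable(
    subtrajs: Sequence,
    estimator: Callable[[Sequence], float | Mapping[str, float]],
    plan: BootstrapPlan,
) -> dict[str, BootstrapSummary]:
    """Bootstrap any estimator over subtrajectory resamples.

    ``estimator`` maps a list of subtrajectories to a scalar or a name->scalar
    mapping (NaNs mark individually missing observables).  Returns one
    BootstrapSummary per observable name; a bare scalar estimator is reported
    under the name "value".
    """
    n = len(subtrajs)
    if n == 0:
        raise ValueError("no subtrajectories")
    rng = np.random.default_rng(plan.seed)
    samples: dict[str, list[float]] = {}
    n_failed = 0
    for _ in range(plan.n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            value = estimator([subtrajs[i] for i in idx])
        except Exception:
            n_failed += 1
            continue
        for name, v in _as_mapping(value).items():
            samples.setdefault(name, []).append(float(v))
    if n_failed == plan.n_boot:
        raise RuntimeError("estimator failed on every bootstrap replicate")
    out: dict[str, BootstrapSummary] = {}
    for name, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        ok = np.isfinite(arr)
        if ok.sum() == 0:
            out[name] = BootstrapSummary(np.nan, np.nan, np.nan, 0)
            continue
        lo, med, hi = np.quantile(arr[ok], [0.025, 0.5, 0.975])
        out[name] = BootstrapSummary(float(med), float(lo), float(hi), int(ok.sum()))
    return out
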