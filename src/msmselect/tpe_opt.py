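"""Bayesian optimization with tree-structured Parzen estimators (TPE).

The surrogate is not a model of the objective but of the hyperparameters
themselves: completed trials are split into "good" (the top gamma quantile by
objective) and "bad" sets, a kernel-density model is fitted to each
(truncated Gaussians per observation for numeric parameters, observed-count
categoricals for discrete ones, each mixed with a flat prior), and the next
point is the candidate drawn from the good density l that maximizes the
density ratio l(theta)/g(theta) — the expected-improvement maximizer.  The
"tree" is the conditional structure of the search space: a child parameter is
sampled and scored only when its parent takes the activating level.

Dual-objective mode replaces the quantile split by successive nondominated
fronts (Pareto sorting); the acquisition stays the l/g ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "Parameter",
    "SearchSpace",
    "TrialRecord",
    "table2_space",
    "feature_trial_allocation",
    "sample_space",
    "split_good_bad",
    "fit_parzen",
    "TreeParzen",
    "propose",
    "optimize",
    "pareto_front",
    "best_so_far",
]

_G_FLOOR = 1e-12  # density floor that keeps the acquisition ratio finite


@dataclass(frozen=True)
class Parameter:
    name: str
    kind: str  # continuous | integer | categorical
    low: float | None = None
    high: float | None = None
    levels: tuple | None = None
    condition: tuple[str, object] | None = None  # (parent name, activating level)

    def __post_init__(self):
        if self.kind in ("continuous", "integer"):
            if self.low is None or self.high is None or not (self.low < self.high):
                raise ValueError(f"parameter {self.name}: finite low < high required")
            if not (math.isfinite(self.low) and math.isfinite(self.high)):
                raise ValueError(f"parameter {self.name}: bounds must be finite")
        elif self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"parameter {self.name}: categorical needs levels")
        else:
            raise ValueError(f"parameter {self.name}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class SearchSpace:
    parameters: tuple

    def __post_init__(self):
        params = tuple(self.parameters)
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        by_name = {p.name: p for p in params}
        for p in params:
            seen = set()
            q = p
            while q.condition is not None:  # walk to the root; a revisit is a cycle
                if q.name in seen:
                    raise ValueError(f"conditional cycle at {p.name}")
                seen.add(q.name)
                parent = q.condition[0]
                if parent not in by_name:
                    raise ValueError(f"parameter {p.name} conditions on unknown {parent}")
                q = by_name[parent]
        object.__setattr__(self, "parameters", params)

    def __iter__(self):
        return iter(self.parameters)

    def __getitem__(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def active(self, theta: dict, p: Parameter) -> bool:
        """Whether p participates given the parent assignments in theta."""
        q = p
        while q.condition is not None:
            parent, level = q.condition
            if theta.get(parent) != level:
                return False
            q = self[parent]
        return True


@dataclass(frozen=True)
class TrialRecord:
    theta: dict
    objectives: tuple
    status: str = "ok"  # ok | failed
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.status == "ok" and not all(math.isfinite(v) for v in self.objectives):
            raise ValueError("ok trials must have finite objectives")


def table2_space() -> SearchSpace:
    """The study's conditional hyperparameter domain: feature family (with the
    logistic transform's center/steepness as children and the distance scheme
    shared by the two distance-based features), tICA dimension and lag,
    kinetic-map scaling, and the k-means microstate count."""
    return SearchSpace((
        Parameter("feature", "categorical", levels=("dihedral", "distance", "logistic_distance")),
        Parameter("scheme_distance", "categorical", levels=("closest-heavy", "alpha-carbon"),
                  condition=("feature", "distance")),
        Parameter("scheme_logistic", "categorical", levels=("closest-heavy", "alpha-carbon"),
                  condition=("feature", "logistic_distance")),
        Parameter("center", "continuous", low=3.0, high=15.0,
                  condition=("feature", "logistic_distance")),
        Parameter("steepness", "continuous", low=0.01, high=5.0,
                  condition=("feature", "logistic_distance")),
        Parameter("tica_dim", "integer", low=1, high=20),
        Parameter("tica_lag", "integer", low=1, high=100),
        Parameter("n_clusters", "integer", low=10, high=1000),
    ))


def feature_trial_allocation(total: int = 140) -> dict[str, int]:
    """Random-search trials per feature family, proportional to the number of
    feature hyperparameters: 1 (dihedral) : 2 (distance, + scheme) : 4
    (logistic, + scheme, center, steepness).  The study total of 140 splits
    as 20 / 40 / 80."""
    weights = {"dihedral": 1, "distance": 2, "logistic_distance": 4}
    total_w = sum(weights.values())
    alloc = {k: total * w // total_w for k, w in weights.items()}
    leftover = total - sum(alloc.values())
    for k in sorted(weights, key=weights.get, reverse=True):
        if leftover <= 0:
            break
        alloc[k] += 1
        leftover -= 1
    return alloc


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _sample_one(p: Parameter, rng: np.random.Generator):
    if p.kind == "categorical":
        return p.levels[rng.integers(len(p.levels))]
    x = rng.uniform(p.low, p.high)
    if p.kind == "integer":
        return int(np.clip(_round_half_up(x), p.low, p.high))
    return float(x)


def sample_space(space: SearchSpace, n: int, seed: int,
                 stratify: tuple[str, dict] | None = None) -> list[dict]:
    """Uniform random assignments respecting the conditional tree.

    ``stratify=(name, {level: count})`` pins a categorical parameter to fixed
    per-level counts (the study allocates feature-family trials this way);
    the counts must sum to n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pinned: list[tuple[str, object] | None] = [None] * n
    if stratify is not None:
        name, counts = stratify
        if sum(counts.values()) != n:
            raise ValueError("stratified counts must sum to n")
        flat = [(name, level) for level, c in counts.items() for _ in range(c)]
        pinned = list(flat)
    out = []
    for i in range(n):
        theta: dict = {}
        if pinned[i] is not None:
            theta[pinned[i][0]] = pinned[i][1]
        for p in space:
            if p.name in theta:
                continue
            if space.active(theta, p):
                theta[p.name] = _sample_one(p, rng)
        out.append(theta)
    return out


# ---------------------------------------------------------------------------
# good/bad split
# ---------------------------------------------------------------------------

def _dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """a dominates b under maximization of every objective."""
    return all(x >= y for x, y in zip(a, b)) and any(x > y for x, y in zip(a, b))


def pareto_front(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    """The nondominated subset (ties kept)."""
    ok = [t for t in trials if t.status == "ok"]
    return [t for t in ok
            if not any(_dominates(u.objectives, t.objectives) for u in ok if u is not t)]


def split_good_bad(trials: Sequence[TrialRecord], gamma: float = 0.25,
                   mode: str = "single") -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Partition completed trials into the good (top ceil(gamma N)) and bad
    sets.  Single mode sorts by the (scalar) objective, ties broken by earlier
    trial index; pareto mode fills the good set by successive nondominated
    fronts, trimming the last front by first objective."""
    ok = [(i, t) for i, t in enumerate(trials) if t.status == "ok"]
    if len(ok) < 2:
        raise ValueError("need at least 2 completed trials to split")
    n_good = math.ceil(gamma * len(ok))
    if mode == "single":
        ranked = sorted(ok, key=lambda it: (-it[1].objectives[0], it[0]))
        good = [t for _, t in ranked[:n_good]]
        bad = [t for _, t in ranked[n_good:]]
        return good, bad
    if mode == "pareto":
        remaining = list(ok)
        good_idx: list[int] = []
        while len(good_idx) < n_good and remaining:
            objs = {i: t.objectives for i, t in remaining}
            front = [i for i, t in remaining
                     if not any(_dominates(objs[j], objs[i]) for j, _ in remaining if j != i)]
            need = n_good - len(good_idx)
            if len(front) > need:  # trim within the front
                front = sorted(front, key=lambda i: (-trials[i].objectives[0], i))[:need]
            good_idx.extend(front)
            remaining = [(i, t) for i, t in remaining if i not in set(front)]
        good_set = set(good_idx)
        return ([trials[i] for i in sorted(good_set)],
                [t for i, t in ok if i not in good_set])
    raise ValueError(f"unknown split mode {mode!r}")


# ---------------------------------------------------------------------------
# Parzen densities
# ---------------------------------------------------------------------------

class _NumericParzen:
    """Mixture of per-observation truncated Gaussians plus one uniform prior
    component, all truncated to [low, high] and equally weighted 1/(N+1).

    Bandwidth per observation: max(distance to the nearest neighbouring
    observation, (high-low)/min(100, N))."""

    def __init__(self, obs: np.ndarray, low: float, high: float):
        obs = np.asarray(obs, dtype=float)
        if obs.size == 0:
            raise ValueError("need at least one observation")
        if np.any(obs < low - 1e-9) or np.any(obs > high + 1e-9):
            raise ValueError("observation outside bounds")
        self.low, self.high = float(low), float(high)
        self.mu = np.clip(obs, low, high)
        n = obs.size
        base = (high - low) / min(100, n)
        if n > 1:
            srt = np.sort(self.mu)
            gaps = np.diff(srt)
            nn = np.empty(n)
            order = np.argsort(self.mu, kind="stable")
            for rank, i in enumerate(order):
                cands = []
                if rank > 0:
                    cands.append(gaps[rank - 1])
                if rank < n - 1:
                    cands.append(gaps[rank])
                nn[i] = min(cands) if cands else base
            sigma = np.maximum(nn, base)
        else:
            sigma = np.array([base])
        self.sigma = np.maximum(sigma, 1e-12)
        # truncation mass of each Gaussian inside the bounds
        a = (self.low - self.mu) / self.sigma
        b = (self.high - self.mu) / self.sigma
        self.z = np.maximum(norm.cdf(b) - norm.cdf(a), 1e-300)
        self.w = 1.0 / (n + 1)  # each observation kernel and the prior

    def pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        inside = (x >= self.low) & (x <= self.high)
        comp = norm.pdf((x[:, None] - self.mu[None, :]) / self.sigma[None, :]) / (
            self.sigma[None, :] * self.z[None, :]
        )
        dens = self.w * comp.sum(axis=1) + self.w / (self.high - self.low)
        return np.where(inside, dens, 0.0)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        n = self.mu.size
        comp = rng.integers(0, n + 1, size=size)
        out = np.empty(size)
        for i, c in enumerate(comp):
            if c == n:  # prior component
                out[i] = rng.uniform(self.low, self.high)
            else:
                while True:  # rejection inside the bounds; kernels are narrow
                    x = rng.normal(self.mu[c], self.sigma[c])
                    if self.low <= x <= self.high:
                        out[i] = x
                        break
        return out


class _CategoricalParzen:
    """Probabilities proportional to observed counts plus one pseudo-count per
    level (the flat prior)."""

    def __init__(self, obs: Sequence, levels: tuple, prior: float = 1.0):
        self.levels = tuple(levels)
        counts = np.array([sum(1 for o in obs if o == lv) for lv in self.levels], dtype=float)
        if len(obs) != int(counts.sum()):
            raise ValueError("observation outside the categorical levels")
        probs = counts + prior
        self.probs = probs / probs.sum()

    def pdf(self, x) -> np.ndarray:
        idx = {lv: i for i, lv in enumerate(self.levels)}
        xs = x if isinstance(x, (list, tuple, np.ndarray)) else [x]
        return np.array([self.probs[idx[v]] if v in idx else 0.0 for v in xs])

    def sample(self, rng: np.random.Generator, size: int) -> list:
        picks = rng.choice(len(self.levels), size=size, p=self.probs)
        return [self.levels[i] for i in picks]


def fit_parzen(observations: Sequence, param: Parameter):
    """Density model for one parameter's observed values."""
    if param.kind == "categorical":
        return _CategoricalParzen(observations, param.levels)
    return _NumericParzen(np.asarray(observations, dtype=float), param.low, param.high)


class TreeParzen:
    """Per-parameter Parzen densities tied together by the conditional tree.

    Built from the theta dicts of one trial subset; a parameter's density uses
    only trials where it was active.  Parameters never observed in the subset
    fall back to the uniform/flat prior alone.
    """

    def __init__(self, thetas: Sequence[dict], space: SearchSpace):
        self.space = space
        self.densities: dict[str, object] = {}
        for p in space:
            obs = [th[p.name] for th in thetas if p.name in th]
            if obs:
                self.densities[p.name] = fit_parzen(obs, p)
            else:
                self.densities[p.name] = None  # prior fallback

    def sample(self, rng: np.random.Generator) -> dict:
        theta: dict = {}
        for p in self.space:
            if not self.space.active(theta, p):
                continue
            d = self.densities[p.name]
            if d is None:
                theta[p.name] = _sample_one(p, rng)
            else:
                v = d.sample(rng, 1)[0]
                if p.kind == "integer":
                    v = int(np.clip(_round_half_up(v), p.low, p.high))
                theta[p.name] = v
        return theta

    def log_density(self, theta: dict) -> float:
        total = 0.0
        for p in self.space:
            if not self.space.active(theta, p) or p.name not in theta:
                continue
            d = self.densities[p.name]
            if d is None:
                dens = (1.0 / (p.high - p.low)) if p.kind != "categorical" else 1.0 / len(p.levels)
            else:
                dens = float(d.pdf(theta[p.name])[0])
            total += math.log(max(dens, _G_FLOOR))
        return total


def propose(l_model: TreeParzen, g_model: TreeParzen, space: SearchSpace,
            n_candidates: int = 24, seed: int = 0) -> dict:
    """Draw candidates from the good density and return the one maximizing
    l(theta)/g(theta)."""
    rng = np.random.default_rng(seed)
    best_theta, best_score = None, -np.inf
    for _ in range(n_candidates):
        theta = l_model.sample(rng)
        score = l_model.log_density(theta) - g_model.log_density(theta)
        if score > best_score:
            best_theta, best_score = theta, score
    assert best_theta is not None
    return best_theta


def optimize(
    objective: Callable[[dict], float | Sequence[float]],
    space: SearchSpace,
    n_trials: int,
    init: Sequence[TrialRecord] = (),
    gamma: float = 0.25,
    seed: int = 0,
    mode: str = "single",
    n_candidates: int = 24,
    n_startup: int = 5,
) -> list[TrialRecord]:
    """Full TPE loop: split, fit l/g, propose, evaluate, append.

    The history is append-only (init included, unmodified).  Evaluations that
    raise or return non-finite values are recorded with status "failed" and
    excluded from density fitting.  Until ``n_startup`` completed trials exist
    the proposals are uniform random.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    history: list[TrialRecord] = list(init)
    ss = np.random.SeedSequence(seed)
    for step in range(n_trials):
        sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        ok = [t for t in history if t.status == "ok"]
        if len(ok) < max(n_startup, 2):
            theta = sample_space(space, 1, seed=sub_seed)[0]
        else:
            good, bad = split_good_bad(history, gamma=gamma, mode=mode)
            l_model = TreeParzen([t.theta for t in good], space)
            g_model = TreeParzen([t.theta for t in bad], space)
            theta = propose(l_model, g_model, space, n_candidates=n_candidates, seed=sub_seed)
        try:
            y = objective(theta)
            objs = tuple(float(v) for v in (y if isinstance(y, (tuple, list, np.ndarray)) else (y,)))
            if not all(math.isfinite(v) for v in objs):
                raise ValueError("non-finite objective")
            history.append(TrialRecord(theta=theta, objectives=objs, status="ok", seed=sub_seed))
        except Exception:
            history.append(TrialRecord(theta=theta, objectives=(), status="failed", seed=sub_seed))
    if not any(t.status == "ok" for t in history) and n_trials > 0:
        raise RuntimeError("objective failed on every trial")
    return history


def best_so_far(history: Sequence[TrialRecord], objective_index: int = 0) -> np.ndarray:
    """Monotone nondecreasing trace of the best objective value."""
    best = -np.inf
    trace = []
    for t in history:
        if t.status == "ok":
            best = max(best, t.objectives[objective_index])
        trace.append(best)
    return np.asarray(trace)
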