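"""Study orchestration: hyperparameter trials over the full pipeline, the
three-state inversion experiment, and rank-consistency analyses.

A *hyperparameter trial* is one full pipeline evaluation at a parameter point
theta: featurize -> tICA -> k-means -> per-lag reversible MSM, with every
observable (implied timescales t_2..t_21, VAMP2(k) and VAMP2_eq(k) for
k = 2..21, i.e. 60 observables per model) bootstrapped over subtrajectories.
A sweep over N_t trials, N_lag lags and N_b bootstrap samples therefore
accounts for N_b * N_t * N_lag * 60 scalar observations; the study design
(100 bootstraps, 140 trials, 10 lags) gives 8,400,000.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .features import FeatureSpec, featurize
from .lag_select import LagGrid
from .msm_core import (CountMatrices, count_transitions, estimate_reversible_mle,
                       largest_connected_set, spectral_decomposition)
from .reduction_cluster import assign_states, fit_kmeans, fit_tica, transform_tica
from .resampling import BootstrapPlan, BootstrapSummary, bootstrap_observable, split_subtrajectories
from .scoring import vamp2_eq, vamp2_score_of_model
from .synthetic_data import GroundTruthMSM, make_three_state_toy, sample_discrete_trajectories
from .tpe_opt import SearchSpace, feature_trial_allocation, sample_space

__all__ = [
    "HyperTrial",
    "ConsistencyMatrix",
    "observation_ledger",
    "model_observables",
    "run_trial",
    "run_sweep",
    "spearman",
    "rank_consistency",
    "toy_inversion_experiment",
    "count_discordant_pairs",
]

DEFAULT_K_RANGE = tuple(range(2, 22))  # the slowest 2..21 eigenvectors are scored


@dataclass
class HyperTrial:
    """One hyperparameter point with its bootstrapped per-lag observables."""

    trial_id: int
    theta: dict
    observables: dict = field(default_factory=dict)  # lag -> {name: BootstrapSummary}
    failures: dict = field(default_factory=dict)     # lag -> error message
    seed: int | None = None

    def median(self, lag: int, name: str) -> float:
        s = self.observables.get(lag, {}).get(name)
        if s is None or s.n_valid == 0:
            return np.nan
        return s.median

    def to_rows(self) -> list[dict]:
        rows = []
        for lag, obs in self.observables.items():
            for name, s in obs.items():
                rows.append({
                    "trial_id": self.trial_id, "lag": lag, "observable": name,
                    "median": s.median, "ci_low": s.ci_low, "ci_high": s.ci_high,
                    "n_valid": s.n_valid,
                })
        return rows


@dataclass(frozen=True)
class ConsistencyMatrix:
    labels: tuple
    rho: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rho, dtype=float)
        if not np.allclose(r, r.T, atol=1e-12, equal_nan=True):
            raise ValueError("consistency matrix must be symmetric")
        object.__setattr__(self, "rho", r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=list(self.labels), columns=list(self.labels))


def observation_ledger(n_trials: int, n_lags: int, n_boot: int,
                       n_observables: int = 3 * len(DEFAULT_K_RANGE)) -> int:
    """Total scalar observations a sweep accounts for: bootstraps x trials x
    lags x per-model observables (20 timescales + 20 VAMP2 + 20 VAMP2_eq by
    default)."""
    return int(n_boot) * int(n_trials) * int(n_lags) * int(n_observables)


def model_observables(dtrajs: Sequence[np.ndarray], lag: int,
                      k_range: Sequence[int] = DEFAULT_K_RANGE,
                      n_states_full: int | None = None,
                      vamp2_basis: str = "reversible_eigenvectors") -> dict[str, float]:
    """Estimate one reversible MSM and report all scored observables.

    Returns {"t_k": ..., "vamp2_k": ..., "vamp2eq_k": ...} for every k in
    ``k_range`` (NaN where the model has too few states or lambda_k <= 0).
    Raises when the largest connected set keeps fewer than two states, or —
    when ``n_states_full`` is given — fewer than half of the full model's
    states (such replicates are counted as failures by the bootstrap).
    """
    counts = count_transitions(dtrajs, lag, n_states=n_states_full)
    _, restricted = largest_connected_set(counts)
    if restricted.n_states < 2:
        raise ValueError("connected set too small for a two-state process")
    if n_states_full is not None and restricted.n_states < 0.5 * n_states_full:
        raise ValueError("connected set lost more than half of the states")
    model = estimate_reversible_mle(restricted)
    spectral_decomposition(model, model.n_states)
    # eigenvalues rounded to 12 decimals: iterative-solver noise in the last
    # bits would otherwise create spurious rank distinctions between
    # observables that are exact monotone functions of the same lambda
    lam = np.round(model.eigenvalues, 12)
    k_max = max(k_range)
    out: dict[str, float] = {}
    for k in k_range:
        if k <= model.n_states:
            out[f"vamp2eq_{k}"] = vamp2_eq(lam, k)
            out[f"vamp2_{k}"] = vamp2_score_of_model(restricted, model, k, basis=vamp2_basis)
        else:
            out[f"vamp2eq_{k}"] = np.nan
            out[f"vamp2_{k}"] = np.nan
    for i in k_range:  # t_i for the same index range
        if i <= model.n_states and 1e-12 < lam[i - 1] < 1.0:
            out[f"t_{i}"] = -lag / np.log(lam[i - 1])
        else:
            out[f"t_{i}"] = np.nan
    assert len(out) == 3 * len(k_range)
    return out


def discretize(theta: dict, data: Sequence[np.ndarray], seed: int,
               fit_stride: int = 10) -> list[np.ndarray]:
    """The hyperparameter-dependent part of the pipeline: featurize each
    continuous trajectory per theta, reduce with tICA, cluster with k-means."""
    scheme = theta.get("scheme_distance") or theta.get("scheme_logistic") or "generic"
    # synthetic point-mass data has no atom types: both schemes reduce to generic
    spec = FeatureSpec(
        kind=theta["feature"],
        pair_scheme="generic" if scheme in ("closest-heavy", "alpha-carbon") else scheme,
        center=theta.get("center", 9.0),
        steepness=theta.get("steepness", 1.0),
    )
    feats = [featurize(x, spec) for x in data]
    m = min(int(theta.get("tica_dim", 2)), feats[0].shape[1])
    tica = fit_tica(feats, lag=int(theta.get("tica_lag", 1)), m=m,
                    scaling=bool(theta.get("tica_scaling", True)))
    Y = transform_tica(tica, feats)
    n_frames = sum(len(y) for y in Y)
    n_clusters = min(int(theta.get("n_clusters", 50)), max(2, n_frames // (2 * fit_stride)))
    km = fit_kmeans(Y, n=n_clusters, seed=seed, fit_stride=fit_stride)
    return assign_states(km, Y)


def run_trial(theta: dict, data: Sequence[np.ndarray], lag_grid: LagGrid,
              plan: BootstrapPlan, k_range: Sequence[int] = DEFAULT_K_RANGE,
              trial_id: int = 0, seed: int = 0, fit_stride: int = 10) -> HyperTrial:
    """Evaluate one hyperparameter point on the data.

    ``data`` is either a list of continuous trajectories (2-D float arrays,
    frames x particles) that go through the full pipeline, or a list of 1-D
    integer state sequences that skip straight to MSM estimation (useful for
    trials that only touch the MSM stage).  Per-lag failures are recorded,
    never fatal.
    """
    trial = HyperTrial(trial_id=trial_id, theta=dict(theta), seed=seed)
    first = np.asarray(data[0])
    try:
        if np.issubdtype(first.dtype, np.integer):
            dtrajs = [np.asarray(d, dtype=np.int64) for d in data]
        else:
            dtrajs = discretize(theta, data, seed=seed, fit_stride=fit_stride)
    except Exception as e:  # feature stage impossible for this data kind
        for lag in lag_grid.lags:
            trial.failures[lag] = f"discretization failed: {e}"
        return trial
    n_states_full = int(max(d.max() for d in dtrajs)) + 1
    subtrajs = split_subtrajectories(dtrajs, plan.subtrajectory_length)
    for j, lag in enumerate(lag_grid.lags):
        if lag >= plan.subtrajectory_length:
            trial.failures[lag] = "lag not below the subtrajectory length"
            continue
        lag_plan = BootstrapPlan(plan.subtrajectory_length, plan.n_boot,
                                 seed=plan.seed + 7919 * j)
        try:
            trial.observables[lag] = bootstrap_observable(
                subtrajs,
                lambda ss: model_observables(ss, lag, k_range, n_states_full=n_states_full),
                lag_plan,
            )
        except Exception as e:
            trial.failures[lag] = str(e)
    return trial


def run_sweep(space: SearchSpace, n_trials: int, data: Sequence[np.ndarray],
              lag_grid: LagGrid, plan: BootstrapPlan, seed: int = 0,
              k_range: Sequence[int] = DEFAULT_K_RANGE,
              stratify_feature: bool = True,
              csv_path=None, fit_stride: int = 10) -> tuple[list[HyperTrial], dict]:
    """Random hyperparameter sweep: sample the space (stratified over feature
    families proportional to their hyperparameter counts when requested), run
    every trial, and account for the total number of observations.

    Returns the trials and a ledger dict with the designed observation count
    and the count actually backed by persisted rows.  When ``csv_path`` is
    given, rows are appended incrementally and completed trial ids are skipped
    on re-entry (resume support).
    """
    stratify = None
    if stratify_feature and any(p.name == "feature" for p in space):
        alloc = feature_trial_allocation(n_trials)
        stratify = ("feature", alloc)
    thetas = sample_space(space, n_trials, seed=seed, stratify=stratify)
    done_ids: set[int] = set()
    if csv_path is not None:
        from pathlib import Path
        if Path(csv_path).exists():
            prev = pd.read_csv(csv_path)
            done_ids = set(prev["trial_id"].unique())
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_trials)]
    trials: list[HyperTrial] = []
    for i, theta in enumerate(thetas):
        if i in done_ids:
            continue
        t = run_trial(theta, data, lag_grid, plan, k_range=k_range,
                      trial_id=i, seed=trial_seeds[i], fit_stride=fit_stride)
        trials.append(t)
        rows = t.to_rows()
        if csv_path is not None and rows:  # all-failed trials write nothing
            from pathlib import Path
            header = not Path(csv_path).exists()
            pd.DataFrame(rows).to_csv(csv_path, mode="a", header=header, index=False)
    n_rows = sum(len(t.to_rows()) for t in trials)
    ledger = {
        "designed_observations": observation_ledger(
            n_trials, len(lag_grid.lags), plan.n_boot, 3 * len(k_range)),
        "recorded_observations": n_rows * plan.n_boot,
        "recorded_rows": n_rows,
        "n_trials": n_trials,
        "n_lags": len(lag_grid.lags),
        "n_boot": plan.n_boot,
        "n_observables": 3 * len(k_range),
    }
    return trials, ledger


def spearman(x, y) -> float:
    """Spearman rank correlation with average ranks on ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero rank variance")
    rx, ry = rankdata(x), rankdata(y)
    if np.array_equal(rx, ry):  # identical rankings are exactly 1 by definition
        return 1.0
    if np.array_equal(rx, ry[::-1].max() + ry.min() - ry):
        return -1.0
    return float(spearmanr(x, y).statistic)


def rank_consistency(trials: Sequence[HyperTrial], vary: str = "lag",
                     lags: Sequence[int] | None = None,
                     ks: Sequence[int] | None = None,
                     fixed_k: int = 2, fixed_lag: int | None = None,
                     score: str = "vamp2eq") -> ConsistencyMatrix:
    """Pairwise Spearman matrix of trial rankings by bootstrap-median score.

    ``vary="lag"`` ranks trials by score at fixed k across the lag axis;
    ``vary="k"`` ranks at fixed lag across the k axis.  Trials missing a value
    anywhere on the axis are excluded listwise.
    """
    if vary == "lag":
        if lags is None:
            raise ValueError("provide the lag axis")
        labels = tuple(lags)
        cols = [(lag, f"{score}_{fixed_k}") for lag in lags]
    elif vary == "k":
        if ks is None or fixed_lag is None:
            raise ValueError("provide the k axis and the fixed lag")
        labels = tuple(ks)
        cols = [(fixed_lag, f"{score}_{k}") for k in ks]
    else:
        raise ValueError("vary must be 'lag' or 'k'")
    table = np.array([[t.median(lag, name) for lag, name in cols] for t in trials])
    keep = np.isfinite(table).all(axis=1)
    table = table[keep]
    if table.shape[0] < 3:
        raise ValueError("fewer than 3 trials have the full observable set")
    n = len(labels)
    rho = np.eye(n)
    for a, b in itertools.combinations(range(n), 2):
        rho[a, b] = rho[b, a] = spearman(table[:, a], table[:, b])
    return ConsistencyMatrix(labels=labels, rho=rho)


def count_discordant_pairs(x, y) -> int:
    """Number of pairs ordered oppositely by x and y (strict inversions)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    return int(np.sum((dx * dy < 0)) // 2)


def toy_inversion_experiment(n_replicates: int = 1000, traj_length: int = 20,
                             lag: int = 1, seed: int = 0,
                             model: GroundTruthMSM | None = None) -> tuple[pd.DataFrame, dict]:
    """Finite-sampling inconsistency of VAMP2(k) on reversible models.

    Each replicate samples one trajectory from the three-state truth,
    estimates a reversible MSM from its raw counts, and records t2, VAMP2(2)
    (whitened score of the reversible eigenvectors against the raw count
    matrices) and VAMP2_eq(2) (= 1 + lambda_2^2).  VAMP2_eq is monotone in
    lambda_2, so its ranking agrees with t2 exactly; VAMP2 need not, and at
    short trajectory lengths rank inversions appear.
    """
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates")
    truth = model if model is not None else make_three_state_toy()
    dtrajs = sample_discrete_trajectories(truth, n_replicates, traj_length, seed=seed)
    rows = []
    n_failed = 0
    for i, d in enumerate(dtrajs):
        try:
            obs = model_observables([d], lag, k_range=(2,),
                                    n_states_full=truth.n_states)
            if not np.isfinite(obs["t_2"]) or not np.isfinite(obs["vamp2_2"]):
                raise ValueError("unresolvable slow process")
            rows.append({"replicate": i, "t2": obs["t_2"],
                         "vamp2_2": obs["vamp2_2"], "vamp2eq_2": obs["vamp2eq_2"]})
        except Exception:
            n_failed += 1
    table = pd.DataFrame(rows)
    report = {
        "n_valid": len(table),
        "n_failed": n_failed,
        "traj_length": traj_length,
        "lag": lag,
        "seed": seed,
        "transition_matrix": truth.transition_matrix.tolist(),
        "spearman_t2_vamp2eq": spearman(table["t2"], table["vamp2eq_2"]),
        "spearman_t2_vamp2": spearman(table["t2"], table["vamp2_2"]),
        "discordant_pairs_vamp2": count_discordant_pairs(table["t2"], table["vamp2_2"]),
    }
    return table, report
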