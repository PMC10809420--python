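"""Count matrices, MSM estimation and spectral analysis.

The estimation path follows the standard discrete-state workflow: transitions
at lag tau are tabulated with a sliding window into C0t; its row and column
sums give the diagonal marginals C00 and Ctt; the nonreversible estimator row-
normalizes C0t; the reversible maximum-likelihood estimator imposes detailed
balance pi_i T_ij = pi_j T_ji through the classic fixed-point iteration on the
symmetric auxiliary variables x_ij.  Spectral quantities (eigenvalues, pi-
orthonormal eigenvectors, implied timescales t_i = -tau/ln lambda_i, mean
first-passage times) are computed from the resulting row-stochastic matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "CountMatrices",
    "MarkovModel",
    "count_transitions",
    "largest_connected_set",
    "estimate_nonreversible",
    "estimate_reversible_mle",
    "spectral_decomposition",
    "implied_timescales",
    "mfpt",
    "two_state_split",
    "eigenvector_overlap",
]


@dataclass(frozen=True)
class CountMatrices:
    """Transition counts C0t at lag tau with diagonal marginals C00 and Ctt."""

    C0t: np.ndarray
    lag: int
    active_set: np.ndarray | None = None

    def __post_init__(self):
        C = np.asarray(self.C0t, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C0t must be square")
        if np.any(C < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "C0t", C)
        if self.active_set is None:
            object.__setattr__(self, "active_set", np.arange(C.shape[0]))
        else:
            object.__setattr__(self, "active_set", np.asarray(self.active_set, dtype=np.int64))

    @property
    def n_states(self) -> int:
        return self.C0t.shape[0]

    @property
    def C00(self) -> np.ndarray:
        return np.diag(self.C0t.sum(axis=1))

    @property
    def Ctt(self) -> np.ndarray:
        return np.diag(self.C0t.sum(axis=0))

    @property
    def total(self) -> float:
        return float(self.C0t.sum())


@dataclass
class MarkovModel:
    """A row-stochastic transition matrix with its spectral decomposition."""

    T: np.ndarray
    pi: np.ndarray
    lag: int
    reversible: bool
    active_set: np.ndarray = field(default=None)  # type: ignore[assignment]
    eigenvalues: np.ndarray | None = None
    left_eigenvectors: np.ndarray | None = None   # phi_i as columns
    right_eigenvectors: np.ndarray | None = None  # psi_i as columns

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows of T must sum to 1 within 1e-10")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.active_set is None:
            self.active_set = np.arange(self.T.shape[0])
        if self.reversible:
            flux = self.pi[:, None] * self.T
            if not np.allclose(flux, flux.T, atol=1e-8):
                raise ValueError("reversible model violates detailed balance")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "T": self.T.tolist(),
            "pi": self.pi.tolist(),
            "lag": int(self.lag),
            "reversible": bool(self.reversible),
            "active_set": self.active_set.tolist(),
        }
        if self.eigenvalues is not None:
            payload["eigenvalues"] = np.asarray(self.eigenvalues).tolist()
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovModel":
        d = json.loads(Path(path).read_text())
        return cls(
            T=np.array(d["T"]), pi=np.array(d["pi"]), lag=d["lag"],
            reversible=d["reversible"], active_set=np.array(d["active_set"]),
        )


def count_transitions(dtrajs: Sequence[np.ndarray], lag: int,
                      n_states: int | None = None) -> CountMatrices:
    """Sliding-window transition counts at the given lag.

    Every pair (s_t, s_{t+lag}) for t in [0, L-1-lag] contributes one count;
    trajectories shorter than lag+1 contribute nothing.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    dtrajs = [np.asarray(d, dtype=np.int64) for d in dtrajs]
    if n_states is None:
        n_states = max((int(d.max()) for d in dtrajs if d.size), default=-1) + 1
    C = np.zeros((n_states, n_states))
    any_counts = False
    for d in dtrajs:
        if d.size <= lag:
            continue
        any_counts = True
        i, j = d[:-lag], d[lag:]
        np.add.at(C, (i, j), 1.0)
    if not any_counts:
        raise ValueError(f"all trajectories are shorter than lag+1 = {lag + 1}")
    return CountMatrices(C0t=C, lag=lag)


def largest_connected_set(C: CountMatrices, directed: bool = True) -> tuple[np.ndarray, CountMatrices]:
    """Largest strongly connected component of the count graph, and the counts
    restricted to it.  Ties between equal-size components go to the one
    containing the lowest state index.  The mapping back to original labels is
    carried in ``active_set``."""
    A = sp.csr_matrix(C.C0t > 0)
    n_comp, labels = connected_components(A, directed=directed, connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    best = np.flatnonzero(sizes == sizes.max())
    # lowest contained original index breaks ties
    chosen = min(best, key=lambda c: int(np.flatnonzero(labels == c)[0]))
    keep = np.flatnonzero(labels == chosen)
    sub = C.C0t[np.ix_(keep, keep)]
    return keep, CountMatrices(C0t=sub, lag=C.lag, active_set=C.active_set[keep])


def estimate_nonreversible(C: CountMatrices) -> MarkovModel:
    """Row-normalized count estimator T_ij = c_ij / c_i."""
    rows = C.C0t.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError("every state needs at least one outgoing count")
    T = C.C0t / rows[:, None]
    pi = _stationary(T)
    return MarkovModel(T=T, pi=pi, lag=C.lag, reversible=False, active_set=C.active_set)


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.abs(np.real(vecs[:, i]))
    return pi / pi.sum()


def log_likelihood(C0t: np.ndarray, T: np.ndarray) -> float:
    mask = C0t > 0
    return float(np.sum(C0t[mask] * np.log(T[mask])))


def estimate_reversible_mle(C: CountMatrices, tol: float = 1e-10,
                            max_iter: int = 100_000) -> MarkovModel:
    """Detailed-balance-constrained maximum likelihood estimate.

    Fixed-point iteration on the symmetric unnormalized flux matrix X:
        x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)
    with x_i = sum_j x_ij, then T_ij = x_ij / x_i and pi_i = x_i / sum(x).
    Counts must already be restricted to a strongly connected set.  The
    iteration increases the likelihood monotonically; convergence is declared
    when the relative log-likelihood change drops below ``tol``.
    """
    Cm = C.C0t
    rows = Cm.sum(axis=1)
    if np.any(rows <= 0) or np.any(Cm.sum(axis=0) <= 0):
        raise ValueError("counts must be restricted to a connected set first")
    X = (Cm + Cm.T) / 2.0  # symmetrized initialization
    Csym = Cm + Cm.T
    T_old = X / X.sum(axis=1)[:, None]
    ll_old = log_likelihood(Cm, T_old)
    # the log-likelihood is flat near the optimum, so a likelihood criterion
    # alone can stop while T still moves at ~sqrt(tol); require T to settle too
    t_tol = max(100.0 * tol, 1e-13)
    converged = False
    ll = ll_old
    for _ in range(max_iter):
        x = X.sum(axis=1)
        denom = rows[:, None] / x[:, None] + rows[None, :] / x[None, :]
        X = np.where(Csym > 0, Csym / denom, 0.0)
        x = X.sum(axis=1)
        T = X / x[:, None]
        ll = log_likelihood(Cm, T)
        if abs(ll - ll_old) <= tol * abs(ll_old) and np.max(np.abs(T - T_old)) <= t_tol:
            converged = True
            break
        ll_old = ll
        T_old = T
    if not converged:
        raise RuntimeError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(last relative change {abs(ll - ll_old) / abs(ll_old):.3e})"
        )
    x = X.sum(axis=1)
    pi = x / x.sum()
    T = X / x[:, None]
    T = T / T.sum(axis=1)[:, None]  # remove residual rounding
    return MarkovModel(T=T, pi=pi, lag=C.lag, reversible=True, active_set=C.active_set)


def reversible_mle_likelihood_trace(C: CountMatrices, n_iter: int) -> np.ndarray:
    """Log-likelihood after each fixed-point update (diagnostic; the MLE
    iteration is an ascent method, so this is non-decreasing)."""
    Cm = C.C0t
    rows = Cm.sum(axis=1)
    X = (Cm + Cm.T) / 2.0
    Csym = Cm + Cm.T
    trace = []
    for _ in range(n_iter):
        x = X.sum(axis=1)
        denom = rows[:, None] / x[:, None] + rows[None, :] / x[None, :]
        X = np.where(Csym > 0, Csym / denom, 0.0)
        x = X.sum(axis=1)
        trace.append(log_likelihood(Cm, X / x[:, None]))
    return np.asarray(trace)


def spectral_decomposition(model: MarkovModel, k: int | None = None) -> MarkovModel:
    """Attach the leading k eigenpairs to the model (in place, also returned).

    Reversible models are diagonalized through the symmetric similarity
    transform D^{1/2} T D^{-1/2} (D = diag(pi)), which guarantees real
    eigenvalues; nonreversible models use the generic solver and sort by
    modulus.  Right eigenvectors are pi-orthonormal (sum_i pi_i psi_a psi_b =
    delta_ab, hence psi_1 = 1), left ones are phi_i = pi * psi_i, and each
    psi's first nonzero entry is made positive.
    """
    n = model.n_states
    if k is None:
        k = n
    if k > n:
        raise ValueError("k cannot exceed the number of states")
    if model.reversible:
        sqrt_pi = np.sqrt(model.pi)
        S = sqrt_pi[:, None] * model.T / sqrt_pi[None, :]
        vals, vecs = scipy.linalg.eigh((S + S.T) / 2.0)
        order = np.argsort(vals)[::-1]
        vals = vals[order]
        vecs = vecs[:, order]
        psi = vecs / sqrt_pi[:, None]
        phi = vecs * sqrt_pi[:, None]
    else:
        vals, vecsR = scipy.linalg.eig(model.T)
        order = np.argsort(np.abs(vals))[::-1]
        vals = np.real(vals[order])
        psi = np.real(vecsR[:, order])
        # biorthogonal left set from the inverse
        phi = np.linalg.inv(psi).T
        # normalize so that sum_i pi_i psi_a(i)^2 = 1 where possible
        scale = np.sqrt(np.abs(np.einsum("i,ia,ia->a", model.pi, psi, psi)))
        scale[scale == 0] = 1.0
        psi = psi / scale
        phi = phi * scale
    # sign convention: first nonzero entry of each psi positive
    for a in range(psi.shape[1]):
        nz = np.flatnonzero(np.abs(psi[:, a]) > 1e-12)
        if nz.size and psi[nz[0], a] < 0:
            psi[:, a] *= -1
            phi[:, a] *= -1
    model.eigenvalues = vals[:k]
    model.right_eigenvectors = psi[:, :k]
    model.left_eigenvectors = phi[:, :k]
    return model


def implied_timescales(model: MarkovModel, k: int) -> np.ndarray:
    """t_i = -tau / ln(lambda_i) for i = 2..k; entries for lambda <= 0 (or
    missing processes) are NaN rather than a number."""
    if model.eigenvalues is None or len(model.eigenvalues) < 2:
        spectral_decomposition(model, min(k, model.n_states))
    lam = np.asarray(model.eigenvalues)
    out = np.full(k - 1, np.nan)
    m = min(k, len(lam))
    for i in range(1, m):
        li = lam[i]
        if 1e-12 < li < 1.0:
            out[i - 1] = -model.lag / np.log(li)
    return out


def mfpt(model: MarkovModel, target: Sequence[int]) -> np.ndarray:
    """Mean first-passage time to the target set from every state, in the
    model's time units: m_i = tau + sum_{j not in target} T_ij m_j, m=0 on
    the target."""
    target = np.asarray(sorted(set(int(t) for t in target)), dtype=np.int64)
    if target.size == 0:
        raise ValueError("target set must be nonempty")
    n = model.n_states
    free = np.setdiff1d(np.arange(n), target)
    m = np.zeros(n)
    if free.size:
        A = np.eye(free.size) - model.T[np.ix_(free, free)]
        b = np.full(free.size, float(model.lag))
        try:
            m[free] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"target unreachable: {e}") from e
    return m


def two_state_split(model: MarkovModel) -> np.ndarray:
    """Binary partition by the sign of psi_2 (zeros join the positive side)."""
    if model.right_eigenvectors is None or model.right_eigenvectors.shape[1] < 2:
        spectral_decomposition(model, min(2, model.n_states))
    if model.n_states < 2:
        raise ValueError("need at least two states")
    lam = model.eigenvalues
    if len(lam) > 2 and np.isclose(lam[1], lam[2], atol=1e-12):
        raise ValueError("degenerate lambda_2: two-state split is not unique")
    psi2 = model.right_eigenvectors[:, 1]
    return (psi2 >= 0).astype(np.int64)


def eigenvector_overlap(model_a: MarkovModel, assign_a: np.ndarray,
                        model_b: MarkovModel, assign_b: np.ndarray) -> float:
    """Absolute Pearson correlation between the per-frame psi_2 values of two
    discretizations of the same frames.  1 means both models resolve the same
    slow process; near 0 means unrelated processes."""
    assign_a = np.asarray(assign_a, dtype=np.int64)
    assign_b = np.asarray(assign_b, dtype=np.int64)
    if assign_a.shape != assign_b.shape:
        raise ValueError("assignments must cover the same frames")
    for m in (model_a, model_b):
        if m.right_eigenvectors is None or m.right_eigenvectors.shape[1] < 2:
            spectral_decomposition(m, min(2, m.n_states))
    # frames whose state survives both active sets
    map_a = {s: i for i, s in enumerate(model_a.active_set)}
    map_b = {s: i for i, s in enumerate(model_b.active_set)}
    ok = np.array([(a in map_a) and (b in map_b) for a, b in zip(assign_a, assign_b)])
    ia = np.array([map_a[a] for a in assign_a[ok]], dtype=np.int64)
    ib = np.array([map_b[b] for b in assign_b[ok]], dtype=np.int64)
    va = model_a.right_eigenvectors[ia, 1]
    vb = model_b.right_eigenvectors[ib, 1]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("psi_2 constant over frames; overlap undefined")
    r = np.corrcoef(va, vb)[0, 1]
    return float(abs(r))
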