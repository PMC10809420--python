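"""tICA dimensionality reduction and k-means discretization.

tICA solves the symmetrized time-lagged generalized eigenproblem
C(tau) v = lambda C(0) v on mean-free data, with C(tau) symmetrized so the
spectrum is real and invariant to time reversal.  With kinetic-map scaling the
projections are multiplied by their eigenvalues so Euclidean distances in the
reduced space approximate kinetic distances.  Cluster centers are fitted by
k-means (k-means++ initialization, scikit-learn) on a strided subset of
frames; assignment always uses every frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

__all__ = ["TICAModel", "ClusterModel", "fit_tica", "transform_tica", "fit_kmeans", "assign_states"]

#: relative shrinkage added to the instantaneous covariance so duplicated or
#: constant features never make the metric singular
_SHRINKAGE = 1e-10


@dataclass
class TICAModel:
    mean: np.ndarray
    eigenvalues: np.ndarray          # descending, in (-1, 1] up to noise
    components: np.ndarray           # features x m, C0-orthonormal columns
    lag: int
    scaling: bool

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "mean": self.mean.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "components": self.components.tolist(),
            "lag": int(self.lag),
            "scaling": bool(self.scaling),
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TICAModel":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["mean"]), np.array(d["eigenvalues"]),
                   np.array(d["components"]), d["lag"], d["scaling"])


@dataclass
class ClusterModel:
    centers: np.ndarray  # n x m

    @property
    def n_states(self) -> int:
        return self.centers.shape[0]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"centers": self.centers.tolist()}, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        return cls(np.array(json.loads(Path(path).read_text())["centers"]))


def _traj_list(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray):
        X = [X]
    return [np.atleast_2d(np.asarray(x, dtype=float)) for x in X]


def fit_tica(X, lag: int, m: int, scaling: bool = True) -> TICAModel:
    """Fit tICA at the given lag and keep the top-m components.

    Covariances are accumulated over all trajectories; C(tau) is symmetrized,
    (C + C^T)/2, and C(0) receives a trace-scaled shrinkage ridge before the
    generalized eigensolve so rank-deficient feature sets stay solvable.
    """
    trajs = _traj_list(X)
    dim = trajs[0].shape[1]
    if m > dim:
        raise ValueError("m cannot exceed the number of features")
    usable = [t for t in trajs if len(t) > lag]
    if not usable:
        raise ValueError("every trajectory must be longer than the tICA lag")
    # mean over all frames that enter either end of a lagged pair
    n_pairs = sum(len(t) - lag for t in usable)
    mean = sum(t[:-lag].sum(axis=0) + t[lag:].sum(axis=0) for t in usable) / (2 * n_pairs)
    C0 = np.zeros((dim, dim))
    Ct = np.zeros((dim, dim))
    for t in usable:
        a = t[:-lag] - mean
        b = t[lag:] - mean
        C0 += a.T @ a + b.T @ b
        Ct += a.T @ b
    C0 /= 2 * n_pairs
    Ct /= n_pairs
    Ct = (Ct + Ct.T) / 2.0
    ridge = _SHRINKAGE * np.trace(C0) / dim
    C0reg = C0 + max(ridge, _SHRINKAGE) * np.eye(dim)
    vals, vecs = scipy.linalg.eigh(Ct, C0reg)
    order = np.argsort(vals)[::-1]
    vals = vals[order][:m]
    vecs = vecs[:, order][:, :m]
    # sign convention: largest-magnitude loading positive
    for a in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, a])))
        if vecs[i, a] < 0:
            vecs[:, a] *= -1
    return TICAModel(mean=mean, eigenvalues=vals, components=vecs, lag=lag, scaling=scaling)


def transform_tica(model: TICAModel, X) -> list[np.ndarray]:
    """Project mean-free data onto the components; kinetic-map scaling
    multiplies each column by its eigenvalue."""
    trajs = _traj_list(X)
    out = []
    for t in trajs:
        if t.shape[1] != model.mean.shape[0]:
            raise ValueError("feature dimensionality does not match the model")
        Y = (t - model.mean) @ model.components
        if model.scaling:
            Y = Y * model.eigenvalues[None, :]
        out.append(Y)
    return out


def fit_kmeans(Y, n: int, seed: int, fit_stride: int = 1,
               max_iter: int = 500, tol: float = 1e-6) -> ClusterModel:
    """k-means++ cluster centers fitted on every ``fit_stride``-th frame."""
    trajs = _traj_list(Y)
    data = np.vstack([t[::fit_stride] for t in trajs])
    if len(data) < n:
        raise ValueError("fewer strided frames than requested clusters")
    if len(np.unique(data, axis=0)) < n:
        raise ValueError("fewer distinct points than requested clusters")
    km = KMeans(n_clusters=n, init="k-means++", n_init=1, max_iter=max_iter,
                tol=tol, random_state=seed & 0x7FFFFFFF)
    km.fit(data)
    return ClusterModel(centers=km.cluster_centers_.copy())


def assign_states(model: ClusterModel, Y) -> list[np.ndarray]:
    """Nearest-center (Euclidean) assignment of every frame; equidistant ties
    go to the lowest center index."""
    trajs = _traj_list(Y)
    out = []
    for t in trajs:
        if t.shape[1] != model.centers.shape[1]:
            raise ValueError("dimension mismatch with cluster centers")
        labels = np.empty(len(t), dtype=np.int64)
        for start in range(0, len(t), 8192):  # chunked to bound memory
            chunk = t[start:start + 8192]
            d2 = ((chunk[:, None, :] - model.centers[None, :, :]) ** 2).sum(axis=2)
            labels[start:start + 8192] = np.argmin(d2, axis=1)  # lowest index on ties
        out.append(labels)
    return out
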