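"""The variational score family.

Three scores are implemented for a model over discrete basis states:

* ``gmrq`` — the Generalized Matrix Rayleigh Quotient, the r=1 stationary/
  reversible member of the family: trace[(U^T C00 U)^-1 U^T C0t U] over the
  top-k eigenvectors U.
* ``vamp_r_score`` — the Koopman-model score: the r-th power of the
  Schatten-r norm of the whitened matrix
  (U^T C00 U)^{-1/2} U^T C0t V (V^T Ctt V)^{-1/2}, summed over its top-k
  singular values.  When U and V are the singular functions of the matrix
  estimated from the same counts, this reduces to sum_i s_i^r of
  C00^{-1/2} C0t Ctt^{-1/2}.
* ``vamp2_eq`` — the equilibrium VAMP2 score of a reversible transition
  matrix, the sum of the squared leading eigenvalues 1 + lambda_2^2 + ...

The study's central observation lives in the gap between the last two: on a
reversible model the eigenvectors fed into the whitened score and the raw
count matrices are numerically inconsistent, so vamp_r_score can rank models
in the opposite order of their slowest timescale, while vamp2_eq (a monotone
function of the eigenvalues alone) cannot.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .msm_core import CountMatrices, MarkovModel, spectral_decomposition

__all__ = ["schatten_power", "vamp_r_score", "gmrq", "vamp2_eq", "vamp2_score_of_model"]

#: eigenvalue floor used when inverting projected metrics
_WHITEN_FLOOR = 1e-12


def schatten_power(singular_values: np.ndarray, r: int, k: int) -> float:
    """sum_{i<=k} s_i^r for a descending nonnegative vector s."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be nonnegative")
    if k > s.size:
        raise ValueError("k exceeds the number of singular values")
    if k <= 0:
        return 0.0
    return float(np.sum(s[:k] ** r))


def _inv_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root with a small-eigenvalue floor."""
    M = (M + M.T) / 2.0
    vals, vecs = scipy.linalg.eigh(M)
    floor = _WHITEN_FLOOR * max(1.0, float(np.max(np.abs(vals))))
    keep = vals > floor
    inv = np.zeros_like(vals)
    inv[keep] = 1.0 / np.sqrt(vals[keep])
    return (vecs * inv[None, :]) @ vecs.T


def whitened_matrix(C: CountMatrices, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """(U^T C00 U)^{-1/2} U^T C0t V (V^T Ctt V)^{-1/2}, all matrices taken on
    the same state set."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape[0] != C.n_states or V.shape[0] != C.n_states:
        raise ValueError("basis matrices must live on the count state set")
    A = _inv_sqrt(U.T @ C.C00 @ U)
    B = _inv_sqrt(V.T @ C.Ctt @ V)
    return A @ (U.T @ C.C0t @ V) @ B


def vamp_r_score(C: CountMatrices, U: np.ndarray, V: np.ndarray,
                 k: int, r: int = 2) -> float:
    """VAMP-r score of the basis spanned by U (left) and V (right)."""
    M = whitened_matrix(C, U, V)
    s = scipy.linalg.svdvals(M)
    k_eff = min(k, s.size)
    return schatten_power(np.sort(s)[::-1], r, k_eff)


def gmrq(C: CountMatrices, U: np.ndarray, k: int) -> float:
    """trace[(U^T C00 U)^{-1} U^T C0t U] over the first k columns of U."""
    U = np.atleast_2d(np.asarray(U, dtype=float))[:, :k]
    A = U.T @ C.C00 @ U
    B = U.T @ C.C0t @ U
    try:
        X = scipy.linalg.solve(A, B, assume_a="sym")
    except scipy.linalg.LinAlgError:
        X = np.linalg.pinv(A) @ B
    return float(np.trace(X))


def vamp2_eq(eigenvalues: np.ndarray, k: int) -> float:
    """Equilibrium VAMP2 score: sum of the squared leading k eigenvalues of a
    reversible transition matrix, 1 + lambda_2^2 + ... + lambda_k^2."""
    lam = np.asarray(eigenvalues, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > lam.size:
        raise ValueError("k exceeds the number of available eigenvalues")
    if not np.isclose(lam[0], 1.0, atol=1e-8):
        raise ValueError("leading eigenvalue must be 1")
    return float(np.sum(lam[:k] ** 2))


def vamp2_score_of_model(C: CountMatrices, model: MarkovModel, k: int,
                         basis: str = "reversible_eigenvectors") -> float:
    """VAMP2(k) of an estimated model against its own (raw) count matrices.

    ``basis`` selects what plays the role of the singular functions:

    * "reversible_eigenvectors" (default): the pi-orthonormal eigenvectors of
      the reversible transition matrix are used for both U and V.  Because the
      reversible pi is generally inconsistent with the raw marginals C00/Ctt,
      this is the variant in which score/timescale rank inversions arise.
    * "nonreversible_svd": U and V are the left/right singular functions of
      the nonreversible estimate C00^{-1/2} C0t Ctt^{-1/2}; score equals the
      plain Schatten sum of that matrix's singular values.
    """
    if basis == "reversible_eigenvectors":
        if model.right_eigenvectors is None or model.right_eigenvectors.shape[1] < k:
            spectral_decomposition(model, min(k, model.n_states))
        U = model.right_eigenvectors[:, : min(k, model.n_states)]
        return vamp_r_score(C, U, U, k=k, r=2)
    if basis == "nonreversible_svd":
        A = _inv_sqrt(C.C00)
        B = _inv_sqrt(C.Ctt)
        s = scipy.linalg.svdvals(A @ C.C0t @ B)
        return schatten_power(np.sort(s)[::-1], 2, min(k, s.size))
    raise ValueError(f"unknown basis variant {basis!r}")
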