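"""Synthetic inputs with known ground truth.

Two generators cover the study's needs: discrete trajectories sampled from a
known row-stochastic transition matrix (the regime in which finite-sampling
artefacts of reversible estimation appear), and 1-D overdamped-Langevin
trajectories in simple multi-well potentials, which stand in for molecular
dynamics data so the full featurize -> tICA -> cluster -> MSM pipeline can be
exercised against a brute-force reference timescale.

Units are arbitrary throughout; thermal energy k_B*T is fixed to 1, so
potentials are expressed directly in units of k_B*T.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GroundTruthMSM",
    "DiffusionSpec",
    "make_three_state_toy",
    "sample_discrete_trajectories",
    "simulate_diffusion",
    "reference_timescale",
    "write_dtrajs",
    "read_dtrajs",
    "write_continuous_trajectory",
    "read_continuous_trajectory",
]

#: Metastable three-state default used by the toy experiments: two slow states
#: (0 and 2) with diagonal 0.90 and a short-lived transition state (1).  The
#: matrix is reversible with pi = (5/12, 1/6, 5/12) and, by its 0<->2 mirror
#: symmetry, has exact eigenvalues (1, 0.88, 0.52).
THREE_STATE_TOY_MATRIX = np.array(
    [
        [0.90, 0.08, 0.02],
        [0.20, 0.60, 0.20],
        [0.02, 0.08, 0.90],
    ]
)


@dataclass(frozen=True)
class GroundTruthMSM:
    """A known Markov chain: row-stochastic matrix plus its stationary vector."""

    transition_matrix: np.ndarray
    stationary: np.ndarray
    step_time: float = 1.0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0):
            raise ValueError("transition matrix entries must be nonnegative")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1 within 1e-12")
        pi = np.asarray(self.stationary, dtype=float)
        if not np.allclose(pi @ T, pi, atol=1e-10):
            raise ValueError("stationary vector must satisfy pi T = pi")
        object.__setattr__(self, "transition_matrix", T)
        object.__setattr__(self, "stationary", pi / pi.sum())

    @classmethod
    def from_matrix(cls, T: np.ndarray, step_time: float = 1.0) -> "GroundTruthMSM":
        """Build from a row-stochastic matrix, deriving pi as the leading left
        eigenvector (normalized, guaranteed real for an irreducible chain)."""
        T = np.asarray(T, dtype=float)
        vals, vecs = np.linalg.eig(T.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi) / np.abs(pi).sum()
        return cls(transition_matrix=T, stationary=pi, step_time=step_time)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """All eigenvalues, sorted descending by real part."""
        vals = np.linalg.eigvals(self.transition_matrix)
        return np.sort(np.real(vals))[::-1]

    def metadata(self) -> dict:
        return {
            "transition_matrix": self.transition_matrix.tolist(),
            "stationary": self.stationary.tolist(),
            "step_time": self.step_time,
        }


def make_three_state_toy(step_time: float = 1.0) -> GroundTruthMSM:
    """The metastable three-state chain used throughout the toy experiments.

    Second implied timescale at unit lag: t2 = -1/ln(0.88) ~ 7.82 steps, so the
    slow 0<->2 exchange is well separated from the fast mode (lambda3 = 0.52).
    """
    return GroundTruthMSM.from_matrix(THREE_STATE_TOY_MATRIX.copy(), step_time=step_time)


def sample_discrete_trajectories(
    model: GroundTruthMSM,
    n_traj: int,
    length: int,
    seed: int,
    start: str | Sequence[int] = "stationary",
) -> list[np.ndarray]:
    """Sample ``n_traj`` state sequences of exactly ``length`` steps.

    Initial states are drawn from the stationary distribution unless ``start``
    is "uniform" or an explicit per-trajectory state list.  The sampler is
    vectorized across trajectories (one pass over time), so many short chains
    cost the same as one long one.  Identical seeds give identical output.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    T = model.transition_matrix
    n = model.n_states
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against rounding in the final column

    if isinstance(start, str):
        if start == "stationary":
            p0 = model.stationary
        elif start == "uniform":
            p0 = np.full(n, 1.0 / n)
        else:
            raise ValueError(f"unknown start mode {start!r}")
        states = rng.choice(n, size=n_traj, p=p0)
    else:
        states = np.asarray(start, dtype=np.int64)
        if states.shape != (n_traj,):
            raise ValueError("explicit start must list one state per trajectory")

    out = np.empty((n_traj, length), dtype=np.int64)
    out[:, 0] = states
    for t in range(1, length):
        u = rng.random(n_traj)
        # searchsorted per current state row of the cumulative matrix
        states = (u[:, None] > cum[states]).sum(axis=1)
        out[:, t] = states
    return [out[i] for i in range(n_traj)]


# ---------------------------------------------------------------------------
# Overdamped Langevin diffusion in simple 1-D potentials
# ---------------------------------------------------------------------------

def _potential_functions(spec: "DiffusionSpec") -> tuple[Callable, Callable, tuple[float, float]]:
    """Return (V, dV/dx, domain) for the spec's potential."""
    p = spec.parameters
    if spec.potential == "harmonic":
        k = p.get("k", 1.0)
        x0 = p.get("x0", 0.0)
        return (
            lambda x: 0.5 * k * (x - x0) ** 2,
            lambda x: k * (x - x0),
            (x0 - 6.0 / np.sqrt(k), x0 + 6.0 / np.sqrt(k)),
        )
    if spec.potential == "double_well":
        h = p.get("barrier", 4.0)  # barrier height in k_B T at x=0
        return (
            lambda x: h * (x**2 - 1.0) ** 2,
            lambda x: 4.0 * h * x * (x**2 - 1.0),
            (-2.2, 2.2),
        )
    if spec.potential == "flat":
        L = p.get("length", 1.0)
        return (lambda x: np.zeros_like(np.asarray(x, dtype=float)),
                lambda x: np.zeros_like(np.asarray(x, dtype=float)),
                (0.0, L))
    raise ValueError(f"unsupported potential {spec.potential!r}")


@dataclass(frozen=True)
class DiffusionSpec:
    """Overdamped 1-D Brownian dynamics specification.

    ``potential`` is one of {"harmonic", "double_well", "flat"}.  With k_B*T=1
    the Euler-Maruyama update is x += -D * V'(x) * dt + sqrt(2 D dt) * xi.
    Stability of the explicit integrator requires dt < 2 / (D * max V''), which
    is enforced at simulation time.
    """

    potential: str = "double_well"
    parameters: dict = field(default_factory=dict)
    diffusion_coefficient: float = 1.0
    timestep: float = 1e-3
    n_particles: int = 1

    def max_curvature(self) -> float:
        V, dV, (lo, hi) = _potential_functions(self)
        x = np.linspace(lo, hi, 2001)
        d2 = np.gradient(dV(x), x)
        return float(np.max(np.abs(d2)))

    def stability_bound(self) -> float:
        """Largest stable timestep for the explicit Euler-Maruyama scheme."""
        curv = self.max_curvature()
        if curv <= 0 or self.diffusion_coefficient == 0:
            return np.inf
        return 2.0 / (self.diffusion_coefficient * curv)

    def metadata(self) -> dict:
        return {
            "potential": self.potential,
            "parameters": dict(self.parameters),
            "diffusion_coefficient": self.diffusion_coefficient,
            "timestep": self.timestep,
            "n_particles": self.n_particles,
        }


def simulate_diffusion(spec: DiffusionSpec, n_steps: int, seed: int,
                       x0: np.ndarray | None = None) -> np.ndarray:
    """Euler-Maruyama path of shape (n_steps, n_particles).

    Particles are independent copies in the same potential.  The "flat"
    potential lives on a bounded domain with reflecting walls.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    D = spec.diffusion_coefficient
    dt = spec.timestep
    if D > 0 and dt >= spec.stability_bound():
        raise ValueError(
            f"timestep {dt} exceeds the stability bound {spec.stability_bound():.3g} "
            f"for potential {spec.potential!r}"
        )
    V, dV, (lo, hi) = _potential_functions(spec)
    rng = np.random.default_rng(seed)
    if x0 is None:
        if spec.potential == "double_well":
            # start half the particles in each well
            x = np.where(np.arange(spec.n_particles) % 2 == 0, -1.0, 1.0).astype(float)
        elif spec.potential == "flat":
            x = rng.uniform(lo, hi, size=spec.n_particles)
        else:
            x = np.zeros(spec.n_particles)
    else:
        x = np.asarray(x0, dtype=float).copy()
    out = np.empty((n_steps, spec.n_particles))
    out[0] = x
    noise_scale = np.sqrt(2.0 * D * dt)
    for t in range(1, n_steps):
        x = x - D * dV(x) * dt + noise_scale * rng.standard_normal(spec.n_particles)
        if spec.potential == "flat":
            # reflecting boundaries
            x = np.where(x < lo, 2 * lo - x, x)
            x = np.where(x > hi, 2 * hi - x, x)
        out[t] = x
    return out


def reference_timescale(spec: DiffusionSpec, lag: float = 1.0, n_bins: int = 400) -> float:
    """Slowest relaxation timescale by brute force.

    The potential is discretized on a fine uniform grid and a nearest-neighbour
    rate matrix satisfying detailed balance w.r.t. exp(-V) is built:
    k(i -> i+-1) = (D/dx^2) * exp(-(V_{i+-1} - V_i)/2).  The slowest timescale
    is -1/lambda_2 of the rate matrix; it does not depend on ``lag`` (kept in
    the signature so callers can express the timescale in lag units if wanted).
    """
    V, _, (lo, hi) = _potential_functions(spec)
    x = np.linspace(lo, hi, n_bins)
    dx = x[1] - x[0]
    v = V(x)
    D = spec.diffusion_coefficient
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    up = (D / dx**2) * np.exp(-(v[1:] - v[:-1]) / 2.0)    # i -> i+1
    down = (D / dx**2) * np.exp(-(v[:-1] - v[1:]) / 2.0)  # i+1 -> i
    Q = np.zeros((n_bins, n_bins))
    idx = np.arange(n_bins - 1)
    Q[idx, idx + 1] = up
    Q[idx + 1, idx] = down
    Q[np.arange(n_bins), np.arange(n_bins)] = -Q.sum(axis=1)
    # symmetrize with the stationary weights for a stable real eigensolve
    w = np.exp(-v / 2.0)
    S = (w[:, None] * Q) / w[None, :]
    vals = np.linalg.eigvalsh((S + S.T) / 2.0)
    vals = np.sort(vals)[::-1]
    lam2 = vals[1]
    if lam2 >= 0:
        raise RuntimeError("degenerate spectrum in reference discretization")
    return float(-1.0 / lam2)


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_dtrajs(dtrajs: Sequence[np.ndarray], directory: str | Path, prefix: str = "dtraj") -> list[Path]:
    """One integer per line, one file per trajectory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, d in enumerate(dtrajs):
        p = directory / f"{prefix}_{i:04d}.txt"
        np.savetxt(p, np.asarray(d, dtype=np.int64), fmt="%d")
        paths.append(p)
    return paths


def read_dtrajs(paths: Sequence[str | Path]) -> list[np.ndarray]:
    return [np.loadtxt(p, dtype=np.int64, ndmin=1) for p in paths]


def write_continuous_trajectory(traj: np.ndarray, path: str | Path,
                                spec: DiffusionSpec | None = None,
                                seed: int | None = None) -> Path:
    """CSV of frames x coordinates with a JSON sidecar recording spec + seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.atleast_2d(traj), delimiter=",")
    sidecar = {"seed": seed}
    if spec is not None:
        sidecar["spec"] = spec.metadata()
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_continuous_trajectory(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)
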