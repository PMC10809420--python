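"""Coordinate featurization: dihedral angles, pair distances, and the
logistic ("soft contact") transform of pair distances.

All features are invariant to global translation; the distance-based ones are
also rotation invariant.  For synthetic point-mass systems the heavy-atom /
alpha-carbon distance schemes collapse to a single generic scheme (every
particle is its own site); the scheme field is kept so hyperparameter search
spaces carry it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureSpec",
    "dihedral_features",
    "pair_distances",
    "logistic_transform",
    "featurize",
    "feature_names",
]

_KINDS = ("dihedral", "distance", "logistic_distance")
_SCHEMES = ("closest-heavy", "alpha-carbon", "generic")


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature family to compute and with what parameters.

    ``center`` (c, length units) and ``steepness`` (s, inverse length) only
    apply to the logistic distance feature; the study's search space bounds
    them to c in [3, 15] and s in [0.01, 5].
    """

    kind: str = "distance"
    pair_scheme: str = "generic"
    min_sequence_separation: int = 3
    center: float = 9.0
    steepness: float = 1.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.pair_scheme not in _SCHEMES:
            raise ValueError(f"pair_scheme must be one of {_SCHEMES}")
        if self.kind == "logistic_distance":
            if not (3.0 <= self.center <= 15.0):
                raise ValueError("logistic center c must lie in [3, 15]")
            if not (0.01 <= self.steepness <= 5.0):
                raise ValueError("logistic steepness s must lie in [0.01, 5]")


def _as_coords(coords: np.ndarray) -> np.ndarray:
    """Accept (frames, particles) 1-D data or (frames, particles, ndim)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[:, :, None]
    if coords.ndim != 3:
        raise ValueError("coordinates must be (frames, particles[, ndim])")
    return coords


def dihedral_features(coords: np.ndarray,
                      angle_definitions: Sequence[tuple[int, int, int, int]]) -> np.ndarray:
    """Sine and cosine of each signed dihedral angle, two columns per angle.

    The angle follows the standard convention in (-pi, pi]: it is the signed
    rotation of the d-c bond projection relative to the a-b projection about
    the central b-c axis, so a trans (planar zig-zag) arrangement gives pi.
    """
    coords = _as_coords(coords)
    if coords.shape[2] != 3:
        raise ValueError("dihedral angles require 3-D coordinates")
    if coords.shape[1] < 4:
        raise ValueError("dihedral angles need at least 4 particles")
    cols = []
    for quad in angle_definitions:
        if len(set(quad)) != 4:
            raise ValueError(f"angle definition {quad} must index 4 distinct particles")
        a, b, c, d = (coords[:, i] for i in quad)
        b0 = a - b
        b1 = c - b
        b2 = d - c
        b1n = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
        v = b0 - np.sum(b0 * b1n, axis=1, keepdims=True) * b1n
        w = b2 - np.sum(b2 * b1n, axis=1, keepdims=True) * b1n
        x = np.sum(v * w, axis=1)
        y = np.sum(np.cross(b1n, v) * w, axis=1)
        angle = np.arctan2(y, x)
        cols.append(np.sin(angle))
        cols.append(np.cos(angle))
    return np.column_stack(cols)


def _retained_pairs(n_particles: int, min_sep: int) -> list[tuple[int, int]]:
    return [(i, j) for i, j in combinations(range(n_particles), 2) if j - i >= min_sep]


def pair_distances(coords: np.ndarray, spec: FeatureSpec) -> np.ndarray:
    """Distances between particle pairs at least ``min_sequence_separation``
    apart in index, one column per retained pair."""
    if spec.min_sequence_separation < 1:
        raise ValueError("min_sequence_separation must be >= 1")
    coords = _as_coords(coords)
    pairs = _retained_pairs(coords.shape[1], spec.min_sequence_separation)
    if not pairs:
        raise ValueError("no particle pair survives the sequence-separation filter")
    cols = [np.linalg.norm(coords[:, i] - coords[:, j], axis=1) for i, j in pairs]
    return np.column_stack(cols)


def logistic_transform(d, c: float, s: float):
    """Soft contact map logit(d) = 1 / (1 + exp(s (d - c))).

    Strictly decreasing in d, 1/2 at d = c; the large-s limit is a hard
    contact indicator d < c.  Total on all real d (overflow-safe).
    """
    if s <= 0:
        raise ValueError("steepness s must be positive")
    z = np.clip(s * (np.asarray(d, dtype=float) - c), -700, 700)
    return 1.0 / (1.0 + np.exp(z))


def featurize(coords: np.ndarray, spec: FeatureSpec,
              angle_definitions: Sequence[tuple[int, int, int, int]] | None = None) -> np.ndarray:
    """Dispatch on the spec's feature kind."""
    if spec.kind == "dihedral":
        if angle_definitions is None:
            coords3 = _as_coords(coords)
            n = coords3.shape[1]
            angle_definitions = [(i, i + 1, i + 2, i + 3) for i in range(n - 3)]
        return dihedral_features(coords, angle_definitions)
    d = pair_distances(coords, spec)
    if spec.kind == "distance":
        return d
    return logistic_transform(d, spec.center, spec.steepness)


def feature_names(n_particles: int, spec: FeatureSpec) -> list[str]:
    """Column names matching :func:`featurize` for CSV output."""
    if spec.kind == "dihedral":
        quads = range(max(n_particles - 3, 0))
        return [f"{fn}_{i}" for i in quads for fn in ("dihed_sin", "dihed_cos")]
    prefix = "dist" if spec.kind == "distance" else "logit"
    return [f"{prefix}_{i}_{j}" for i, j in _retained_pairs(n_particles, spec.min_sequence_separation)]
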