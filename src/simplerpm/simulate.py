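"""Gaussian rule-manifold simulator with controlled geometry.

Provides representation-level fixtures: ellipsoidal Gaussian manifolds with a
prescribed total variance, participation ratio, centroid separation (signal)
and signal-noise overlap. Used to validate the error theory against direct
trial simulation and as planted input for the training objectives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import ManifoldStats

__all__ = [
    "GaussianManifold",
    "spectrum_with_participation_ratio",
    "planted_pair",
    "planted_clusters",
    "oracle_grid",
    "sample_trial_triples",
]


@dataclass(frozen=True)
class GaussianManifold:
    """Gaussian cloud with given centroid, orthonormal axes and radii."""

    centroid: np.ndarray
    axes: np.ndarray   # (k, N) orthonormal rows
    radii: np.ndarray  # (k,)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, self.radii.size))
        return self.centroid + (z * self.radii) @ self.axes

    def stats(self) -> ManifoldStats:
        """Population statistics (no sampling noise)."""
        order = np.argsort(self.radii)[::-1]
        return ManifoldStats(
            centroid=self.centroid.copy(),
            axes=self.axes[order],
            radii=self.radii[order],
        )


def spectrum_with_participation_ratio(n_dim: int, d_target: float, total: float = 1.0) -> np.ndarray:
    """Geometric variance spectrum r_i^2 = c q^i with participation ratio d_target.

    A smooth spectrum (rather than d_target equal radii padded with zeros)
    mirrors how effective dimensionality behaves in measured representations.
    """
    if not 1.0 <= d_target <= n_dim:
        raise ValueError("participation ratio must lie in [1, n_dim]")
    if d_target == n_dim:
        r2 = np.ones(n_dim)
    else:
        def pr(q):
            r2 = q ** np.arange(n_dim)
            return (r2.sum() ** 2) / np.sum(r2**2)

        q = brentq(lambda q: pr(q) - d_target, 1e-9, 1 - 1e-12)
        r2 = q ** np.arange(n_dim)
    return r2 * (total / r2.sum())


def _random_orthonormal(n: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def planted_pair(
    n_dim: int,
    signal: float,
    dim: float,
    overlap: str | float = "none",
    bias: float = 0.0,
    total_variance: float = 1.0,
    shared_axes: bool = False,
    rng: np.random.Generator | int = 0,
) -> tuple[GaussianManifold, GaussianManifold]:
    """Two Gaussian manifolds with controlled pair geometry.

    ``signal`` is |dx|^2 in units of manifold a's total squared radius;
    ``dim`` the participation ratio of both spectra; ``overlap`` places the
    centroid gap along the leading axis of a ("high"/1.0), its trailing
    axis ("none"/0.0) or an interpolation; ``bias`` sets Rb^2/Ra^2 - 1.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    r2a = spectrum_with_participation_ratio(n_dim, dim, total_variance)
    r2b = spectrum_with_participation_ratio(n_dim, dim, total_variance * (1.0 + bias))
    qa = _random_orthonormal(n_dim, rng)
    qb = qa if shared_axes else _random_orthonormal(n_dim, rng)
    if isinstance(overlap, str):
        overlap = {"none": 0.0, "high": 1.0}[overlap]
    direction = np.sqrt(1.0 - overlap) * qa[-1] + np.sqrt(overlap) * qa[0]
    direction /= np.linalg.norm(direction)
    gap = np.sqrt(signal * r2a.sum()) * direction
    a = GaussianManifold(centroid=np.zeros(n_dim), axes=qa, radii=np.sqrt(r2a))
    b = GaussianManifold(centroid=gap, axes=qb, radii=np.sqrt(r2b))
    return a, b


def planted_clusters(
    n_rules: int,
    n_dim: int,
    signal: float = 4.0,
    dim: float = 5.0,
    rng: np.random.Generator | int = 0,
) -> list[GaussianManifold]:
    """Several rule manifolds with centroids at mutual distance sqrt(signal)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    manifolds = []
    centroids = rng.standard_normal((n_rules, n_dim))
    centroids -= centroids.mean(axis=0)
    norms = np.linalg.norm(centroids, axis=1, keepdims=True)
    centroids *= np.sqrt(signal) / norms
    for c in centroids:
        q = _random_orthonormal(n_dim, rng)
        r2 = spectrum_with_participation_ratio(n_dim, dim, 1.0)
        manifolds.append(GaussianManifold(centroid=c, axes=q, radii=np.sqrt(r2)))
    return manifolds


def oracle_grid(
    n_dim: int = 100,
    signals: Sequence[float] = (0.0, 1.0, 4.0),
    dims: Sequence[float] = (5.0, 50.0),
    overlaps: Sequence[str] = ("none", "high"),
    rng: np.random.Generator | int = 0,
) -> list[tuple[dict, GaussianManifold, GaussianManifold]]:
    """The planted-geometry grid used to validate the error theory (12 points)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    grid = []
    for dim in dims:
        for signal in signals:
            for overlap in overlaps:
                a, b = planted_pair(n_dim, signal, dim, overlap, rng=rng)
                grid.append(({"signal": signal, "dim": dim, "overlap": overlap}, a, b))
    return grid


def sample_trial_triples(
    a: GaussianManifold,
    b: GaussianManifold,
    n: int,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(sample, correct, incorrect) representation triples for pair (a, b)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return a.sample(n, rng), a.sample(n, rng), b.sample(n, rng)
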