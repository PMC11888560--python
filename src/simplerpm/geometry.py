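"""Rule-manifold geometry and the SNR theory of two-choice generalization.

Each rule's cloud of representation vectors (its *rule manifold*) is summarized
by a centroid, orthonormal principal axes and per-axis radii (standard
deviations). For an ordered rule pair (a, b), the two-choice trial margin

    h = ||s - c||^2 - ||s - i||^2,   s, c ~ manifold a,  i ~ manifold b,

determines the generalization error eps_a = P(h > 0). Under a Gaussian
manifold model, the dominant moments of h give the interpretable closed form

    SNR_a = (signal + bias) /
            sqrt(6/D_a + 2 (1+bias)^2 / D_b + 4 xab + 4 ova + 4 ovb)

with
    signal = |dx|^2 / Ra^2              (squared centroid gap over total
                                         squared radius Ra^2 = sum_i R_i^2),
    bias   = Rb^2 / Ra^2 - 1            (relative manifold size difference),
    D      = (sum R_i^2)^2/sum R_i^4    (participation ratio),
    ova/b  = dx' Sigma_{a/b} dx / Ra^4  (signal-noise overlap: squared
                                         projection of the gap on the
                                         radius-scaled axes),
    xab    = tr(Sigma_a Sigma_b)/Ra^4   (noise-noise axis alignment),

and eps_a ~= H(SNR_a) where H is the Gaussian tail. The closed form is
exposed as ``snr_dominant``. Because h is a quadratic form in Gaussians, its
tail probability can also be computed exactly by characteristic-function
inversion; the default ``snr`` is the Gaussian-equivalent margin
Phi^{-1}(1 - eps_exact), so eps = H(snr) holds identically and the two SNRs
agree once D is not small (D >~ 20). The exact route is what makes the error
prediction hold even for low-dimensional manifolds, where the margin is
noticeably skewed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

from .dataset import SplitSpec, ordered_heldout_pairs
from .trials import build_trials, evaluate, random_projection

__all__ = [
    "ManifoldStats",
    "PairGeometry",
    "estimate_manifold",
    "gaussian_tail",
    "pair_snr",
    "closed_form_snr",
    "normalized_overlap",
    "subspace_alignment",
    "layerwise_report",
    "summarize_layerwise",
]


class DegenerateManifoldError(ValueError):
    """All samples identical — no manifold geometry to estimate."""


def gaussian_tail(x) -> float | np.ndarray:
    """H(x) = int_x^inf exp(-t^2/2)/sqrt(2 pi) dt, the upper Gaussian tail."""
    return norm.sf(x)


@dataclass(frozen=True)
class ManifoldStats:
    """Centroid, orthonormal principal axes (rows) and descending radii."""

    centroid: np.ndarray
    axes: np.ndarray      # (k, N), orthonormal rows
    radii: np.ndarray     # (k,), nonnegative, descending

    def __post_init__(self) -> None:
        if self.axes.shape[1] != self.centroid.shape[0]:
            raise ValueError("axes and centroid dimensions disagree")
        if self.axes.shape[0] != self.radii.shape[0]:
            raise ValueError("one radius per axis required")
        if np.any(np.diff(self.radii) > 1e-9):
            raise ValueError("radii must be sorted descending")

    @property
    def n_dim(self) -> int:
        return self.centroid.shape[0]

    @property
    def total_variance(self) -> float:
        """Squared manifold radius R^2 = sum_i R_i^2 (trace of the covariance)."""
        return float(np.sum(self.radii**2))

    @property
    def mean_squared_radius(self) -> float:
        """Per-dimension mean of the variance spectrum, R^2 / N."""
        return self.total_variance / self.n_dim

    @property
    def participation_ratio(self) -> float:
        """D = (sum R_i^2)^2 / sum R_i^4; 1 <= D <= N, = N iff flat spectrum."""
        r2 = self.radii**2
        s = r2.sum()
        if s <= 0:
            raise DegenerateManifoldError("zero-radius manifold has no dimensionality")
        return float(s * s / np.sum(r2 * r2))

    def covariance(self) -> np.ndarray:
        return (self.axes * self.radii[:, None] ** 2).T @ self.axes

    def scaled_axes(self) -> np.ndarray:
        """Rows u_i R_i — the radius-scaled axes entering the overlap terms."""
        return self.axes * self.radii[:, None]


def estimate_manifold(X: np.ndarray) -> ManifoldStats:
    """Manifold statistics of a samples-by-features matrix.

    Centroid is the sample mean; axes and radii come from the spectrum of the
    unbiased sample covariance (radii^2 = per-axis variance). Requires at
    least two distinct samples.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    if not np.any(np.abs(Xc) > 0):
        raise DegenerateManifoldError("all samples identical")
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(X.shape[0] - 1, X.shape[1])
    radii = s[:k] / np.sqrt(X.shape[0] - 1)
    return ManifoldStats(centroid=centroid, axes=Vt[:k], radii=radii)


@dataclass(frozen=True)
class PairGeometry:
    """Geometric terms and SNR of an ordered rule pair (a, b)."""

    signal: float
    bias: float
    inv_dimensionality: float
    overlap_a: float
    overlap_b: float
    cross_overlap: float
    snr_dominant: float
    snr: float
    predicted_error: float
    signal_direction: np.ndarray


def _pair_terms(a: ManifoldStats, b: ManifoldStats):
    if a.n_dim != b.n_dim:
        raise ValueError("manifolds live in different dimensions")
    Ta, Tb = a.total_variance, b.total_variance
    if Ta <= 0:
        raise DegenerateManifoldError("reference manifold has zero radius")
    delta = b.centroid - a.centroid
    ua, ub = a.scaled_axes(), b.scaled_axes()
    o_a = float(np.sum((ua @ delta) ** 2))      # delta' Sigma_a delta
    o_b = float(np.sum((ub @ delta) ** 2))
    cross = float(np.sum((ua @ ub.T) ** 2))     # tr(Sigma_a Sigma_b)
    return Ta, Tb, delta, o_a, o_b, cross


def closed_form_snr(a: ManifoldStats, b: ManifoldStats) -> float:
    """Dominant-terms SNR from the first two moments of the trial margin."""
    Ta, Tb, delta, o_a, o_b, cross = _pair_terms(a, b)
    num = float(delta @ delta) + Tb - Ta
    r4a = float(np.sum(a.radii**4))
    r4b = float(np.sum(b.radii**4))
    var = 6 * r4a + 2 * r4b + 4 * cross + 4 * o_a + 4 * o_b
    if var <= 0:
        raise DegenerateManifoldError("margin variance vanishes (point manifolds)")
    return num / np.sqrt(var)


# ---------------------------------------------------------------------------
# exact margin tail for Gaussian manifolds


def _margin_tail_probability(a: ManifoldStats, b: ManifoldStats) -> float:
    """P(h > 0) for Gaussian manifolds, by Imhof/Gil-Pelaez inversion.

    The computation is performed in the joint span of both manifolds' axes and
    the centroid gap, where h = sum_i lam_i z_i^2 + g_i z_i + c in independent
    standard normals.
    """
    delta = b.centroid - a.centroid
    # orthonormal basis of the joint span (axes already orthonormal per manifold)
    stack = [a.scaled_axes(), b.scaled_axes(), delta[None, :]]
    B = np.concatenate(stack, axis=0)
    q, r = np.linalg.qr(B.T)
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r).max())
    B = q[:, keep].T                          # (d, N) orthonormal rows
    d = B.shape[0]
    Sa = B @ a.covariance() @ B.T
    Sb = B @ b.covariance() @ B.T
    dv = B @ delta

    Z = np.zeros((d, d))
    eye = np.eye(d)
    Q = np.block([[Z, -eye, eye], [-eye, eye, Z], [eye, Z, -eye]])
    bvec = np.concatenate([2 * dv, np.zeros(d), -2 * dv])
    c = -float(dv @ dv) - float(delta @ delta - dv @ dv)  # gap may exit the span

    def msqrt(S):
        w, V = np.linalg.eigh(S)
        return (V * np.sqrt(np.clip(w, 0, None))) @ V.T
    Ra, Rb = msqrt(Sa), msqrt(Sb)
    Sh = np.block([[Ra, Z, Z], [Z, Ra, Z], [Z, Z, Rb]])
    A = Sh @ Q @ Sh
    A = (A + A.T) / 2
    lam, U = np.linalg.eigh(A)
    g = U.T @ (Sh @ bvec)

    scale = np.max(np.abs(lam)) if lam.size else 0.0
    nz = np.abs(lam) > 1e-12 * max(scale, 1.0)
    l, gn = lam[nz], g[nz]
    sig0 = float(np.sqrt(np.sum(g[~nz] ** 2)))
    if l.size == 0:
        if sig0 == 0.0:
            return 0.5 if c == 0 else float(c > 0)
        return float(norm.cdf(c / sig0))
    m = gn / (2 * l)
    c0 = c - float(np.sum(l * m * m))

    def imag_cf(u):
        den = 1 - 2j * l * u
        val = (
            np.exp(1j * u * c0 - 0.5 * sig0**2 * u**2)
            * np.prod(den**-0.5)
            * np.exp(np.sum(1j * l * u * m * m / den))
        )
        return val.imag

    val, _ = integrate.quad(lambda u: imag_cf(u) / u, 0.0, np.inf, limit=400)
    return float(np.clip(0.5 + val / np.pi, 0.0, 1.0))


_SNR_CLIP = 8.0  # |Phi^-1| ceiling when the exact tail under/overflows


def pair_snr(a: ManifoldStats, b: ManifoldStats, method: str = "exact") -> PairGeometry:
    """Geometry terms, SNR and predicted error for the ordered pair (a, b).

    ``method="exact"`` (default) predicts the error exactly under the
    Gaussian-manifold model and reports the Gaussian-equivalent SNR;
    ``method="dominant"`` uses the interpretable closed form directly. The
    result is asymmetric in (a, b): swapping the pair flips the sign of the
    bias and re-normalizes by the new reference manifold.
    """
    Ta, Tb, delta, o_a, o_b, cross = _pair_terms(a, b)
    signal = float(delta @ delta) / Ta
    bias = Tb / Ta - 1.0
    snr_dom = closed_form_snr(a, b)
    if method == "dominant":
        snr = snr_dom
        err = float(gaussian_tail(snr))
    elif method == "exact":
        err = _margin_tail_probability(a, b)
        if err <= 0.0 or err >= 1.0:
            snr = _SNR_CLIP if err <= 0.0 else -_SNR_CLIP
            err = float(gaussian_tail(snr))
        else:
            snr = float(norm.isf(err))
    else:
        raise ValueError(f"unknown method {method!r}")
    return PairGeometry(
        signal=signal,
        bias=bias,
        inv_dimensionality=1.0 / a.participation_ratio,
        overlap_a=o_a / Ta**2,
        overlap_b=o_b / Ta**2,
        cross_overlap=cross / Ta**2,
        snr_dominant=snr_dom,
        snr=snr,
        predicted_error=err,
        signal_direction=delta,
    )


def normalized_overlap(pg: PairGeometry) -> float:
    """Signal-noise overlap normalized by signal magnitude.

    Distinguishes genuine alignment of the manifolds' axes with the signal
    direction from a merely large signal; invariant under joint rescaling of
    radii and centroid gap.
    """
    if pg.signal <= 0:
        raise ValueError("normalized overlap undefined at zero signal")
    return (pg.overlap_a + pg.overlap_b) / pg.signal


def subspace_alignment(
    heldout_X: np.ndarray,
    train_X: np.ndarray | Sequence[np.ndarray],
    k: int = 35,
) -> float:
    """Fraction of held-out variance inside the top-k training-rule PCs.

    The principal components are computed from all pooled training-rule rows
    (capturing rule centroids and within-rule variation); held-out rows are
    centered on the training mean and their energy fraction within the
    subspace returned. 1.0 means full containment, 0.0 orthogonality.
    """
    if not isinstance(train_X, np.ndarray):
        train_X = np.concatenate([np.asarray(x) for x in train_X], axis=0)
    train_X = np.asarray(train_X, dtype=float)
    mu = train_X.mean(axis=0)
    Xc = train_X - mu
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the training representation rank {rank}")
    V = Vt[:k]
    H = np.asarray(heldout_X, dtype=float) - mu
    total = float(np.sum(H * H))
    if total == 0:
        raise DegenerateManifoldError("held-out data coincides with the training mean")
    return float(np.sum((H @ V.T) ** 2) / total)


# ---------------------------------------------------------------------------
# layer-wise driver


def layerwise_report(
    extractors: Mapping[str, Callable],
    rows_by_rule: Mapping[int, Sequence],
    split: SplitSpec,
    n_trials: int = 500,
    projection_dim: int | None = 400,
    rng: np.random.Generator | int = 0,
    method: str = "exact",
) -> pd.DataFrame:
    """Per-layer error and geometry over the ordered held-out pairs.

    ``extractors`` maps layer names to row -> feature-vector callables (any
    encoder's intermediate stages). Each layer's features are passed through a
    seeded random projection to ``projection_dim`` before scoring and
    geometric analysis, so layers of different widths are compared at a fixed
    dimensionality.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    records = []
    pairs = ordered_heldout_pairs(split)
    for layer, fn in extractors.items():
        proj: dict[str, np.ndarray] = {}
        proj_seed = int(rng.integers(2**31))

        def rep(row, _fn=fn, _proj=proj, _seed=proj_seed):
            v = np.asarray(_fn(row), dtype=float).ravel()
            if projection_dim is None:
                return v
            if "P" not in _proj:
                _proj["P"] = random_projection(v.size, projection_dim, _seed)
            elif _proj["P"].shape[0] != v.size:
                raise ValueError(f"layer {layer!r}: feature dimension changed across rows")
            return v @ _proj["P"]

        reps = {r: np.stack([rep(row) for row in rows_by_rule[r]]) for r in split.heldout_rules}
        stats = {r: estimate_manifold(X) for r, X in reps.items()}
        for a, b in pairs:
            trials = build_trials(a, b, rows_by_rule[a], rows_by_rule[b], n=n_trials, rng=rng)
            lookup = {id(row): i for r in (a, b) for i, row in enumerate(rows_by_rule[r])}
            err, _ = evaluate(trials, lambda row: reps[row.rule.rule_id][lookup[id(row)]])
            pg = pair_snr(stats[a], stats[b], method=method)
            records.append(
                {
                    "layer": layer,
                    "rule_a": a,
                    "rule_b": b,
                    "error": err,
                    "predicted_error": pg.predicted_error,
                    "snr": pg.snr,
                    "signal": pg.signal,
                    "bias": pg.bias,
                    "dimensionality": 1.0 / pg.inv_dimensionality,
                    "overlap": normalized_overlap(pg) if pg.signal > 0 else np.nan,
                }
            )
    return pd.DataFrame.from_records(records)


def summarize_layerwise(report: pd.DataFrame) -> pd.DataFrame:
    """Mean and s.e.m. of each metric per layer, aggregated over rule pairs."""
    metrics = [c for c in report.columns if c not in ("layer", "rule_a", "rule_b")]
    grouped = report.groupby("layer", sort=False)[metrics]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    return mean.join(sem)
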