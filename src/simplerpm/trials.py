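"""Two-alternative trials and Euclidean nearest-choice scoring.

A trial presents a sample row governed by rule ``a``, a correct choice (a
second, distinct row of rule ``a``) and an incorrect choice (a row of rule
``b``). A representation function maps rows to fixed-dimension vectors; the
trial is scored correct when the correct choice is *strictly* closer to the
sample in Euclidean distance. Ties count as incorrect — the case has measure
zero for non-degenerate representations, and the convention makes the
behavior of collapsed (constant) representations well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .dataset import SplitSpec, ordered_heldout_pairs
from .render import render_row
from .rules import RowSpec

__all__ = [
    "Trial",
    "build_trials",
    "evaluate",
    "evaluate_arrays",
    "PixelRepresentation",
    "pixel_baseline",
    "generalization_error",
    "random_projection",
]


@dataclass(frozen=True)
class Trial:
    """(sample, correct, incorrect) rows for the ordered rule pair (a, b)."""

    sample: RowSpec
    correct: RowSpec
    incorrect: RowSpec
    rule_pair: tuple[int, int]
    trial_uid: str = ""


class InsufficientRowsError(ValueError):
    """Not enough distinct rows to build the requested number of unique trials."""


def build_trials(
    rule_a: int,
    rule_b: int,
    rows_a: Sequence[RowSpec],
    rows_b: Sequence[RowSpec],
    n: int = 500,
    rng: np.random.Generator | int = 0,
) -> list[Trial]:
    """Build ``n`` unique trials for the ordered pair (rule_a, rule_b).

    Sample and correct rows are distinct rows of rule_a; the incorrect row is
    drawn from rule_b. Uniqueness is at the level of (sample, correct,
    incorrect) index triples. Deterministic given the seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_a, n_b = len(rows_a), len(rows_b)
    if n_a < 2 or n_b < 1 or n_a * (n_a - 1) * n_b < n:
        raise InsufficientRowsError(
            f"cannot build {n} unique trials from {n_a} rule-{rule_a} rows "
            f"and {n_b} rule-{rule_b} rows"
        )
    seen: set[tuple[int, int, int]] = set()
    trials: list[Trial] = []
    while len(trials) < n:
        i, j = rng.choice(n_a, size=2, replace=False)
        k = int(rng.integers(n_b))
        key = (int(i), int(j), k)
        if key in seen:
            continue
        seen.add(key)
        trials.append(
            Trial(
                sample=rows_a[int(i)],
                correct=rows_a[int(j)],
                incorrect=rows_b[k],
                rule_pair=(rule_a, rule_b),
                trial_uid=f"p{rule_a:02d}-{rule_b:02d}-t{len(trials):05d}",
            )
        )
    return trials


def evaluate_arrays(sample: np.ndarray, correct: np.ndarray, incorrect: np.ndarray) -> tuple[float, np.ndarray]:
    """Score pre-computed representation triples; returns (error, outcomes)."""
    if not sample.shape == correct.shape == incorrect.shape:
        raise ValueError("representation matrices must share a shape")
    d_c = np.sum((sample - correct) ** 2, axis=1)
    d_i = np.sum((sample - incorrect) ** 2, axis=1)
    outcomes = d_c < d_i  # strict: ties are incorrect
    return float(np.mean(~outcomes)), outcomes


def evaluate(trials: Sequence[Trial], rep: Callable[[RowSpec], np.ndarray]) -> tuple[float, np.ndarray]:
    """Error rate of a representation function on a trial set.

    The representation is evaluated once per distinct row (cached by row
    identity) and must return a fixed-dimension vector.
    """
    cache: dict = {}

    def embed(row: RowSpec) -> np.ndarray:
        key = id(row)
        if key not in cache:
            v = np.asarray(rep(row), dtype=float).ravel()
            cache[key] = v
        return cache[key]

    reps = [(embed(t.sample), embed(t.correct), embed(t.incorrect)) for t in trials]
    dims = {v.shape for triple in reps for v in triple}
    if len(dims) != 1:
        raise ValueError(f"representation dimensions differ across rows: {dims}")
    s, c, i = (np.stack(x) for x in zip(*reps))
    return evaluate_arrays(s, c, i)


def random_projection(in_dim: int, out_dim: int, rng: np.random.Generator | int) -> np.ndarray:
    """Seeded Gaussian projection, entries N(0, 1)/sqrt(out_dim)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return rng.standard_normal((in_dim, out_dim)) / np.sqrt(out_dim)


class PixelRepresentation:
    """Row -> flattened pixels, optionally through a seeded random projection.

    The projection matrix is built lazily on the first call (when the input
    dimension is known) and reused; with ``projection_dim=None`` raw flattened
    pixels (dimension 3*160*160) are returned.
    """

    def __init__(self, projection_dim: int | None = 400, seed: int = 0):
        self.projection_dim = projection_dim
        self.seed = seed
        self._matrix: np.ndarray | None = None
        self._cache: dict[int, np.ndarray] = {}

    def __call__(self, row: RowSpec) -> np.ndarray:
        key = id(row)
        if key in self._cache:
            return self._cache[key]
        x = render_row(row).astype(np.float32).ravel()
        if self.projection_dim is not None:
            if self._matrix is None:
                self._matrix = random_projection(
                    x.size, self.projection_dim, np.random.default_rng(self.seed)
                ).astype(np.float32)
            x = x @ self._matrix
        self._cache[key] = x
        return x


def pixel_baseline(
    trials: Sequence[Trial],
    projection_dim: int | None = 400,
    rng: np.random.Generator | int = 0,
) -> float:
    """Error of the raw pixel representation (optionally 400-dim projected)."""
    seed = int(rng if isinstance(rng, (int, np.integer)) else rng.integers(2**31))
    rep = PixelRepresentation(projection_dim=projection_dim, seed=seed)
    error, _ = evaluate(trials, rep)
    return error


def generalization_error(
    rows_by_rule: dict[int, Sequence[RowSpec]],
    split: SplitSpec,
    rep: Callable[[RowSpec], np.ndarray],
    n_trials: int = 500,
    rng: np.random.Generator | int = 0,
) -> tuple[float, dict[tuple[int, int], float]]:
    """Mean two-choice error over the 20 ordered held-out pairs of a split."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    per_pair: dict[tuple[int, int], float] = {}
    for a, b in ordered_heldout_pairs(split):
        trials = build_trials(a, b, rows_by_rule[a], rows_by_rule[b], n=n_trials, rng=rng)
        err, _ = evaluate(trials, rep)
        per_pair[(a, b)] = err
    return float(np.mean(list(per_pair.values()))), per_pair
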