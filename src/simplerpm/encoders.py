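"""Encoders mapping rows (or arbitrary feature vectors) to relational representations.

Two reference encoders are provided, both plain numpy with hand-coded
backward passes: a linear map, and a panel-wise dense feature extractor with
a shared relational head over the concatenated panel features (the structural
sketch of relational architectures — per-panel encoding followed by
cross-panel integration — at desk scale). The ``Encoder`` interface is what
the training loop consumes, so any external model can be plugged in by
implementing ``forward``/``backward``/``params``/``grads``.
"""

from __future__ import annotations

import numpy as np

from .render import render_row

__all__ = ["Encoder", "LinearEncoder", "RelationalMLPEncoder", "rows_to_batch"]


def rows_to_batch(rows) -> np.ndarray:
    """Render rows to a (B, 3*160*160) float matrix scaled to [0, 1]."""
    return np.stack([render_row(r).astype(np.float32).ravel() for r in rows]) / 255.0


class Encoder:
    """Minimal trainable-encoder interface."""

    def forward(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dZ: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:  # pragma: no cover - interface
        raise NotImplementedError

    def grads(self) -> dict[str, np.ndarray]:  # pragma: no cover - interface
        raise NotImplementedError

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params().items():
            v[...] = state[k]


class LinearEncoder(Encoder):
    """Z = X W (+ b)."""

    def __init__(self, in_dim: int, out_dim: int, bias: bool = True, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = rng.standard_normal((in_dim, out_dim)) / np.sqrt(in_dim)
        self.b = np.zeros(out_dim) if bias else None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b) if bias else None
        self._X: np.ndarray | None = None

    def forward(self, X: np.ndarray) -> np.ndarray:
        self._X = np.asarray(X, dtype=float)
        Z = self._X @ self.W
        return Z if self.b is None else Z + self.b

    def backward(self, dZ: np.ndarray) -> np.ndarray:
        self.dW = self._X.T @ dZ
        if self.b is not None:
            self.db = dZ.sum(axis=0)
        return dZ @ self.W.T

    def params(self):
        p = {"W": self.W}
        if self.b is not None:
            p["b"] = self.b
        return p

    def grads(self):
        g = {"W": self.dW}
        if self.b is not None:
            g["b"] = self.db
        return g


def _relu(x):
    return np.maximum(x, 0.0)


class RelationalMLPEncoder(Encoder):
    """Shared per-panel dense features + relational head over all panels.

    Input is a (B, 3*panel_dim) matrix of flattened rows. Each panel passes
    through a shared dense+ReLU layer; the concatenated panel features pass
    through a dense+ReLU relational layer and a linear projection to the
    representation space.
    """

    def __init__(
        self,
        panel_dim: int = 160 * 160,
        panel_features: int = 64,
        relational_features: int = 128,
        out_dim: int = 64,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.panel_dim = panel_dim
        init = lambda m, n: rng.standard_normal((m, n)) * np.sqrt(2.0 / m)
        self.p = {
            "W1": init(panel_dim, panel_features),
            "b1": np.zeros(panel_features),
            "W2": init(3 * panel_features, relational_features),
            "b2": np.zeros(relational_features),
            "W3": init(relational_features, out_dim) / np.sqrt(2.0),
            "b3": np.zeros(out_dim),
        }
        self.g = {k: np.zeros_like(v) for k, v in self.p.items()}
        self._cache: dict = {}

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        B = X.shape[0]
        panels = X.reshape(B * 3, self.panel_dim)
        a1 = panels @ self.p["W1"] + self.p["b1"]
        h1 = _relu(a1).reshape(B, -1)
        a2 = h1 @ self.p["W2"] + self.p["b2"]
        h2 = _relu(a2)
        Z = h2 @ self.p["W3"] + self.p["b3"]
        self._cache = {"panels": panels, "a1": a1, "h1": h1, "a2": a2, "h2": h2, "B": B}
        return Z

    def backward(self, dZ: np.ndarray) -> np.ndarray:
        c = self._cache
        self.g["W3"] = c["h2"].T @ dZ
        self.g["b3"] = dZ.sum(axis=0)
        dh2 = dZ @ self.p["W3"].T
        da2 = dh2 * (c["a2"] > 0)
        self.g["W2"] = c["h1"].T @ da2
        self.g["b2"] = da2.sum(axis=0)
        dh1 = (da2 @ self.p["W2"].T).reshape(c["B"] * 3, -1)
        da1 = dh1 * (c["a1"] > 0)
        self.g["W1"] = c["panels"].T @ da1
        self.g["b1"] = da1.sum(axis=0)
        dX = (da1 @ self.p["W1"].T).reshape(c["B"], -1)
        return dX

    def params(self):
        return self.p

    def grads(self):
        return self.g
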