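"""Rasterization of row specifications into 3x160x160 grayscale arrays.

Objects are drawn as filled binary masks (no anti-aliasing) so renders are
bit-exact across platforms. A pixel belongs to an object when its center lies
inside the shape. Shapes are drawn vertex-up, scaled so the ink's vertical
extent equals the size value (the bounding-box height); the pentagon and star,
whose regular vertex-up forms are ~5% wider than tall, are squeezed
horizontally to keep every object inside its [40,40] bounding box (the grid
pitch is 40 px, so wider shapes at adjacent cells could otherwise touch).
Shapes with a rotational symmetry axis through the center have their ink
centroid at the cell centroid by construction; the triangle is placed so its
area centroid (not its box center) sits on the cell centroid.

The background is white (255); shades span 230 (close to white) down to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from PIL import Image

from .rules import (
    POSITION_CENTROIDS,
    SHADE_LEVELS,
    SHAPE_NAMES,
    SIZE_HEIGHTS,
    ObjectSpec,
    RowSpec,
)

__all__ = [
    "PANEL_SIZE",
    "BACKGROUND",
    "RowImage",
    "render_panel",
    "render_row",
    "write_png",
]

PANEL_SIZE = 160
BACKGROUND = 255


class PanelLayoutError(ValueError):
    """Two objects assigned to the same grid cell."""


@dataclass(frozen=True)
class RowImage:
    """Rendered row: (3, 160, 160) uint8 pixels plus provenance."""

    pixels: np.ndarray
    rule_id: int
    row_uid: str = ""

    def __post_init__(self) -> None:
        if self.pixels.shape != (3, PANEL_SIZE, PANEL_SIZE):
            raise ValueError(f"expected (3,160,160), got {self.pixels.shape}")


def _shape_vertices(shape: str, h: float) -> np.ndarray | None:
    """Polygon vertices (math coords, y up) centered on the ink centroid.

    Returns None for the circle (handled analytically).
    """
    if shape == "circle":
        return None
    if shape == "square":
        r = h / 2.0
        return np.array([(-r, -r), (r, -r), (r, r), (-r, r)])
    if shape == "triangle":
        # isoceles, vertex up, area centroid at the origin
        return np.array([(0.0, 2.0 * h / 3.0), (-h / 2.0, -h / 3.0), (h / 2.0, -h / 3.0)])
    if shape in ("pentagon", "hexagon", "octagon"):
        n = {"pentagon": 5, "hexagon": 6, "octagon": 8}[shape]
        ang = np.pi / 2 + 2 * np.pi * np.arange(n) / n
        v = np.column_stack([np.cos(ang), np.sin(ang)])
    elif shape == "star":
        outer = np.pi / 2 + 2 * np.pi * np.arange(5) / 5
        inner = outer + np.pi / 5
        ratio = math.sin(math.pi / 10) / math.sin(3 * math.pi / 10)  # pentagram
        v = np.empty((10, 2))
        v[0::2] = np.column_stack([np.cos(outer), np.sin(outer)])
        v[1::2] = ratio * np.column_stack([np.cos(inner), np.sin(inner)])
    else:  # pragma: no cover - shape names are validated upstream
        raise ValueError(f"unknown shape {shape!r}")
    # scale so the vertical ink extent equals h, cap the width at h
    vspan = v[:, 1].max() - v[:, 1].min()
    v *= h / vspan
    hspan = v[:, 0].max() - v[:, 0].min()
    if hspan > h:
        v[:, 0] *= h / hspan
    return v


def _object_mask(obj: ObjectSpec) -> tuple[np.ndarray, int, int]:
    """Boolean ink mask for one object plus its (row0, col0) placement."""
    h = float(SIZE_HEIGHTS[obj.size])
    cx, cy = POSITION_CENTROIDS[obj.position]
    shape = SHAPE_NAMES[obj.shape]

    half = h / 2.0 + 1.5  # margin for the off-center triangle/pentagon extents
    r0 = max(int(math.floor(cy - half)), 0)
    r1 = min(int(math.ceil(cy + half)) + 1, PANEL_SIZE)
    c0 = max(int(math.floor(cx - half)), 0)
    c1 = min(int(math.ceil(cx + half)) + 1, PANEL_SIZE)

    # pixel centers relative to the cell centroid; image rows grow downward
    px = np.arange(c0, c1) + 0.5 - cx
    py = cy - (np.arange(r0, r1) + 0.5)
    X, Y = np.meshgrid(px, py)

    verts = _shape_vertices(shape, h)
    if verts is None:
        mask = X * X + Y * Y <= (h / 2.0) ** 2
    else:
        pts = np.column_stack([X.ravel(), Y.ravel()])
        mask = MplPath(verts).contains_points(pts, radius=1e-9).reshape(X.shape)
    return mask, r0, c0


def render_panel(panel: tuple[ObjectSpec, ...]) -> np.ndarray:
    """Rasterize one panel to a (160, 160) uint8 grid, background 255."""
    positions = [o.position for o in panel]
    if len(set(positions)) != len(positions):
        raise PanelLayoutError("two objects share a grid cell")
    img = np.full((PANEL_SIZE, PANEL_SIZE), BACKGROUND, dtype=np.uint8)
    for obj in panel:
        mask, r0, c0 = _object_mask(obj)
        h, w = mask.shape
        region = img[r0 : r0 + h, c0 : c0 + w]
        region[mask] = SHADE_LEVELS[obj.shade]
    return img


def render_row(row: RowSpec, layout: str = "stacked") -> np.ndarray:
    """Rasterize a row.

    layout="stacked" gives the (3, 160, 160) model input; "horizontal"
    concatenates panels left-to-right into (160, 480) for human display.
    """
    panels = np.stack([render_panel(p) for p in row.panels])
    if layout == "stacked":
        return panels
    if layout == "horizontal":
        return np.concatenate(list(panels), axis=1)
    raise ValueError(f"unknown layout {layout!r}")


def write_png(row: RowSpec, path, layout: str = "horizontal") -> None:
    """Write a row as a PNG image (horizontal layout by default)."""
    arr = render_row(row, layout=layout)
    if arr.ndim == 3:
        arr = np.concatenate(list(arr), axis=1)
    Image.fromarray(arr, mode="L").save(path)
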