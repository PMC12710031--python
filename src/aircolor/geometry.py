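"""Projective-geometry and rasterization helpers shared across modules.

Pixel convention: image pixel (i, j) (row, column, 0-based) has its center
at continuous coordinates (x, y) = (j + 0.5, i + 0.5). A pixel belongs to a
polygon iff its center lies inside; this half-open convention means
adjacent polygons never double-count a pixel.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path


def project_points(homography: np.ndarray, points) -> np.ndarray:
    """Apply a 3x3 homography to (n, 2) xy points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    h = np.asarray(homography, dtype=float)
    ones = np.ones((pts.shape[0], 1))
    out = np.hstack([pts, ones]) @ h.T
    with np.errstate(divide="ignore", invalid="ignore"):
        return out[:, :2] / out[:, 2:3]


def polygon_is_convex(poly) -> bool:
    """True iff the 4-point polygon is convex and non-self-intersecting."""
    p = np.asarray(poly, dtype=float)
    if p.shape != (4, 2) or not np.all(np.isfinite(p)):
        return False
    crosses = []
    for i in range(4):
        a, b, c = p[i], p[(i + 1) % 4], p[(i + 2) % 4]
        u, v = b - a, c - b
        crosses.append(u[0] * v[1] - u[1] * v[0])
    crosses = np.asarray(crosses)
    if np.any(crosses == 0):
        return False
    return bool(np.all(crosses > 0) or np.all(crosses < 0))


def pixels_in_polygon(poly_xy, image_shape) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels whose centers fall inside the polygon.

    Returns (rows, cols), restricted to the image bounds.
    """
    poly = np.asarray(poly_xy, dtype=float)
    h, w = image_shape[:2]
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())), w)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())), h)
    if x1 <= x0 or y1 <= y0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cols, rows = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    centers = np.column_stack([cols.ravel() + 0.5, rows.ravel() + 0.5])
    inside = Path(poly).contains_points(centers)
    return rows.ravel()[inside], cols.ravel()[inside]


def polygon_raster(poly_xy, image_shape, value: int = 255) -> np.ndarray:
    """Binary uint8 raster of the polygon under the pixel-center convention."""
    mask = np.zeros(image_shape[:2], dtype=np.uint8)
    rr, cc = pixels_in_polygon(poly_xy, image_shape)
    mask[rr, cc] = value
    return mask


def scale_polygon_about_center(poly_xy, scale_x: float, scale_y: float,
                               center=None) -> np.ndarray:
    """Scale polygon vertices about a center point (default: vertex mean)."""
    poly = np.asarray(poly_xy, dtype=float)
    c = poly.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    out = poly.copy()
    out[:, 0] = c[0] + (poly[:, 0] - c[0]) * scale_x
    out[:, 1] = c[1] + (poly[:, 1] - c[1]) * scale_y
    return out
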