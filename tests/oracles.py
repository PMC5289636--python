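"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths: connected
components and holes come from scipy flood-fill labeling, polyline
simplification from a direct recursive implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from swarmscan.contours import Connectivity

_S8 = np.ones((3, 3), dtype=int)
_S4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def component_count(img: np.ndarray, conn: Connectivity) -> int:
    """Foreground component count by scipy labeling."""
    s = _S8 if conn is Connectivity.FG8_BG4 else _S4
    return int(ndimage.label(img, structure=s)[1])


def hole_count(img: np.ndarray, conn: Connectivity) -> int:
    """0-components not connected to the frame, under the dual connectivity."""
    s = _S4 if conn is Connectivity.FG8_BG4 else _S8
    labels, n = ndimage.label(1 - np.asarray(img), structure=s)
    touching = (
        set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    )
    touching.discard(0)
    return int(n - len(touching))


def component_pixel_sets(img: np.ndarray, conn: Connectivity) -> list[set]:
    s = _S8 if conn is Connectivity.FG8_BG4 else _S4
    labels, n = ndimage.label(img, structure=s)
    return [set(zip(*np.nonzero(labels == k))) for k in range(1, n + 1)]


def rdp_recursive(points: list[tuple[float, float]], eps: float) -> list:
    """Textbook recursive Ramer-Douglas-Peucker on an open chain."""
    if len(points) < 3:
        return list(points)
    ax, ay = points[0]
    bx, by = points[-1]
    dx, dy = bx - ax, by - ay
    norm = math.hypot(dx, dy)
    best_d, best_k = -1.0, 0
    for k in range(1, len(points) - 1):
        px, py = points[k]
        if norm == 0:
            d = math.hypot(px - ax, py - ay)
        else:
            d = abs(dx * (py - ay) - dy * (px - ax)) / norm
        if d > best_d:
            best_d, best_k = d, k
    if best_d > eps:
        left = rdp_recursive(points[: best_k + 1], eps)
        right = rdp_recursive(points[best_k:], eps)
        return left[:-1] + right
    return [points[0], points[-1]]


def random_binary_image(rng: np.random.Generator, max_side: int = 32) -> np.ndarray:
    h, w = rng.integers(1, max_side + 1, 2)
    p = rng.uniform(0.05, 0.95)
    return (rng.random((h, w)) < p).astype(np.uint8)


def point_in_polygon(x: float, y: float, poly: np.ndarray) -> bool:
    """Ray casting, used by the Monte-Carlo area oracle."""
    inside = False
    n = len(poly)
    for k in range(n):
        x1, y1 = poly[k]
        x2, y2 = poly[(k + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside
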