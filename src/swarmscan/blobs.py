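"""Blob extraction: polygon simplification, moments and size filtering.

Outer borders become simplified polygons via Ramer-Douglas-Peucker; the
shoelace moments of the polygon give each blob its area and centroid.
Coordinates here are ``(x, y)`` = (column, row) floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import BorderHierarchy
from .imaging import ROI

__all__ = ["Blob", "simplify_polygon", "polygon_moments", "make_blobs", "filter_blobs"]

#: default RDP tolerance (px) and blob-size acceptance window (px^2)
DEFAULT_EPSILON = 1.0
DEFAULT_MIN_AREA = 1.0
DEFAULT_MAX_AREA = 400.0

_DEGENERATE_AREA = 1e-9


@dataclass(frozen=True)
class Blob:
    """One detected body: simplified polygon, centroid, area, bounding box."""

    polygon: tuple[tuple[float, float], ...]
    centroid: tuple[float, float]
    area: float
    bbox: tuple[float, float, float, float]  # (x0, y0, w, h)


def _perp_distances(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Perpendicular distance of each point to the line through a and b.

    Falls back to euclidean distance to ``a`` when the chord is degenerate.
    """
    d = b - a
    norm = float(np.hypot(d[0], d[1]))
    if norm == 0.0:
        return np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1])
    cross = d[0] * (pts[:, 1] - a[1]) - d[1] * (pts[:, 0] - a[0])
    return np.abs(cross) / norm


def _rdp_keep_mask(pts: np.ndarray, epsilon: float) -> np.ndarray:
    """Keep-mask of the open-chain RDP simplification (iterative)."""
    n = len(pts)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        s, e = stack.pop()
        if e - s < 2:
            continue
        dist = _perp_distances(pts[s + 1 : e], pts[s], pts[e])
        k = int(np.argmax(dist))
        if dist[k] > epsilon:
            m = s + 1 + k
            keep[m] = True
            stack.append((s, m))
            stack.append((m, e))
    return keep


def simplify_polygon(
    points, epsilon: float, *, closed: bool = False
) -> np.ndarray:
    """Ramer-Douglas-Peucker simplification of a point chain.

    Open chains keep both endpoints.  Closed chains (border cycles) are
    anchored at the two mutually most distant points and each half is
    simplified independently; the result starts at the first anchor, so
    it is a subsequence of the input read cyclically.

    Every discarded point lies within perpendicular distance ``epsilon``
    of the retained chord spanning it.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an Nx2 point list, got shape {pts.shape}")
    if len(pts) == 0:
        raise ValueError("point list must be non-empty")
    if len(pts) <= 2:
        return pts.copy()

    if not closed:
        return pts[_rdp_keep_mask(pts, epsilon)]

    # Closed cycle: anchor at the diameter pair (i < k), simplify both arcs.
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, k = np.unravel_index(int(np.argmax(d2)), d2.shape)
    if d2[i, k] == 0.0:  # all points coincide
        return pts[:1].copy()
    if i > k:
        i, k = k, i
    arc1 = pts[i : k + 1]
    arc2 = np.concatenate([pts[k:], pts[: i + 1]])
    out1 = arc1[_rdp_keep_mask(arc1, epsilon)]
    out2 = arc2[_rdp_keep_mask(arc2, epsilon)]
    return np.concatenate([out1, out2[1:-1]])


def polygon_moments(poly) -> tuple[float, tuple[float, float]]:
    """Shoelace area and area centroid of a polygon.

    Degenerate polygons (area below 1e-9) report area 0 with the vertex
    mean as centroid.
    """
    pts = np.asarray(poly, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("polygon must be a non-empty Nx2 vertex list")
    x = pts[:, 0]
    y = pts[:, 1]
    xn = np.roll(x, -1)
    yn = np.roll(y, -1)
    cross = x * yn - xn * y
    signed = cross.sum() / 2.0
    if abs(signed) < _DEGENERATE_AREA:
        return 0.0, (float(x.mean()), float(y.mean()))
    cx = float(((x + xn) * cross).sum() / (6.0 * signed))
    cy = float(((y + yn) * cross).sum() / (6.0 * signed))
    # Self-intersecting chains (borders of 1-px-wide parts) can push the
    # signed centroid outside the hull; fall back to the vertex mean there.
    if not (x.min() <= cx <= x.max() and y.min() <= cy <= y.max()):
        cx, cy = float(x.mean()), float(y.mean())
    return abs(float(signed)), (cx, cy)


def make_blobs(hier: BorderHierarchy, epsilon: float = DEFAULT_EPSILON) -> list[Blob]:
    """One blob per outer border (hole borders produce none)."""
    blobs: list[Blob] = []
    for border in hier.outer_borders():
        pts = np.array([(c, r) for r, c in border.points], dtype=np.float64)
        poly = simplify_polygon(pts, epsilon, closed=True)
        area, centroid = polygon_moments(poly)
        x0 = float(poly[:, 0].min())
        y0 = float(poly[:, 1].min())
        bbox = (x0, y0, float(poly[:, 0].max()) - x0, float(poly[:, 1].max()) - y0)
        blobs.append(
            Blob(tuple(map(tuple, poly.tolist())), centroid, area, bbox)
        )
    return blobs


def filter_blobs(
    blobs: list[Blob],
    min_area: float = DEFAULT_MIN_AREA,
    max_area: float = DEFAULT_MAX_AREA,
    roi: ROI | None = None,
) -> list[Blob]:
    """Keep blobs with min_area <= area <= max_area and centroid inside roi.

    Pure, order-preserving filter; ``roi=None`` disables the spatial test.
    """
    if min_area < 0 or min_area > max_area:
        raise ValueError(f"need 0 <= min_area <= max_area, got {min_area}..{max_area}")
    out = []
    for b in blobs:
        if not (min_area <= b.area <= max_area):
            continue
        if roi is not None and not roi.contains(*b.centroid):
            continue
        out.append(b)
    return out
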