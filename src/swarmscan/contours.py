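"""Topological border following on binary images.

Implements the classical raster-scan border-following scheme: every
8- (or 4-) connected component of 1-pixels yields exactly one *outer*
border, every enclosed 0-component yields one *hole* border, and each
border records the id of the border directly surrounding it.  Id 1 is
reserved for the implicit picture frame (all pixels beyond the image are
0-pixels); discovered borders are numbered 2, 3, ... in raster order.

The input image is never modified; marking happens on an internal copy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Connectivity",
    "BorderType",
    "Border",
    "BorderHierarchy",
    "FRAME_ID",
    "follow_borders",
    "count_components",
]

FRAME_ID = 1

# Clockwise neighbor orders in image coordinates (row grows downward):
# starting at "east" and turning through "south".
_NBRS8 = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))
_NBRS4 = ((0, 1), (1, 0), (0, -1), (-1, 0))


class Connectivity(Enum):
    """Foreground/background connectivity dual.

    The two are tied together (8-connected foreground forces 4-connected
    background and vice versa) to avoid topological paradoxes.
    """

    FG8_BG4 = "fg8_bg4"
    FG4_BG8 = "fg4_bg8"


class BorderType(Enum):
    OUTER = "outer"
    HOLE = "hole"


@dataclass
class Border:
    """One followed border: ordered pixel chain with type and parent link.

    ``points`` are ``(row, col)`` pixel coordinates in following order,
    starting at the raster-scan hit pixel.  On 1-pixel-wide parts of a
    component the following pass visits a pixel once per side, so points
    may legitimately repeat (consecutive points never do, except for a
    single-point border).
    """

    id: int
    points: list[tuple[int, int]]
    border_type: BorderType
    parent: int


@dataclass
class BorderHierarchy:
    borders: list[Border] = field(default_factory=list)
    connectivity: Connectivity = Connectivity.FG8_BG4

    def outer_borders(self) -> list[Border]:
        return [b for b in self.borders if b.border_type is BorderType.OUTER]

    def hole_borders(self) -> list[Border]:
        return [b for b in self.borders if b.border_type is BorderType.HOLE]

    def to_json(self) -> str:
        """Debug dump: id, type, parent and point count per border."""
        return json.dumps(
            [
                {
                    "id": b.id,
                    "type": b.border_type.value,
                    "parent": b.parent,
                    "n_points": len(b.points),
                }
                for b in self.borders
            ]
        )


def _validate_binary(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"binary image must be 2-D, got shape {arr.shape}")
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("binary image may contain only 0 and 1")
    return arr


def follow_borders(
    img: np.ndarray, connectivity: Connectivity = Connectivity.FG8_BG4
) -> BorderHierarchy:
    """Extract all borders of ``img`` with their outer/hole type and parents.

    The scan proceeds row-major over the whole array; a border is started
    whenever an unvisited 1-pixel has a 0-pixel immediately to its left
    (outer border) or a pixel of a traced component has a 0-pixel
    immediately to its right that is not yet accounted for (hole border).
    """
    arr = _validate_binary(img)
    if arr.size == 0:
        return BorderHierarchy([], connectivity)
    height, width = arr.shape

    # Work on an int copy padded by one ring of 0-pixels standing in for
    # the conceptual picture frame; the input stays untouched.
    f = np.zeros((height + 2, width + 2), dtype=np.int64)
    f[1:-1, 1:-1] = arr

    nbrs = _NBRS8 if connectivity is Connectivity.FG8_BG4 else _NBRS4
    nsteps = len(nbrs)
    dir_of = {d: k for k, d in enumerate(nbrs)}

    # Marks are only ever written to 1-pixels, so the nonzero support of f
    # is constant: scan just those columns per row.
    support = [np.flatnonzero(arr[r]) + 1 for r in range(height)]

    btype: dict[int, BorderType] = {FRAME_ID: BorderType.HOLE}
    parent: dict[int, int] = {FRAME_ID: 0}
    borders: list[Border] = []
    nbd = FRAME_ID

    for i in range(1, height + 1):
        lnbd = FRAME_ID
        for j in support[i - 1]:
            fij = f[i, j]
            if fij == 1 and f[i, j - 1] == 0:
                nbd += 1
                new_type = BorderType.OUTER
                i2, j2 = i, j - 1
            elif fij >= 1 and f[i, j + 1] == 0:
                nbd += 1
                new_type = BorderType.HOLE
                i2, j2 = i, j + 1
                if fij > 1:
                    lnbd = int(fij)
            else:
                if fij != 1:
                    lnbd = int(abs(fij))
                continue

            # Parent from the border last met on this row (lnbd):
            # same type -> share its parent; opposite type -> it is the parent.
            if new_type is btype[lnbd]:
                par = parent[lnbd]
            else:
                par = lnbd
            btype[nbd] = new_type
            parent[nbd] = par

            pts = _trace(f, i, j, i2, j2, nbd, nbrs, nsteps, dir_of)
            borders.append(Border(nbd, pts, new_type, par))

            if f[i, j] != 1:
                lnbd = int(abs(f[i, j]))

    return BorderHierarchy(borders, connectivity)


def _trace(f, i, j, i2, j2, nbd, nbrs, nsteps, dir_of):
    """Follow one border starting at (i, j); marks pixels in ``f`` in place.

    Returns the list of (row, col) points in original (unpadded) coordinates.
    """
    # Search clockwise around (i, j) starting from (i2, j2) for a nonzero pixel.
    d0 = dir_of[(i2 - i, j2 - j)]
    found = None
    for step in range(nsteps):
        d = nbrs[(d0 + step) % nsteps]
        p, q = i + d[0], j + d[1]
        if f[p, q] != 0:
            found = (p, q)
            break
    if found is None:  # isolated pixel: degenerate single-point border
        f[i, j] = -nbd
        return [(i - 1, j - 1)]

    i1, j1 = found
    i2, j2 = i1, j1
    i3, j3 = i, j
    pts: list[tuple[int, int]] = []
    while True:
        # Counterclockwise search around (i3, j3), starting one past (i2, j2).
        d0 = dir_of[(i2 - i3, j2 - j3)]
        right_was_zero = False
        for step in range(1, nsteps + 1):
            d = nbrs[(d0 - step) % nsteps]
            p, q = i3 + d[0], j3 + d[1]
            if f[p, q] != 0:
                i4, j4 = p, q
                break
            if p == i3 and q == j3 + 1:
                right_was_zero = True

        pts.append((i3 - 1, j3 - 1))
        if right_was_zero:
            f[i3, j3] = -nbd
        elif f[i3, j3] == 1:
            f[i3, j3] = nbd

        if (i4, j4) == (i, j) and (i3, j3) == (i1, j1):
            return pts
        i2, j2 = i3, j3
        i3, j3 = i4, j4


def count_components(
    img: np.ndarray, connectivity: Connectivity = Connectivity.FG8_BG4
) -> int:
    """Number of connected 1-components (= number of outer borders)."""
    return len(follow_borders(img, connectivity).outer_borders())
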