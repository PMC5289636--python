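"""Frame preparation: grayscale conversion, thresholding, ROI cropping.

All images are numpy arrays in image convention: index ``(i, j)`` is
(row from top, column from left), 0-based.  Grayscale frames are 8-bit
(``uint8``); binary images hold only 0/1 values and are the input to
:mod:`swarmscan.contours`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "ThresholdMode",
    "ROI",
    "to_grayscale",
    "apply_threshold",
    "binarize",
    "crop_roi",
]

#: ITU-R BT.601 luma weights (R, G, B).
_LUMA = np.array([0.299, 0.587, 0.114])


class ThresholdMode(IntEnum):
    """The five threshold types selectable in the detection front-end."""

    BINARY = 0
    BINARY_INVERTED = 1
    TRUNCATE = 2
    TO_ZERO = 3
    TO_ZERO_INVERTED = 4


@dataclass(frozen=True)
class ROI:
    """Half-open rectangular region ``[x0, x0+w) x [y0, y0+h)`` in pixel units.

    ``x`` is the column coordinate, ``y`` the row coordinate.
    """

    x0: int
    y0: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"ROI must have w, h >= 1, got {self.w}x{self.h}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.x0}, {self.y0})")

    def validate_for(self, shape: tuple[int, int]) -> None:
        """Raise ``ValueError`` unless the ROI lies fully inside ``shape`` (H, W)."""
        height, width = shape[0], shape[1]
        if self.x0 + self.w > width or self.y0 + self.h > height:
            raise ValueError(
                f"ROI {self} exceeds frame bounds {height}x{width}"
            )

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership test for a point (x=col, y=row)."""
        return (self.x0 <= x < self.x0 + self.w) and (self.y0 <= y < self.y0 + self.h)

    @classmethod
    def full_frame(cls, shape: tuple[int, int]) -> "ROI":
        return cls(0, 0, int(shape[1]), int(shape[0]))


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an H x W x 3 color raster to an 8-bit grayscale frame.

    Uses BT.601 luma: ``round(0.299 R + 0.587 G + 0.114 B)``, clipped to
    [0, 255].  Raises ``ValueError`` for non-3-channel input.
    """
    arr = np.asarray(frame)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 color frame, got shape {arr.shape}")
    luma = np.floor(arr.astype(np.float64) @ _LUMA + 0.5)
    return np.clip(luma, 0, 255).astype(np.uint8)


def apply_threshold(img: np.ndarray, level: float, mode: ThresholdMode) -> np.ndarray:
    """Apply one of the five threshold modes at ``level`` (strict ``v > level``).

    binary:           255 where v > T else 0
    binary_inverted:  0 where v > T else 255
    truncate:         min(v, T)
    to_zero:          v where v > T else 0
    to_zero_inverted: 0 where v > T else v
    """
    if not 0 <= level <= 255:
        raise ValueError(f"threshold level must be in [0, 255], got {level}")
    mode = ThresholdMode(mode)
    v = np.asarray(img)
    above = v > level
    if mode is ThresholdMode.BINARY:
        out = np.where(above, 255, 0)
    elif mode is ThresholdMode.BINARY_INVERTED:
        out = np.where(above, 0, 255)
    elif mode is ThresholdMode.TRUNCATE:
        out = np.minimum(v, level)
    elif mode is ThresholdMode.TO_ZERO:
        out = np.where(above, v, 0)
    else:  # TO_ZERO_INVERTED
        out = np.where(above, 0, v)
    return out.astype(np.uint8)


def binarize(img: np.ndarray) -> np.ndarray:
    """Map a grayscale frame to a 0/1 binary image (any nonzero pixel -> 1)."""
    return (np.asarray(img) > 0).astype(np.uint8)


def crop_roi(img: np.ndarray, roi: ROI) -> np.ndarray:
    """Extract the ROI sub-image (exact pixel copy, no interpolation)."""
    arr = np.asarray(img)
    roi.validate_for(arr.shape)
    return arr[roi.y0 : roi.y0 + roi.h, roi.x0 : roi.x0 + roi.w].copy()
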