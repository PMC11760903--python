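"""Axis-aligned bounding boxes in YOLO center format.

A box is ``(cx, cy, w, h)``: center coordinates plus positive width and
height, all in the same length unit (pixels, or normalized image fractions
as in YOLO label files).  The module provides the scalar :class:`Box` type,
corner-format converters, and the enclosure geometry shared by the CIoU and
SIoU regression losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box",
    "EnclosureGeometry",
    "InvalidBoxError",
    "as_box_array",
    "validate_boxes",
    "center_to_corners",
    "corners_to_center",
    "enclosure_geometry",
]


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive width or height."""


@dataclass(frozen=True)
class Box:
    """An axis-aligned rectangle in center format.

    Parameters
    ----------
    cx, cy : float
        Center coordinates.
    w, h : float
        Width and height; must be strictly positive.  Degenerate boxes are
        rejected rather than clamped, so annotation bugs surface early.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"box must have positive extent, got w={self.w}, h={self.h}")

    def to_corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) corner representation."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "Box":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def area(self) -> float:
        return self.w * self.h

    def as_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=np.float64)


def as_box_array(boxes) -> np.ndarray:
    """Coerce a Box, a sequence of Boxes, or array-like to shape (..., 4)."""
    if isinstance(boxes, Box):
        return boxes.as_array()
    if isinstance(boxes, (list, tuple)) and len(boxes) > 0 and isinstance(boxes[0], Box):
        return np.stack([b.as_array() for b in boxes])
    arr = np.asarray(boxes, dtype=np.float64)
    if arr.ndim >= 1 and arr.shape[-1] != 4:
        raise ValueError(f"expected trailing dimension 4 (cx, cy, w, h), got shape {arr.shape}")
    return arr


def validate_boxes(arr: np.ndarray) -> None:
    if arr.size and not (np.all(arr[..., 2] > 0) and np.all(arr[..., 3] > 0)):
        raise InvalidBoxError("all boxes must have positive width and height")


def center_to_corners(boxes) -> np.ndarray:
    """(cx, cy, w, h) -> (x1, y1, x2, y2), vectorized over leading axes."""
    b = as_box_array(boxes)
    out = np.empty_like(b)
    out[..., 0] = b[..., 0] - b[..., 2] / 2
    out[..., 1] = b[..., 1] - b[..., 3] / 2
    out[..., 2] = b[..., 0] + b[..., 2] / 2
    out[..., 3] = b[..., 1] + b[..., 3] / 2
    return out


def corners_to_center(corners) -> np.ndarray:
    """(x1, y1, x2, y2) -> (cx, cy, w, h), vectorized over leading axes."""
    c = np.asarray(corners, dtype=np.float64)
    out = np.empty_like(c)
    out[..., 0] = (c[..., 0] + c[..., 2]) / 2
    out[..., 1] = (c[..., 1] + c[..., 3]) / 2
    out[..., 2] = c[..., 2] - c[..., 0]
    out[..., 3] = c[..., 3] - c[..., 1]
    return out


@dataclass(frozen=True)
class EnclosureGeometry:
    """Geometry of two boxes and their smallest enclosing rectangle.

    ``enclose_w``/``enclose_h`` are the enclosure's width and height,
    ``diag`` its diagonal; ``center_dx``/``center_dy`` are the absolute
    center offsets and ``center_dist`` the Euclidean center distance.  The
    height offset between centers and the enclosure height are distinct
    quantities and are kept as separate fields.
    """

    enclose_w: float
    enclose_h: float
    diag: float
    center_dx: float
    center_dy: float
    center_dist: float


def enclosure_geometry(pred, gt) -> EnclosureGeometry:
    """Enclosure geometry of a scalar box pair."""
    p = Box(*as_box_array(pred)) if not isinstance(pred, Box) else pred
    g = Box(*as_box_array(gt)) if not isinstance(gt, Box) else gt
    px1, py1, px2, py2 = p.to_corners()
    gx1, gy1, gx2, gy2 = g.to_corners()
    ew = max(px2, gx2) - min(px1, gx1)
    eh = max(py2, gy2) - min(py1, gy1)
    dx = abs(g.cx - p.cx)
    dy = abs(g.cy - p.cy)
    return EnclosureGeometry(
        enclose_w=ew,
        enclose_h=eh,
        diag=float(np.hypot(ew, eh)),
        center_dx=dx,
        center_dy=dy,
        center_dist=float(np.hypot(dx, dy)),
    )
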