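"""Axis-aligned bounding boxes in center/width/height form.

The (xc, yc, w, h) parameterization is the one the regression losses are
defined in; corners are derived as l = xc - w/2, r = xc + w/2 and
analogously for top/bottom (y grows downward, image convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoxCWH",
    "Detection",
    "GroundTruth",
    "InvalidBoxError",
    "as_box_array",
    "cwh_to_xyxy",
    "xyxy_to_cwh",
    "rasterized_iou_oracle",
]


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive or non-finite width/height."""


@dataclass(frozen=True)
class BoxCWH:
    """A box as (center-x, center-y, width, height) in pixels."""

    xc: float
    yc: float
    w: float
    h: float

    def __post_init__(self):
        vals = (self.xc, self.yc, self.w, self.h)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidBoxError(f"non-finite box {vals}")
        if self.w <= 0 or self.h <= 0:
            raise InvalidBoxError(f"degenerate box w={self.w}, h={self.h}")

    def to_xyxy(self) -> tuple[float, float, float, float]:
        return (self.xc - self.w / 2, self.yc - self.h / 2,
                self.xc + self.w / 2, self.yc + self.h / 2)

    @classmethod
    def from_xyxy(cls, x1: float, y1: float, x2: float, y2: float) -> "BoxCWH":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def as_array(self) -> np.ndarray:
        return np.array([self.xc, self.yc, self.w, self.h], dtype=float)

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class GroundTruth:
    """A class-labeled box."""

    box: BoxCWH
    label: int


@dataclass(frozen=True)
class Detection:
    """A scored, class-labeled box."""

    box: BoxCWH
    score: float
    label: int

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0,1], got {self.score}")


def as_box_array(box, validate: bool = True) -> np.ndarray:
    """Coerce a BoxCWH / 4-sequence / (...,4) array to a float array."""
    if isinstance(box, BoxCWH):
        return box.as_array()
    arr = np.asarray(box, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError(f"expected last dimension 4, got shape {arr.shape}")
    if validate:
        if not np.all(np.isfinite(arr)):
            raise InvalidBoxError("non-finite box coordinates")
        if np.any(arr[..., 2] <= 0) or np.any(arr[..., 3] <= 0):
            raise InvalidBoxError("degenerate box: width and height must be positive")
    return arr


def cwh_to_xyxy(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    half = boxes[..., 2:] / 2
    return np.concatenate([boxes[..., :2] - half, boxes[..., :2] + half], axis=-1)


def xyxy_to_cwh(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    wh = boxes[..., 2:] - boxes[..., :2]
    return np.concatenate([(boxes[..., :2] + boxes[..., 2:]) / 2, wh], axis=-1)


def rasterized_iou_oracle(a, b, grid: int = 1000) -> float:
    """Brute-force IoU by counting lattice cells on a grid x grid raster.

    The raster covers the joint extent of both boxes; each cell is
    classified by its center point.  Agreement with the analytic IoU is
    O(1/grid).  This is a test oracle, not a production path.
    """
    if grid < 100:
        raise ValueError("grid must be >= 100")
    a = as_box_array(a)
    b = as_box_array(b)
    ax1, ay1, ax2, ay2 = cwh_to_xyxy(a)
    bx1, by1, bx2, by2 = cwh_to_xyxy(b)
    x_lo, x_hi = min(ax1, bx1), max(ax2, bx2)
    y_lo, y_hi = min(ay1, by1), max(ay2, by2)
    xs = x_lo + (np.arange(grid) + 0.5) * (x_hi - x_lo) / grid
    ys = y_lo + (np.arange(grid) + 0.5) * (y_hi - y_lo) / grid
    in_a = ((xs >= ax1) & (xs <= ax2))[None, :] & ((ys >= ay1) & (ys <= ay2))[:, None]
    in_b = ((xs >= bx1) & (xs <= bx2))[None, :] & ((ys >= by1) & (ys <= by2))[:, None]
    inter = int(np.count_nonzero(in_a & in_b))
    union = int(np.count_nonzero(in_a | in_b))
    if union == 0:
        return 0.0
    return inter / union


def rasterized_iou_batch(a: np.ndarray, b: np.ndarray, grid: int = 1000) -> np.ndarray:
    """Vectorized equivalent of :func:`rasterized_iou_oracle`.

    For axis-aligned boxes the 2-D cell counts factor into per-axis
    counts (a cell center is inside a box iff its x is inside the x-range
    and its y inside the y-range), so the same lattice count is computed
    without materializing the grid.  Used to sweep large randomized
    suites; exact agreement with the 2-D raster is asserted in tests.
    """
    a = as_box_array(np.atleast_2d(a))
    b = as_box_array(np.atleast_2d(b))
    axy = cwh_to_xyxy(a)
    bxy = cwh_to_xyxy(b)

    def _axis_counts(a1, a2, b1, b2):
        lo = np.minimum(a1, b1)
        hi = np.maximum(a2, b2)
        step = (hi - lo) / grid
        # cell center index i has coordinate lo + (i + .5) step; inside [c1,c2]
        # iff i in [ceil((c1-lo)/step - .5), floor((c2-lo)/step - .5)]
        def count(c1, c2):
            i0 = np.ceil((c1 - lo) / step - 0.5 - 1e-12)
            i1 = np.floor((c2 - lo) / step - 0.5 + 1e-12)
            i0 = np.clip(i0, 0, grid - 1)
            i1 = np.clip(i1, -1, grid - 1)
            return np.maximum(i1 - i0 + 1, 0)

        na = count(a1, a2)
        nb = count(b1, b2)
        c1 = np.maximum(a1, b1)
        c2 = np.minimum(a2, b2)
        ni = np.where(c2 > c1, count(c1, c2), 0)
        return na, nb, ni

    nax, nbx, nix = _axis_counts(axy[:, 0], axy[:, 2], bxy[:, 0], bxy[:, 2])
    nay, nby, niy = _axis_counts(axy[:, 1], axy[:, 3], bxy[:, 1], bxy[:, 3])
    inter = nix * niy
    union = nax * nay + nbx * nby - inter
    return np.where(union > 0, inter / np.maximum(union, 1), 0.0)
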