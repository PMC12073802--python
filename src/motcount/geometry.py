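"""Axis-aligned bounding boxes and overlap measures.

Coordinates are continuous pixel units with the origin at the top-left of
the frame and y increasing downward.  Boxes are stored in
top-left/width/height form; conversions to corner and center/aspect/height
forms are exact.

The association cost used by the tracker's second matching stage is the
Complete-IoU (CIoU): plain IoU penalised by the normalised squared distance
between box centers and by an aspect-ratio consistency term,

    CIoU = IoU - rho^2(b, b_gt) / c^2 - alpha * v

where rho is the Euclidean distance between the two centers, c the diagonal
of the smallest axis-aligned box enclosing both, v = (4/pi^2) *
(arctan(w_gt/h_gt) - arctan(w/h))^2, and alpha = v / ((1 - IoU) + v).
CIoU lies in (-2, 1] and equals 1 exactly when the boxes coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BoundingBox", "CIoUTerms", "iou", "ciou", "ciou_cost", "iou_cost"]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left corner, width and height, in pixels."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite box field {name}={v!r}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate box: w={self.w}, h={self.h} (must be > 0)")

    # -- derived quantities -------------------------------------------------
    @property
    def cx(self) -> float:
        return self.x + self.w / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def aspect(self) -> float:
        """Width over height."""
        return self.w / self.h

    # -- lossless representation changes ------------------------------------
    def to_corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) with x2 > x1 and y2 > y1."""
        return (self.x, self.y, self.x + self.w, self.y + self.h)

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "BoundingBox":
        return cls(x1, y1, x2 - x1, y2 - y1)

    def to_xyah(self) -> tuple[float, float, float, float]:
        """(center_x, center_y, aspect=w/h, height) — the Kalman measurement."""
        return (self.cx, self.cy, self.w / self.h, self.h)

    @classmethod
    def from_xyah(cls, cx: float, cy: float, a: float, h: float) -> "BoundingBox":
        w = a * h
        return cls(cx - w / 2.0, cy - h / 2.0, w, h)

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x + dx, self.y + dy, self.w, self.h)


@dataclass(frozen=True)
class CIoUTerms:
    """All intermediate quantities of the CIoU score.

    Attributes
    ----------
    iou : plain intersection-over-union, in [0, 1].
    center_dist_sq : squared Euclidean distance between box centers (px^2).
    enclosing_diag_sq : squared diagonal of the smallest enclosing box (px^2).
    aspect_term_v : aspect-ratio inconsistency, (4/pi^2) * delta_arctan^2.
    balance_alpha : trade-off weight v / ((1 - iou) + v), in [0, 1].
    ciou : the combined score, in (-2, 1].
    """

    iou: float
    center_dist_sq: float
    enclosing_diag_sq: float
    aspect_term_v: float
    balance_alpha: float
    ciou: float


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1].

    Areas are computed from corner differences so that identical boxes give
    exactly 1 in floating point.
    """
    ax1, ay1, ax2, ay2 = a.to_corners()
    bx1, by1, bx2, by2 = b.to_corners()
    ix = min(ax2, bx2) - max(ax1, bx1)
    iy = min(ay2, by2) - max(ay1, by1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def ciou(pred: BoundingBox, gt: BoundingBox) -> CIoUTerms:
    """Complete-IoU between a predicted and a reference box.

    Returns every term so callers can inspect the geometry; the headline
    score is ``.ciou``.  Equals 1 iff the boxes are identical; the center
    penalty is bounded by 1 and alpha*v by 1, hence the (-2, 1] range.
    """
    overlap = iou(pred, gt)

    dx = pred.cx - gt.cx
    dy = pred.cy - gt.cy
    center_dist_sq = dx * dx + dy * dy

    ex1 = min(pred.x, gt.x)
    ey1 = min(pred.y, gt.y)
    ex2 = max(pred.x + pred.w, gt.x + gt.w)
    ey2 = max(pred.y + pred.h, gt.y + gt.h)
    enclosing_diag_sq = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2

    dt = math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)
    v = (4.0 / math.pi**2) * dt * dt
    # alpha -> 0 as v -> 0; guard the 0/0 at identical aspect + full overlap
    alpha = 0.0 if v == 0.0 else v / ((1.0 - overlap) + v)

    score = overlap - center_dist_sq / enclosing_diag_sq - alpha * v
    return CIoUTerms(
        iou=overlap,
        center_dist_sq=center_dist_sq,
        enclosing_diag_sq=enclosing_diag_sq,
        aspect_term_v=v,
        balance_alpha=alpha,
        ciou=score,
    )


def ciou_cost(pred: BoundingBox, gt: BoundingBox) -> float:
    """Non-negative association cost (1 - CIoU)/2, mapping (-2, 1] to [0, 1.5)."""
    return (1.0 - ciou(pred, gt).ciou) / 2.0


def iou_cost(a: BoundingBox, b: BoundingBox) -> float:
    """Classic second-stage cost 1 - IoU, in [0, 1]."""
    return 1.0 - iou(a, b)
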