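"""IoU-family bounding-box regression losses: IoU, CIoU, EIoU, Focal-EIoU.

All losses are pure geometric functions of two axis-aligned boxes and
expose every intermediate term (overlap, centre distance, enclosing-box
dimensions, aspect term, trade-off weight) in a :class:`LossBreakdown` so
each component can be inspected or tested in isolation.

Definitions, for prediction box b = (w, h) and ground truth b_gt =
(w_gt, h_gt) with minimum enclosing box (w_c, h_c) and squared centre
distance rho2:

    CIoU       = IoU - (rho2 / (w_c^2 + h_c^2) + alpha * v)
    v          = (4 / pi^2) * (arctan(w_gt / h_gt) - arctan(w / h)) ** p
    alpha      = v / ((1 - IoU) + v)          (:= 0 at IoU = 1, v = 0)
    L_CIoU     = 1 - CIoU

    L_EIoU     = (1 - IoU)
               + rho2 / (w_c^2 + h_c^2)
               + (w - w_gt)^2 / w_c^2 + (h - h_gt)^2 / h_c^2
    L_FocalEIoU = IoU^gamma * L_EIoU

The aspect exponent p defaults to 2, the standard CIoU form; p = 3 is
available (it makes v sign-indefinite and is offered for comparison
only).  The focal exponent gamma defaults to 0.5.
"""

from __future__ import annotations

import dataclasses
import math

EPS = 1e-9


@dataclasses.dataclass(frozen=True)
class BBox:
    """Axis-aligned box in continuous pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise ValueError(f"invalid box: min corner must not exceed max corner, got {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    @classmethod
    def from_xyxy(cls, coords) -> "BBox":
        x0, y0, x1, y1 = coords
        return cls(float(x0), float(y0), float(x1), float(y1))


@dataclasses.dataclass(frozen=True)
class LossBreakdown:
    """Every intermediate geometric term of the IoU-family losses."""

    iou: float
    center_dist_sq: float       # rho^2(b, b_gt)
    enclose_w: float            # w_c
    enclose_h: float            # h_c
    v: float = 0.0              # aspect-similarity term (CIoU)
    alpha: float = 0.0          # trade-off weight (CIoU)
    l_iou: float = 0.0          # 1 - IoU
    l_dis: float = 0.0          # centre-distance penalty
    l_asp: float = 0.0          # aspect / side-length penalty
    gamma: float = 0.0          # focal exponent (Focal-EIoU only)
    value: float = 0.0          # the final loss

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def iou(a: BBox, b: BBox) -> float:
    """Intersection area over union area; 0 when the union is empty."""
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def _enclosing(a: BBox, b: BBox) -> tuple[float, float]:
    return (
        max(a.x_max, b.x_max) - min(a.x_min, b.x_min),
        max(a.y_max, b.y_max) - min(a.y_min, b.y_min),
    )


def _center_dist_sq(a: BBox, b: BBox) -> float:
    (ax, ay), (bx, by) = a.center, b.center
    return (ax - bx) ** 2 + (ay - by) ** 2


def ciou(pred: BBox, gt: BBox, v_exponent: int = 2) -> LossBreakdown:
    """Complete-IoU loss with full breakdown; ``value`` is 1 - CIoU."""
    if v_exponent not in (2, 3):
        raise ValueError("v_exponent must be 2 or 3")
    if gt.area <= 0.0:
        raise ValueError("ground-truth box must have positive area")
    overlap = iou(pred, gt)
    rho2 = _center_dist_sq(pred, gt)
    wc, hc = _enclosing(pred, gt)
    diag2 = wc**2 + hc**2
    v = (4.0 / math.pi**2) * (
        math.atan2(gt.width, gt.height) - math.atan2(pred.width, pred.height)
    ) ** v_exponent
    denom = (1.0 - overlap) + v
    alpha = 0.0 if abs(denom) < EPS else v / denom
    l_dis = rho2 / max(diag2, EPS)
    ciou_value = overlap - (l_dis + alpha * v)
    return LossBreakdown(
        iou=overlap,
        center_dist_sq=rho2,
        enclose_w=wc,
        enclose_h=hc,
        v=v,
        alpha=alpha,
        l_iou=1.0 - overlap,
        l_dis=l_dis,
        value=1.0 - ciou_value,
    )


def eiou_loss(pred: BBox, gt: BBox) -> LossBreakdown:
    """Efficient-IoU loss: L_IoU + L_dis + L_asp."""
    wc, hc = _enclosing(pred, gt)
    if wc <= 0.0 and hc <= 0.0:
        raise ValueError("degenerate enclosing box: both boxes are points at the same location")
    overlap = iou(pred, gt)
    rho2 = _center_dist_sq(pred, gt)
    l_iou = 1.0 - overlap
    l_dis = rho2 / max(wc**2 + hc**2, EPS)
    l_asp = (pred.width - gt.width) ** 2 / max(wc**2, EPS) + (
        pred.height - gt.height
    ) ** 2 / max(hc**2, EPS)
    return LossBreakdown(
        iou=overlap,
        center_dist_sq=rho2,
        enclose_w=wc,
        enclose_h=hc,
        l_iou=l_iou,
        l_dis=l_dis,
        l_asp=l_asp,
        value=l_iou + l_dis + l_asp,
    )


def focal_eiou_loss(pred: BBox, gt: BBox, gamma: float = 0.5) -> LossBreakdown:
    """Focal-EIoU loss: IoU^gamma * L_EIoU (0 when the boxes are disjoint)."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    base = eiou_loss(pred, gt)
    weight = base.iou**gamma if base.iou > 0.0 else 0.0
    return dataclasses.replace(base, gamma=gamma, value=weight * base.value)
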