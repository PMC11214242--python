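"""Independent oracles used by the test suite.

Everything here is written straight from the definitions, deliberately not
sharing code with the package: exact rational-arithmetic IoU, Monte-Carlo
membership IoU, direct-transcription CIoU / EIoU / Focal-EIoU, brute-force
one-to-one detection matching, and a dense-sampling symmetric Hausdorff
distance between curves.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy.spatial import cKDTree


def iou_exact(a, b) -> Fraction:
    """IoU via exact interval arithmetic on Fractions."""
    ax0, ay0, ax1, ay1 = (Fraction(v).limit_denominator(10**12) for v in a)
    bx0, by0, bx1, by1 = (Fraction(v).limit_denominator(10**12) for v in b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    inter = max(iw, Fraction(0)) * max(ih, Fraction(0))
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    if union <= 0:
        return Fraction(0)
    return inter / union


def iou_monte_carlo(a, b, n_samples: int, rng: np.random.Generator) -> float:
    """IoU estimated by uniform point membership in the joint bounding box."""
    x0 = min(a[0], b[0])
    y0 = min(a[1], b[1])
    x1 = max(a[2], b[2])
    y1 = max(a[3], b[3])
    xs = rng.uniform(x0, x1, n_samples)
    ys = rng.uniform(y0, y1, n_samples)
    in_a = (xs >= a[0]) & (xs <= a[2]) & (ys >= a[1]) & (ys <= a[3])
    in_b = (xs >= b[0]) & (xs <= b[2]) & (ys >= b[1]) & (ys <= b[3])
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return np.count_nonzero(in_a & in_b) / union


def _iou_float(a, b) -> float:
    iw = max(min(a[2], b[2]) - max(a[0], b[0]), 0.0)
    ih = max(min(a[3], b[3]) - max(a[1], b[1]), 0.0)
    inter = iw * ih
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / union if union > 0 else 0.0


def ciou_loss_oracle(pred, gt, v_exponent: int = 2) -> float:
    """1 - CIoU transcribed directly from the definition."""
    overlap = _iou_float(pred, gt)
    pcx, pcy = (pred[0] + pred[2]) / 2, (pred[1] + pred[3]) / 2
    gcx, gcy = (gt[0] + gt[2]) / 2, (gt[1] + gt[3]) / 2
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    wc = max(pred[2], gt[2]) - min(pred[0], gt[0])
    hc = max(pred[3], gt[3]) - min(pred[1], gt[1])
    w, h = pred[2] - pred[0], pred[3] - pred[1]
    wgt, hgt = gt[2] - gt[0], gt[3] - gt[1]
    v = (4 / math.pi**2) * (math.atan2(wgt, hgt) - math.atan2(w, h)) ** v_exponent
    denom = (1 - overlap) + v
    alpha = v / denom if abs(denom) > 1e-9 else 0.0
    return 1 - (overlap - (rho2 / max(wc**2 + hc**2, 1e-9) + alpha * v))


def eiou_loss_oracle(pred, gt) -> float:
    overlap = _iou_float(pred, gt)
    pcx, pcy = (pred[0] + pred[2]) / 2, (pred[1] + pred[3]) / 2
    gcx, gcy = (gt[0] + gt[2]) / 2, (gt[1] + gt[3]) / 2
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    wc = max(pred[2], gt[2]) - min(pred[0], gt[0])
    hc = max(pred[3], gt[3]) - min(pred[1], gt[1])
    w, h = pred[2] - pred[0], pred[3] - pred[1]
    wgt, hgt = gt[2] - gt[0], gt[3] - gt[1]
    return (
        (1 - overlap)
        + rho2 / max(wc**2 + hc**2, 1e-9)
        + (w - wgt) ** 2 / max(wc**2, 1e-9)
        + (h - hgt) ** 2 / max(hc**2, 1e-9)
    )


def focal_eiou_loss_oracle(pred, gt, gamma: float = 0.5) -> float:
    overlap = _iou_float(pred, gt)
    weight = overlap**gamma if overlap > 0 else 0.0
    return weight * eiou_loss_oracle(pred, gt)


def best_matching_bruteforce(pred_boxes, gt_boxes, threshold: float = 0.5):
    """Optimal one-to-one matching by exhaustion.

    Maximizes the number of matched pairs with IoU > threshold, breaking
    ties by total matched IoU.  Returns (tp, total_iou).
    """
    n_p, n_g = len(pred_boxes), len(gt_boxes)
    best = (0, 0.0)
    k = min(n_p, n_g)
    for size in range(k, -1, -1):
        if size < best[0]:
            break
        for p_idx in itertools.combinations(range(n_p), size):
            for g_perm in itertools.permutations(range(n_g), size):
                ious = [_iou_float(pred_boxes[i], gt_boxes[j]) for i, j in zip(p_idx, g_perm)]
                if all(v > threshold for v in ious):
                    cand = (size, sum(ious))
                    if cand > best:
                        best = cand
    return best


def ellipse_boundary(center, semi_axes, n: int = 2000) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + semi_axes[0] * np.cos(t), center[1] + semi_axes[1] * np.sin(t)]
    )


def densify_polygon(vertices, step: float = 0.5) -> np.ndarray:
    """Sample a closed polygon's edges at roughly ``step``-pixel spacing."""
    pts = []
    verts = list(vertices)
    for (x0, y0), (x1, y1) in zip(verts, verts[1:] + verts[:1]):
        length = math.hypot(x1 - x0, y1 - y0)
        n = max(2, int(math.ceil(length / step)))
        for t in np.linspace(0, 1, n, endpoint=False):
            pts.append((x0 + t * (x1 - x0), y0 + t * (y1 - y0)))
    return np.asarray(pts)


def symmetric_hausdorff(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """max over both directions of the max nearest-neighbour distance."""
    tree_a, tree_b = cKDTree(curve_a), cKDTree(curve_b)
    d_ab = tree_b.query(curve_a)[0].max()
    d_ba = tree_a.query(curve_b)[0].max()
    return float(max(d_ab, d_ba))


def random_boxes(rng: np.random.Generator, n: int, lo: float = 0.0, hi: float = 100.0,
                 min_side: float = 0.5):
    """n pairs of random valid boxes with sides >= min_side."""
    pairs = []
    for _ in range(n):
        boxes = []
        for _ in range(2):
            x0, y0 = rng.uniform(lo, hi - min_side, 2)
            w, h = rng.uniform(min_side, (hi - lo) / 2, 2)
            boxes.append((x0, y0, min(x0 + w, hi), min(y0 + h, hi)))
        pairs.append(tuple(boxes))
    return pairs
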