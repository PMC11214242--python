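"""Detection evaluation and vertical cup-to-disc ratio (vCDR) screening.

Matching follows the standard IoU-thresholded protocol: within each class,
prediction/ground-truth pairs whose axis-aligned box IoU exceeds the
threshold (default 0.5, strict inequality) are matched greedily by
descending IoU, one-to-one.  Matched predictions are true positives,
unmatched predictions false positives, unmatched ground truths false
negatives; true negatives are fixed at 0 (ill-defined in detection) and do
not enter any metric.

The clinical quantity is the vCDR — the vertical diameter of the optic cup
divided by the vertical diameter of the optic disc, both measured as the
vertical extent (max y - min y) of the corresponding polygon.  A vCDR
above 0.5 flags elevated glaucoma risk.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Polygon

from .adapter import CUP_CLASS, DISC_CLASS, PolygonAnnotation
from .box_losses import BBox, iou
from .phantoms import GrayscaleMask

GLAUCOMA_VCDR_THRESHOLD = 0.5


@dataclasses.dataclass(frozen=True)
class Detection:
    """One detected (or ground-truth) instance: polygon, its tight box hull,
    and a confidence score."""

    class_id: int
    polygon: PolygonAnnotation
    confidence: float = 1.0

    @property
    def bbox(self) -> BBox:
        return BBox.from_xyxy(self.polygon.to_pixels().bbox())

    @classmethod
    def from_annotation(cls, ann: PolygonAnnotation, confidence: float = 1.0) -> "Detection":
        return cls(class_id=ann.class_id, polygon=ann, confidence=confidence)


@dataclasses.dataclass(frozen=True)
class MatchResult:
    tp: int
    fp: int
    fn: int
    tn: int = 0
    matched_pairs: tuple[tuple[int, int, float], ...] = ()

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            tp=self.tp + other.tp, fp=self.fp + other.fp,
            fn=self.fn + other.fn, tn=self.tn + other.tn,
        )


@dataclasses.dataclass(frozen=True)
class MetricSet:
    precision: float
    recall: float
    f1: float


@dataclasses.dataclass(frozen=True)
class VcdrResult:
    """Clinical output: vertical diameters (px), their ratio, and the risk flag."""

    vdd: float
    vdc: float
    vcdr: float
    glaucoma_risk: bool


def _pair_iou(a: Detection, b: Detection, mode: str) -> float:
    if mode == "bbox":
        return iou(a.bbox, b.bbox)
    pa = Polygon(a.polygon.to_pixels().vertices).buffer(0)
    pb = Polygon(b.polygon.to_pixels().vertices).buffer(0)
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union > 0 else 0.0


def match_detections(
    predictions: Sequence[Detection],
    ground_truth: Sequence[Detection],
    iou_threshold: float = 0.5,
    min_confidence: float = 0.0,
    iou_mode: Literal["bbox", "polygon"] = "bbox",
) -> MatchResult:
    """Greedy one-to-one matching per class at an IoU threshold.

    Candidate pairs with IoU strictly greater than the threshold are sorted
    by descending IoU (ties: lower prediction index, then lower ground-truth
    index) and matched greedily; each prediction and each ground truth is
    used at most once.  ``min_confidence`` drops low-scoring predictions
    before matching (default keeps everything).
    """
    preds = [(i, p) for i, p in enumerate(predictions) if p.confidence >= min_confidence]
    classes = {p.class_id for _, p in preds} | {g.class_id for g in ground_truth}
    matched: list[tuple[int, int, float]] = []
    tp = fp = fn = 0
    for cls in sorted(classes):
        cls_preds = [(i, p) for i, p in preds if p.class_id == cls]
        cls_gts = [(j, g) for j, g in enumerate(ground_truth) if g.class_id == cls]
        candidates = []
        for rank_p, (i, p) in enumerate(cls_preds):
            for rank_g, (j, g) in enumerate(cls_gts):
                overlap = _pair_iou(p, g, iou_mode)
                if overlap > iou_threshold:
                    candidates.append((-overlap, rank_p, rank_g, i, j))
        candidates.sort()
        used_p: set[int] = set()
        used_g: set[int] = set()
        for neg_iou, _, _, i, j in candidates:
            if i in used_p or j in used_g:
                continue
            used_p.add(i)
            used_g.add(j)
            matched.append((i, j, -neg_iou))
        tp += len(used_p)
        fp += len(cls_preds) - len(used_p)
        fn += len(cls_gts) - len(used_g)
    return MatchResult(tp=tp, fp=fp, fn=fn, tn=0, matched_pairs=tuple(sorted(matched)))


def compute_metrics(match: MatchResult) -> MetricSet:
    """Precision, recall and F1 from TP/FP/FN counts; any 0/0 yields 0."""
    tp, fp, fn = match.tp, match.fp, match.fn
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricSet(precision=precision, recall=recall, f1=f1)


def vertical_diameter(region: PolygonAnnotation | GrayscaleMask, gray_value: int | None = None) -> float:
    """Vertical extent of a region in pixels.

    For a polygon: max vertex y minus min vertex y.  For a mask plus a gray
    value: max minus min of the matching row indices — the same convention
    as polygons produced by the adapter, which retains the first and last
    occupied rows, so the two forms agree on adapter output.
    """
    if isinstance(region, PolygonAnnotation):
        if not region.vertices:
            raise ValueError("empty polygon has no vertical diameter")
        ys = [y for _, y in region.to_pixels().vertices]
        return max(ys) - min(ys)
    if gray_value is None:
        raise ValueError("mask form requires a gray value")
    rows = np.flatnonzero((region.pixels == gray_value).any(axis=1))
    if rows.size == 0:
        raise ValueError(f"mask contains no pixel with value {gray_value}")
    return float(rows[-1] - rows[0])


def compute_vcdr(disc: PolygonAnnotation, cup: PolygonAnnotation) -> VcdrResult:
    """vCDR = vertical diameter of the cup / vertical diameter of the disc."""
    if disc is None:
        raise ValueError("missing disc annotation")
    if cup is None:
        raise ValueError("missing cup annotation")
    vdd = vertical_diameter(disc)
    vdc = vertical_diameter(cup)
    if vdd <= 0:
        raise ValueError("disc vertical diameter is zero")
    ratio = vdc / vdd
    return VcdrResult(vdd=vdd, vdc=vdc, vcdr=ratio, glaucoma_risk=ratio > GLAUCOMA_VCDR_THRESHOLD)


def vcdr_from_annotations(annotations: Sequence[PolygonAnnotation]) -> VcdrResult:
    """Convenience: pick the disc and cup polygons out of an annotation list."""
    disc = next((a for a in annotations if a.class_id == DISC_CLASS), None)
    cup = next((a for a in annotations if a.class_id == CUP_CLASS), None)
    if disc is None or cup is None:
        missing = "disc" if disc is None else "cup"
        raise ValueError(f"missing {missing} annotation")
    return compute_vcdr(disc, cup)
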