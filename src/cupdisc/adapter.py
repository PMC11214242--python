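"""Mask-to-polygon annotation conversion and YOLO-segmentation label I/O.

Converts a REFUGE-convention grayscale label mask (cup = 0, disc = 128,
background = 255) into per-class polygon annotations through three steps:

1. row-extreme extraction — for every image row, the leftmost and rightmost
   pixel of the target gray value;
2. stride subsampling — keep every ``sampling_stride``-th occupied row
   (default every 15th), always retaining the bottom row so the vertical
   extent of the region is preserved exactly;
3. clockwise angular sort about the vertex centroid.

The resulting polygons are written to / read from the standard YOLO
segmentation label dialect: one instance per line,
``class_id x1 y1 x2 y2 ...`` with coordinates normalized to [0, 1].
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .phantoms import CUP_GRAY, DISC_GRAY, GrayscaleMask

logger = logging.getLogger(__name__)

DISC_CLASS = 0
CUP_CLASS = 1

Point = tuple[float, float]


@dataclasses.dataclass(frozen=True)
class AdapterConfig:
    disc_gray: int = DISC_GRAY
    cup_gray: int = CUP_GRAY
    sampling_stride: int = 15
    min_vertices: int = 3
    gray_tolerance: int = 0  # non-zero only for lossy-compressed masks

    def __post_init__(self) -> None:
        if self.sampling_stride < 1:
            raise ValueError("sampling_stride must be >= 1")
        if self.disc_gray == self.cup_gray:
            raise ValueError("disc_gray and cup_gray must differ")


@dataclasses.dataclass(frozen=True)
class BoundaryPointList:
    """Row-extreme boundary points of one class, ordered top to bottom.

    Invariant: at most two points per image row (the left and the right
    extreme; a single point when they coincide).
    """

    points: tuple[Point, ...]
    class_label: str

    def rows(self) -> list[int]:
        """Distinct occupied rows, ascending."""
        return sorted({int(p[1]) for p in self.points})


@dataclasses.dataclass(frozen=True)
class PolygonAnnotation:
    """A class-labelled polygon, vertices in clockwise screen order.

    Vertices are ``(x, y)`` pairs, either in pixel coordinates or
    normalized to [0, 1] by the image width/height (``normalized`` flag).
    """

    class_id: int
    vertices: tuple[Point, ...]
    normalized: bool
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        if self.class_id not in (DISC_CLASS, CUP_CLASS):
            raise ValueError(f"class_id must be 0 (disc) or 1 (cup), got {self.class_id}")
        if self.normalized:
            arr = np.asarray(self.vertices, dtype=float)
            if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
                raise ValueError("normalized vertices must lie in [0, 1]")

    def to_pixels(self) -> "PolygonAnnotation":
        if not self.normalized:
            return self
        w, h = self.image_size
        verts = tuple((x * w, y * h) for x, y in self.vertices)
        return dataclasses.replace(self, vertices=verts, normalized=False)

    def to_normalized(self) -> "PolygonAnnotation":
        if self.normalized:
            return self
        w, h = self.image_size
        verts = tuple((min(max(x / w, 0.0), 1.0), min(max(y / h, 0.0), 1.0)) for x, y in self.vertices)
        return dataclasses.replace(self, vertices=verts, normalized=True)

    def bbox(self) -> tuple[float, float, float, float]:
        """Tight axis-aligned hull (x_min, y_min, x_max, y_max)."""
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return (min(xs), min(ys), max(xs), max(ys))


def signed_area(points: Sequence[Point]) -> float:
    """Shoelace signed area; positive means clockwise on screen (y-down axes)."""
    n = len(points)
    s = 0.0
    for i in range(n):
        x0, y0 = points[i]
        x1, y1 = points[(i + 1) % n]
        s += x0 * y1 - x1 * y0
    return 0.5 * s


def is_clockwise(points: Sequence[Point]) -> bool:
    return signed_area(points) > 0


def extract_row_extremes(
    mask: GrayscaleMask, gray_value: int, config: AdapterConfig | None = None
) -> BoundaryPointList:
    """Per row, the leftmost and rightmost pixel equal to ``gray_value``.

    Rows are scanned top to bottom; a row contributes one point when the
    extremes coincide.  Returns an empty list when no pixel matches.
    """
    config = config or AdapterConfig()
    tol = config.gray_tolerance
    arr = mask.pixels.astype(np.int16)
    hit = np.abs(arr - int(gray_value)) <= tol if tol else arr == int(gray_value)
    label = {config.disc_gray: "disc", config.cup_gray: "cup"}.get(int(gray_value), str(gray_value))
    points: list[Point] = []
    rows = np.flatnonzero(hit.any(axis=1))
    for r in rows:
        cols = np.flatnonzero(hit[r])
        left, right = int(cols[0]), int(cols[-1])
        points.append((float(left), float(r)))
        if right != left:
            points.append((float(right), float(r)))
    return BoundaryPointList(points=tuple(points), class_label=label)


def subsample_boundary(points: BoundaryPointList, stride: int) -> BoundaryPointList:
    """Keep the extreme pair of every ``stride``-th occupied row.

    The stride counts occupied rows starting from the topmost one; the
    bottommost occupied row is always retained so the region's vertical
    extent survives subsampling exactly.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not points.points:
        return points
    rows = points.rows()
    keep = set(rows[::stride])
    keep.add(rows[-1])
    kept = tuple(p for p in points.points if int(p[1]) in keep)
    return dataclasses.replace(points, points=kept)


def sort_clockwise(points: Iterable[Point]) -> list[Point]:
    """Order points clockwise (on screen) about their centroid.

    The centroid C is the arithmetic mean of the points.  Each point P is
    keyed by the angle of the vector CP measured counterclockwise from +x
    in y-up axes — i.e. ``atan2(-(y - Cy), x - Cx)`` in image coordinates —
    and sorted by descending angle, which is clockwise as displayed.  Angle
    ties are broken by ascending distance from C.
    """
    pts = list(points)
    if len(set(pts)) < 3:
        raise ValueError("need at least 3 distinct points to form a polygon")
    cx = sum(p[0] for p in pts) / len(pts)
    cy = sum(p[1] for p in pts) / len(pts)

    def key(p: Point) -> tuple[float, float]:
        dx, dy = p[0] - cx, p[1] - cy
        return (-math.atan2(-dy, dx), math.hypot(dx, dy))

    return sorted(pts, key=key)


def mask_to_annotations(
    mask: GrayscaleMask, config: AdapterConfig | None = None
) -> list[PolygonAnnotation]:
    """Full adapter pipeline: extremes -> stride subsample -> clockwise sort.

    Runs once per class (disc then cup).  A class absent from the mask is
    omitted silently; a class present but yielding fewer than
    ``min_vertices`` vertices is omitted with a warning.  Output vertices
    are in pixel coordinates.
    """
    config = config or AdapterConfig()
    out: list[PolygonAnnotation] = []
    size = (mask.width, mask.height)
    for gray, class_id in ((config.disc_gray, DISC_CLASS), (config.cup_gray, CUP_CLASS)):
        extremes = extract_row_extremes(mask, gray, config)
        if not extremes.points:
            continue
        sampled = subsample_boundary(extremes, config.sampling_stride)
        if len(set(sampled.points)) < config.min_vertices:
            logger.warning(
                "class %s (gray %d) yielded %d vertices, fewer than min_vertices=%d; omitted",
                extremes.class_label, gray, len(sampled.points), config.min_vertices,
            )
            continue
        ordered = sort_clockwise(sampled.points)
        out.append(
            PolygonAnnotation(
                class_id=class_id, vertices=tuple(ordered), normalized=False, image_size=size
            )
        )
    return out


class LabelFormatError(ValueError):
    """A YOLO segmentation label file is malformed."""


def write_yolo_labels(
    annotations: Sequence[PolygonAnnotation],
    image_size: tuple[int, int],
    path: Path | str,
    confidences: Sequence[float] | None = None,
) -> Path:
    """Write annotations as YOLO segmentation labels.

    One line per instance: ``class_id x1 y1 x2 y2 ...`` with coordinates
    normalized to [0, 1] by the image width/height, 6 decimal places.
    ``confidences``, when given, appends one trailing score per line (the
    dialect used for prediction files).
    """
    path = Path(path)
    w, h = image_size
    lines = []
    for i, ann in enumerate(annotations):
        pix = ann.to_pixels()
        coords = []
        for x, y in pix.vertices:
            coords.append(f"{min(max(x / w, 0.0), 1.0):.6f}")
            coords.append(f"{min(max(y / h, 0.0), 1.0):.6f}")
        line = f"{ann.class_id} " + " ".join(coords)
        if confidences is not None:
            line += f" {confidences[i]:.6f}"
        lines.append(line)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_yolo_labels(
    path: Path | str,
    image_size: tuple[int, int],
    with_confidence: bool = False,
) -> list[PolygonAnnotation] | tuple[list[PolygonAnnotation], list[float]]:
    """Read a YOLO segmentation label file back into pixel-coordinate polygons.

    Inverse of :func:`write_yolo_labels` up to the 6-decimal quantization
    (round-trip error at most 0.5e-6 in normalized units).  Malformed lines
    raise :class:`LabelFormatError` naming the 1-based line number.
    """
    path = Path(path)
    w, h = image_size
    annotations: list[PolygonAnnotation] = []
    confidences: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split()
        try:
            class_id = int(fields[0])
        except ValueError:
            raise LabelFormatError(f"{path.name} line {lineno}: class id {fields[0]!r} not an integer")
        if class_id not in (DISC_CLASS, CUP_CLASS):
            raise LabelFormatError(f"{path.name} line {lineno}: class id {class_id} not in {{0, 1}}")
        values = fields[1:]
        conf = 1.0
        if with_confidence:
            if len(values) % 2 == 1:
                conf = float(values[-1])
                values = values[:-1]
            else:
                raise LabelFormatError(
                    f"{path.name} line {lineno}: expected trailing confidence field"
                )
        if len(values) % 2 == 1:
            raise LabelFormatError(f"{path.name} line {lineno}: odd coordinate count ({len(values)})")
        if len(values) < 6:
            raise LabelFormatError(f"{path.name} line {lineno}: fewer than 3 vertices")
        coords = [float(v) for v in values]
        if any(c < 0.0 or c > 1.0 for c in coords):
            raise LabelFormatError(f"{path.name} line {lineno}: coordinate outside [0, 1]")
        verts = tuple((coords[i] * w, coords[i + 1] * h) for i in range(0, len(coords), 2))
        annotations.append(
            PolygonAnnotation(class_id=class_id, vertices=verts, normalized=False, image_size=(w, h))
        )
        confidences.append(conf)
    if with_confidence:
        return annotations, confidences
    return annotations
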