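"""Fixed-fraction ROI cropping and detection-style augmentations.

The ROI crop keeps a fixed fractional window of the fundus image — rows
from 0.25 to 0.65 of the height and columns from 0 to 0.5 of the width by
default — which is where the optic nerve head sits in standard fundus
photographs.  The three augmentations (letterbox, mosaic, mixup) are the
usual detection-training transforms, each with the exact induced transform
on polygon vertex coordinates.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from PIL import Image
from shapely.geometry import Polygon, box as shapely_box
from skimage import color as skcolor

from .adapter import PolygonAnnotation, sort_clockwise


@dataclasses.dataclass(frozen=True)
class RoiConfig:
    height_min_frac: float = 0.25
    height_max_frac: float = 0.65
    width_min_frac: float = 0.0
    width_max_frac: float = 0.5

    def __post_init__(self) -> None:
        for lo, hi, axis in (
            (self.height_min_frac, self.height_max_frac, "height"),
            (self.width_min_frac, self.width_max_frac, "width"),
        ):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"{axis} fractions must satisfy 0 <= min < max <= 1")


@dataclasses.dataclass(frozen=True)
class RoiWindow:
    """Half-open pixel window [row_start, row_end) x [col_start, col_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.row_start < self.row_end and 0 <= self.col_start < self.col_end):
            raise ValueError("window must be non-empty with non-negative starts")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start


@dataclasses.dataclass(frozen=True)
class AugConfig:
    canvas_size: int = 640
    mosaic_center_jitter: tuple[float, float] = (0.25, 0.75)
    mixup_beta_alpha: float = 32.0
    letterbox_pad_value: int = 0
    seed: int = 0
    flip_prob: float = 0.5
    scale_range: tuple[float, float] = (0.5, 1.5)
    hsv_gains: tuple[float, float, float] = (0.015, 0.7, 0.4)

    def __post_init__(self) -> None:
        if self.canvas_size < 2:
            raise ValueError("canvas_size must be >= 2")
        lo, hi = self.mosaic_center_jitter
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("mosaic_center_jitter must be a sub-range of (0, 1)")
        if self.mixup_beta_alpha <= 0:
            raise ValueError("mixup_beta_alpha must be > 0")


def compute_roi_window(image_height: int, image_width: int, config: RoiConfig | None = None) -> RoiWindow:
    """Fractional bounds to a concrete pixel window.

    Starts are floored and ends are ceiled so no boundary pixel of the
    fractional region is ever lost.
    """
    if image_height < 1 or image_width < 1:
        raise ValueError("image dimensions must be >= 1")
    config = config or RoiConfig()
    return RoiWindow(
        row_start=math.floor(image_height * config.height_min_frac),
        row_end=math.ceil(image_height * config.height_max_frac),
        col_start=math.floor(image_width * config.width_min_frac),
        col_end=math.ceil(image_width * config.width_max_frac),
    )


def crop_roi(
    image: np.ndarray,
    annotations: Sequence[PolygonAnnotation],
    window: RoiWindow,
) -> tuple[np.ndarray, list[PolygonAnnotation]]:
    """Slice the image to the window and shift annotation vertices with it.

    Annotations lying entirely outside the window are dropped; vertices of
    partially-outside annotations are clipped to the window boundary.
    Annotations must be in pixel coordinates of the uncropped image.
    """
    h, w = image.shape[:2]
    if window.row_end > h or window.col_end > w:
        raise ValueError(f"window {window} exceeds image bounds {w}x{h}")
    cropped = image[window.row_start:window.row_end, window.col_start:window.col_end].copy()
    size = (window.width, window.height)
    out: list[PolygonAnnotation] = []
    for ann in annotations:
        pix = ann.to_pixels()
        x0, y0, x1, y1 = pix.bbox()
        if x1 < window.col_start or x0 >= window.col_end or y1 < window.row_start or y0 >= window.row_end:
            continue
        verts = tuple(
            (
                min(max(x - window.col_start, 0.0), float(window.width)),
                min(max(y - window.row_start, 0.0), float(window.height)),
            )
            for x, y in pix.vertices
        )
        out.append(dataclasses.replace(pix, vertices=verts, image_size=size))
    return cropped, out


@dataclasses.dataclass(frozen=True)
class LetterboxRecord:
    """Exact forward transform of a letterbox: v -> v * scale + pad."""

    scale: float
    pad_x: float
    pad_y: float
    original_size: tuple[int, int]  # (width, height)
    target_size: int

    def apply(self, xy: tuple[float, float]) -> tuple[float, float]:
        return (xy[0] * self.scale + self.pad_x, xy[1] * self.scale + self.pad_y)

    def invert(self, xy: tuple[float, float]) -> tuple[float, float]:
        return ((xy[0] - self.pad_x) / self.scale, (xy[1] - self.pad_y) / self.scale)


def letterbox(
    image: np.ndarray,
    annotations: Sequence[PolygonAnnotation],
    target_size: int,
    config: AugConfig | None = None,
) -> tuple[np.ndarray, list[PolygonAnnotation], LetterboxRecord]:
    """Aspect-preserving resize to ``target_size`` square with border padding.

    The image is scaled by ``target_size / max(h, w)``, then padded with
    ``letterbox_pad_value`` on the short side, split evenly with the odd
    pixel going to the bottom/right.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    config = config or AugConfig()
    h, w = image.shape[:2]
    scale = target_size / max(h, w)
    new_h, new_w = round(h * scale), round(w * scale)
    pil = Image.fromarray(image)
    resized = np.asarray(pil.resize((new_w, new_h), Image.BILINEAR))
    pad_top = (target_size - new_h) // 2
    pad_left = (target_size - new_w) // 2
    shape = (target_size, target_size) + image.shape[2:]
    canvas = np.full(shape, config.letterbox_pad_value, dtype=image.dtype)
    canvas[pad_top:pad_top + new_h, pad_left:pad_left + new_w] = resized
    record = LetterboxRecord(
        scale=scale, pad_x=float(pad_left), pad_y=float(pad_top),
        original_size=(w, h), target_size=target_size,
    )
    out = []
    for ann in annotations:
        pix = ann.to_pixels()
        verts = tuple(record.apply(v) for v in pix.vertices)
        out.append(dataclasses.replace(pix, vertices=verts, image_size=(target_size, target_size)))
    return canvas, out, record


def _hsv_jitter(image: np.ndarray, gains: tuple[float, float, float], rng: np.random.Generator) -> np.ndarray:
    dh = float(rng.uniform(-gains[0], gains[0]))
    ds = float(rng.uniform(-gains[1], gains[1]))
    dv = float(rng.uniform(-gains[2], gains[2]))
    if dh == ds == dv == 0.0:
        return image
    hsv = skcolor.rgb2hsv(image)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1.0 + ds), 0.0, 1.0)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1.0 + dv), 0.0, 1.0)
    return (skcolor.hsv2rgb(hsv) * 255.0).round().astype(np.uint8)


def _random_item_transform(
    image: np.ndarray,
    annotations: Sequence[PolygonAnnotation],
    config: AugConfig,
    rng: np.random.Generator,
    identity: bool,
) -> tuple[np.ndarray, list[PolygonAnnotation]]:
    """Per-item mosaic pre-transform: optional horizontal flip, uniform
    scale, HSV jitter.  Vertex coordinates follow exactly."""
    anns = [a.to_pixels() for a in annotations]
    if identity:
        return image, anns
    h, w = image.shape[:2]
    if rng.uniform() < config.flip_prob:
        image = image[:, ::-1].copy()
        anns = [
            dataclasses.replace(a, vertices=tuple((w - x, y) for x, y in a.vertices))
            for a in anns
        ]
    s = float(rng.uniform(*config.scale_range))
    if s != 1.0:
        new_h, new_w = max(1, round(h * s)), max(1, round(w * s))
        sx, sy = new_w / w, new_h / h
        image = np.asarray(Image.fromarray(image).resize((new_w, new_h), Image.BILINEAR))
        anns = [
            dataclasses.replace(
                a,
                vertices=tuple((x * sx, y * sy) for x, y in a.vertices),
                image_size=(new_w, new_h),
            )
            for a in anns
        ]
    if image.ndim == 3:
        image = _hsv_jitter(image, config.hsv_gains, rng)
    return image, anns


def _clip_polygon_to_rect(
    ann: PolygonAnnotation, rect: tuple[float, float, float, float]
) -> PolygonAnnotation | None:
    """Intersect a polygon with an axis-aligned rectangle; None if fewer
    than 3 vertices survive."""
    poly = Polygon(ann.vertices)
    if not poly.is_valid:
        poly = poly.buffer(0)
    clipped = poly.intersection(shapely_box(*rect))
    if clipped.is_empty or clipped.geom_type != "Polygon":
        return None
    verts = list(clipped.exterior.coords)[:-1]
    if len(set(verts)) < 3:
        return None
    return dataclasses.replace(ann, vertices=tuple(sort_clockwise(verts)))


def mosaic(
    items: Sequence[tuple[np.ndarray, Sequence[PolygonAnnotation]]],
    config: AugConfig | None = None,
    rng: np.random.Generator | None = None,
    center: tuple[float, float] | None = None,
    identity_transforms: bool = False,
) -> tuple[np.ndarray, list[PolygonAnnotation]]:
    """Stitch four images into one mosaic canvas.

    A mosaic centre is sampled uniformly inside ``canvas * jitter`` (or
    fixed via ``center``); each input is independently flipped / scaled /
    colour-jittered and placed in the upper-left, upper-right, lower-left
    and lower-right quadrants, cropped at the centre lines.  Vertices are
    transformed accordingly and clipped to their quadrant; polygons left
    with fewer than 3 vertices are dropped.
    """
    if len(items) != 4:
        raise ValueError(f"mosaic requires exactly 4 items, got {len(items)}")
    config = config or AugConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    s = config.canvas_size
    if center is None:
        lo, hi = config.mosaic_center_jitter
        cx = float(rng.uniform(s * lo, s * hi))
        cy = float(rng.uniform(s * lo, s * hi))
    else:
        cx, cy = float(center[0]), float(center[1])
    icx, icy = int(round(cx)), int(round(cy))

    first = items[0][0]
    channels = first.shape[2:] if first.ndim == 3 else ()
    canvas = np.full((s, s) + channels, 114, dtype=np.uint8)
    out: list[PolygonAnnotation] = []
    for k, (image, annotations) in enumerate(items):
        image, anns = _random_item_transform(image, annotations, config, rng, identity_transforms)
        h, w = image.shape[:2]
        if k == 0:  # upper-left: bottom-right corner of the image at the centre
            x1a, y1a, x2a, y2a = max(icx - w, 0), max(icy - h, 0), icx, icy
            x1b, y1b = w - (x2a - x1a), h - (y2a - y1a)
        elif k == 1:  # upper-right
            x1a, y1a, x2a, y2a = icx, max(icy - h, 0), min(icx + w, s), icy
            x1b, y1b = 0, h - (y2a - y1a)
        elif k == 2:  # lower-left
            x1a, y1a, x2a, y2a = max(icx - w, 0), icy, icx, min(icy + h, s)
            x1b, y1b = w - (x2a - x1a), 0
        else:  # lower-right
            x1a, y1a, x2a, y2a = icx, icy, min(icx + w, s), min(icy + h, s)
            x1b, y1b = 0, 0
        if x2a <= x1a or y2a <= y1a:
            continue
        canvas[y1a:y2a, x1a:x2a] = image[y1b:y1b + (y2a - y1a), x1b:x1b + (x2a - x1a)]
        dx, dy = x1a - x1b, y1a - y1b
        for ann in anns:
            shifted = dataclasses.replace(
                ann,
                vertices=tuple((x + dx, y + dy) for x, y in ann.vertices),
                image_size=(s, s),
            )
            clipped = _clip_polygon_to_rect(shifted, (x1a, y1a, x2a, y2a))
            if clipped is not None:
                out.append(clipped)
    return canvas, out


def mixup(
    item_a: tuple[np.ndarray, Sequence[PolygonAnnotation]],
    item_b: tuple[np.ndarray, Sequence[PolygonAnnotation]],
    config: AugConfig | None = None,
    rng: np.random.Generator | None = None,
    lam: float | None = None,
) -> tuple[np.ndarray, list[PolygonAnnotation]]:
    """Convex pixel-wise blend of two same-size images.

    The mixing weight ``lambda`` is drawn from ``Beta(alpha, alpha)`` with a
    large symmetric shape parameter (default 32), concentrating near 0.5.
    The output annotation list is the concatenation of both inputs' lists.
    """
    config = config or AugConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    img_a, anns_a = item_a
    img_b, anns_b = item_b
    if img_a.shape != img_b.shape:
        raise ValueError(f"mixup requires same-shape images, got {img_a.shape} vs {img_b.shape}")
    if lam is None:
        lam = float(rng.beta(config.mixup_beta_alpha, config.mixup_beta_alpha))
    blended = np.clip(
        np.rint(lam * img_a.astype(np.float64) + (1.0 - lam) * img_b.astype(np.float64)),
        0, 255,
    ).astype(np.uint8)
    return blended, [a.to_pixels() for a in anns_a] + [b.to_pixels() for b in anns_b]
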