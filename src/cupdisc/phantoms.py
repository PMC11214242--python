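"""Synthetic fundus phantoms with known optic-disc / optic-cup geometry.

A phantom is an RGB pseudo-fundus image paired with a grayscale label mask
in the REFUGE labelling convention (optic cup = 0, optic disc = 128,
background = 255).  Both structures are ellipses with exactly known centres
and semi-axes, so every downstream computation (polygon extraction, box
losses, vCDR) can be checked against closed-form geometry.

Coordinate convention used throughout the package: 0-based, ``x`` = column,
``y`` = row, origin at the top-left of the image.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from PIL import Image

CUP_GRAY = 0
DISC_GRAY = 128
BACKGROUND_GRAY = 255

_MASK_VALUES = frozenset({CUP_GRAY, DISC_GRAY, BACKGROUND_GRAY})


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its geometric invariants."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth geometry of one phantom.

    Semi-axes are ``(a, b)`` with ``a`` the horizontal (x) semi-axis and
    ``b`` the vertical (y) semi-axis, in pixels.  The vertical diameter of
    an ellipse is therefore ``2 * b``, the quantity entering the vertical
    cup-to-disc ratio.
    """

    image_height: int
    image_width: int
    disc_center: tuple[float, float]
    disc_semi_axes: tuple[float, float]
    cup_center: tuple[float, float]
    cup_semi_axes: tuple[float, float]
    vessel_noise: bool = True
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`PhantomSpecError` naming the first violated invariant."""
        for name, (a, b) in (("disc", self.disc_semi_axes), ("cup", self.cup_semi_axes)):
            if not (a > 0 and b > 0):
                raise PhantomSpecError(
                    f"degenerate ellipse: {name} semi-axes {(a, b)} must be strictly positive"
                )
        if self.image_height < 1 or self.image_width < 1:
            raise PhantomSpecError("image dimensions must be >= 1 pixel")
        for name, (cx, cy), (a, b) in (
            ("disc", self.disc_center, self.disc_semi_axes),
            ("cup", self.cup_center, self.cup_semi_axes),
        ):
            if cx - a < 0 or cx + a > self.image_width or cy - b < 0 or cy + b > self.image_height:
                raise PhantomSpecError(
                    f"{name} ellipse extends outside the image bounds "
                    f"({self.image_width}x{self.image_height})"
                )
        if not self._cup_inside_disc():
            raise PhantomSpecError("cup ellipse is not fully contained in the disc ellipse")

    def _cup_inside_disc(self, n_angles: int = 720) -> bool:
        # Sample the cup boundary densely; every point must satisfy the
        # disc's implicit ellipse inequality.
        t = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
        cx, cy = self.cup_center
        a, b = self.cup_semi_axes
        px = cx + a * np.cos(t)
        py = cy + b * np.sin(t)
        dcx, dcy = self.disc_center
        da, db = self.disc_semi_axes
        q = ((px - dcx) / da) ** 2 + ((py - dcy) / db) ** 2
        return bool(np.all(q <= 1.0 + 1e-12))

    @property
    def true_vcdr(self) -> float:
        """Analytic vertical cup-to-disc ratio ``b_cup / b_disc``."""
        return self.cup_semi_axes[1] / self.disc_semi_axes[1]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("disc_center", "disc_semi_axes", "cup_center", "cup_semi_axes"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class GrayscaleMask:
    """8-bit label raster in the {0, 128, 255} REFUGE convention."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.uint8)
        object.__setattr__(self, "pixels", arr)
        if arr.ndim != 2:
            raise ValueError("mask must be a 2-D array")
        values = set(np.unique(arr).tolist())
        if not values <= _MASK_VALUES:
            raise ValueError(
                f"mask contains values outside {{0, 128, 255}}: {sorted(values - _MASK_VALUES)}"
            )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


def _ellipse_membership(
    height: int, width: int, center: tuple[float, float], semi_axes: tuple[float, float]
) -> np.ndarray:
    """Boolean raster: pixel (i, j) is inside iff its centre (j+0.5, i+0.5)
    satisfies the implicit ellipse inequality."""
    cx, cy = center
    a, b = semi_axes
    ys = (np.arange(height, dtype=np.float64) + 0.5 - cy) / b
    xs = (np.arange(width, dtype=np.float64) + 0.5 - cx) / a
    return ys[:, None] ** 2 + xs[None, :] ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GrayscaleMask]:
    """Rasterize one phantom: RGB pseudo-fundus image plus its label mask.

    The mask layers the cup (0) over the disc (128) over the background
    (255).  The RGB image is cosmetic — bright disc on an orange fundus,
    optional dark vessel strokes — and is a deterministic function of the
    spec (same seed gives bit-identical output).  Vessel strokes never
    alter the mask.
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    disc = _ellipse_membership(h, w, spec.disc_center, spec.disc_semi_axes)
    cup = _ellipse_membership(h, w, spec.cup_center, spec.cup_semi_axes)

    mask = np.full((h, w), BACKGROUND_GRAY, dtype=np.uint8)
    mask[disc] = DISC_GRAY
    mask[cup] = CUP_GRAY

    rng = np.random.default_rng(spec.seed)
    rgb = np.empty((h, w, 3), dtype=np.uint8)
    rgb[..., 0] = 170
    rgb[..., 1] = 70
    rgb[..., 2] = 35
    # low-amplitude texture so the background is not constant
    rgb = rgb.astype(np.int16) + rng.integers(-12, 13, size=(h, w, 1), dtype=np.int16)
    disc_color = np.array([235, 190, 120], dtype=np.int16)
    cup_color = np.array([250, 225, 170], dtype=np.int16)
    rgb[disc] = disc_color + rng.integers(-8, 9, size=(int(disc.sum()), 1), dtype=np.int16)
    rgb[cup] = cup_color + rng.integers(-8, 9, size=(int(cup.sum()), 1), dtype=np.int16)

    if spec.vessel_noise:
        _draw_vessels(rgb, rng)

    rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    return rgb, GrayscaleMask(mask)


def _draw_vessels(rgb: np.ndarray, rng: np.random.Generator, n_vessels: int = 6) -> None:
    """Stamp dark meandering strokes into the RGB image (in place)."""
    h, w = rgb.shape[:2]
    vessel = np.array([120, 30, 25], dtype=np.int16)
    for _ in range(n_vessels):
        x = float(rng.uniform(0, w))
        y = float(rng.uniform(0, h))
        angle = float(rng.uniform(0, 2 * np.pi))
        half = max(1, int(rng.integers(1, max(2, w // 200))))
        for _ in range(max(h, w)):
            angle += float(rng.normal(0.0, 0.15))
            x += np.cos(angle)
            y += np.sin(angle)
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < w and 0 <= yi < h):
                break
            y0, y1 = max(0, yi - half), min(h, yi + half + 1)
            x0, x1 = max(0, xi - half), min(w, xi + half + 1)
            rgb[y0:y1, x0:x1] = vessel


@dataclasses.dataclass(frozen=True)
class JitterRanges:
    """Fractional uniform jitter applied to a base spec when sampling a dataset.

    Each fraction f means the corresponding quantity is multiplied by a
    uniform draw from [1 - f, 1 + f] (for semi-axes) or shifted by a uniform
    draw from +/- f * semi-axis (for centres).
    """

    disc_axes: float = 0.1
    cup_axes: float = 0.1
    center_shift: float = 0.05


def generate_dataset(
    n: int,
    base_spec: PhantomSpec,
    jitter: JitterRanges | None = None,
    seed: int = 0,
    max_attempts: int = 100,
) -> list[tuple[np.ndarray, GrayscaleMask, PhantomSpec]]:
    """Sample ``n`` phantoms around ``base_spec`` with uniform jitter.

    Invalid draws (containment or bounds violations) are rejected and
    resampled, up to ``max_attempts`` per phantom.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_spec.validate()
    jitter = jitter or JitterRanges()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = None
        for _ in range(max_attempts):
            candidate = _jitter_spec(base_spec, jitter, rng, seed=int(rng.integers(0, 2**31)))
            try:
                candidate.validate()
            except PhantomSpecError:
                continue
            spec = candidate
            break
        if spec is None:
            raise PhantomSpecError(
                f"could not sample a valid phantom spec within {max_attempts} attempts "
                f"(phantom {i}); narrow the jitter ranges"
            )
        rgb, mask = generate_phantom(spec)
        out.append((rgb, mask, spec))
    return out


def _jitter_spec(
    base: PhantomSpec, jitter: JitterRanges, rng: np.random.Generator, seed: int
) -> PhantomSpec:
    def scale(pair: tuple[float, float], f: float) -> tuple[float, float]:
        return (
            pair[0] * float(rng.uniform(1 - f, 1 + f)),
            pair[1] * float(rng.uniform(1 - f, 1 + f)),
        )

    da = scale(base.disc_semi_axes, jitter.disc_axes)
    ca = scale(base.cup_semi_axes, jitter.cup_axes)
    f = jitter.center_shift
    dc = (
        base.disc_center[0] + float(rng.uniform(-f, f)) * base.disc_semi_axes[0],
        base.disc_center[1] + float(rng.uniform(-f, f)) * base.disc_semi_axes[1],
    )
    cc = (
        dc[0] + float(rng.uniform(-f, f)) * ca[0],
        dc[1] + float(rng.uniform(-f, f)) * ca[1],
    )
    return dataclasses.replace(
        base, disc_semi_axes=da, cup_semi_axes=ca, disc_center=dc, cup_center=cc, seed=seed
    )


def save_phantom(
    rgb: np.ndarray, mask: GrayscaleMask, spec: PhantomSpec, out_dir: Path | str, stem: str
) -> dict[str, Path]:
    """Write image (RGB PNG), mask (single-channel 8-bit PNG) and spec JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.png",
        "mask": out_dir / f"{stem}_mask.png",
        "spec": out_dir / f"{stem}_spec.json",
    }
    Image.fromarray(rgb, mode="RGB").save(paths["image"])
    Image.fromarray(mask.pixels, mode="L").save(paths["mask"])
    paths["spec"].write_text(json.dumps(spec.to_dict(), indent=2, sort_keys=True) + "\n")
    return paths


def load_mask(path: Path | str) -> GrayscaleMask:
    """Read a single-channel 8-bit mask image (PNG/BMP)."""
    with Image.open(path) as im:
        return GrayscaleMask(np.asarray(im.convert("L")))
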