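# Methods

## Scope and model

The package implements the non-neural machinery of a detection-style
optic-disc/optic-cup segmentation pipeline: annotation conversion, ROI
cropping, augmentation geometry, the IoU-family box-regression losses,
IoU-thresholded detection metrics, and the clinical vertical cup-to-disc
ratio (vCDR). Network training and inference are deliberately out of
scope; everything here is exact geometry and counting, which is why it can
be validated end to end on synthetic phantoms.

Coordinates are 0-based with `x` = column, `y` = row, origin at the
top-left, throughout.

## Synthetic phantoms

A phantom is defined by two ellipses (disc and cup) with centres and
semi-axes `(a, b)` in pixels, the cup contained in the disc (checked by
sampling the cup boundary at 720 angles against the disc's implicit
inequality). Rasterization is pixel-centred: pixel `(i, j)` belongs to an
ellipse iff its centre `(j + 0.5, i + 0.5)` satisfies
`((x−cx)/a)² + ((y−cy)/b)² ≤ 1`. This makes the mask a deterministic,
unambiguous function of the spec and bounds the measured vertical extent
of each structure within ±1 px of `2b`.

The RGB image (bright disc on an orange fundus, optional dark meandering
vessel strokes) is cosmetic: only the mask carries ground truth, and
vessel strokes never touch the mask. All randomness flows from a single
integer seed through `numpy.random.default_rng`, so identical specs give
bit-identical phantoms.

What the phantoms emulate: the REFUGE labelling convention (cup 0, disc
128, background 255), realistic structure scales (at the native 1634×1634
frame a disc is ~400 px tall, cups 0.3–0.7 of that), and per-image
geometric variation via uniform jitter on axes and centres with
rejection-resampling of invalid draws. What they do not emulate:
photometric realism, pathology (hemorrhages, exudates), annotation
disagreement between graders, or non-elliptical boundaries. Passing tests
therefore demonstrate the correctness of the geometric chain, not
segmentation performance on clinical images.

## Mask-to-polygon adapter

Three steps, each with a fixed convention:

1. **Row extremes.** For every image row containing the target gray value,
   emit the leftmost and rightmost such pixel (one point if they
   coincide). Gray matching is exact by default (REFUGE-style masks are
   palette-exact); a ±tolerance is available for lossy-compressed masks.
2. **Stride subsampling.** Keep the extreme pair of every 15th *occupied*
   row, anchored at the topmost occupied row, and always retain the
   bottommost occupied row. The stride is interpreted over rows (not
   contour arc length) because the extraction itself is row-wise; forcing
   the last row preserves the region's vertical extent exactly, which the
   vCDR depends on.
3. **Clockwise sort.** About the vertex centroid C, each point P is keyed
   by `atan2(−(y−Cy), x−Cx)` and sorted descending — clockwise as
   displayed with y pointing down — with angle ties broken by ascending
   radius. The result always passes the shoelace orientation test
   (positive signed area in image coordinates).

Classes absent from a mask are omitted; classes yielding fewer than 3
vertices are omitted with a warning. The adapter must run before
letterbox/mosaic padding, which introduces value-0 pixels that would alias
with the cup label.

Label files use the standard YOLO segmentation dialect: one instance per
line, `class_id x1 y1 x2 y2 …`, coordinates normalized by image
width/height at 6 decimals (round-trip error ≤ 0.5·10⁻⁶ normalized).
Class ids are fixed: disc → 0, cup → 1. Prediction files may carry one
trailing confidence per line.

**Fidelity.** The polygon's symmetric Hausdorff distance to the true
ellipse boundary is bounded by the sampling stride: vertex error comes
from ±1 px rasterization, and inter-vertex error from the chord-vs-arc
deviation, largest near the vertical extremes where the boundary is
flattest (for a 15-row stride on REFUGE-scale ellipses the measured
maximum is ~4 px).

## ROI crop and augmentations

The ROI window is fractional: rows `[0.25·H, 0.65·H)`, columns
`[0, 0.5·W)` by default, with floor on starts and ceil on ends so no
boundary pixel of the fractional region is lost. Vertices shift by the
window origin; annotations entirely outside are dropped, partially
outside are clamped to the window.

Letterbox scales by `target / max(h, w)`, rounds the scaled shape, and
splits the padding evenly with the odd pixel to the bottom/right; the
transform record (scale, pads) inverts vertices exactly. Mosaic samples a
centre uniformly in `canvas·[0.25, 0.75]²`, applies per-item horizontal
flip (p = 0.5), uniform scale in [0.5, 1.5] and HSV jitter (gains ±0.015,
±0.7, ±0.4 in hue/saturation/value fractions), then places the four items
in the UL/UR/LL/LR quadrants cropped at the centre lines; polygons are
clipped to their quadrant with Shapely and dropped below 3 vertices.
Mixup draws λ from Beta(32, 32) — a large symmetric shape concentrating
near 0.5, matching the "mixing" intent — blends pixels convexly, and
concatenates the two label lists. All magnitudes are configurable; none
of them is canonical, as only the operation kinds are fixed by practice.

Because vCDR is a ratio of vertical extents, uniform scaling and
translation (letterbox; crop with a fully contained disc) leave it
unchanged up to quantization — a property the tests exploit.

## Box losses

`iou` is intersection area over union area (0 for an empty union). The
aspect term exponent in CIoU defaults to 2, the standard definition;
exponent 3 is available for comparison but makes `v` sign-indefinite, so
`α` can leave [0, 1]. `α` is defined as 0 at the removable singularity
IoU = 1, v = 0, keeping the loss continuous at the optimum. γ in
Focal-EIoU defaults to 0.5 and `0^γ := 0`, so disjoint pairs get zero
loss — the focal weight deliberately suppresses low-overlap pairs, which
also means Focal-EIoU is *not* monotone along a straight-line approach
(it rises from ~0 before falling to 0 at coincidence) even though EIoU
itself is. Denominators are guarded with ε = 10⁻⁹; non-degenerate values
change by less than 10⁻⁹ relative.

## Evaluation

Matching is per class on axis-aligned box IoU (the tight hull of each
polygon); polygon-mask IoU is available as an option. Pairs with IoU
strictly greater than the threshold (default 0.5) are matched greedily by
descending IoU, ties broken by lower prediction index then lower ground
truth index, one-to-one. On instances with ≤6 boxes per side greedy
matching attains the exhaustive-optimal TP count (verified by brute
force). TN is fixed at 0 and excluded — it is ill-defined in detection —
and F1 is micro-averaged over pooled classes by default with a per-class
report, since no averaging convention is canonical. Confidence is carried
but not thresholded unless requested.

`vertical_diameter` of a polygon is `max y − min y` over vertices; the
mask form uses `max − min` of occupied row indices for consistency with
adapter polygons (which retain the first and last occupied rows), so the
two forms agree exactly on adapter output.

## Numerical and problem-size choices

- Rasterized vertical extent of an ellipse of semi-axis `b` is `2b − 1`
  px (max − min of ~2b occupied rows), so the relative vCDR bias is about
  `1/(2·b_cup) − 1/(2·b_disc)`. vCDR-recovery checks therefore run on
  REFUGE-scale phantoms (1634×1634, disc b = 200, cup b = 110, jitter
  ±10–20%), where this bias is ~1% — comfortably inside the 2% recovery
  band while spanning true ratios 0.40–0.73 across the 0.5 decision line.
- Oracle checks use 1000 random box pairs against exact `Fraction`
  arithmetic (tolerance 10⁻¹²), a 10⁶-point Monte-Carlo membership
  estimate (10⁻²), and direct formula transcriptions (10⁻⁹).
- Pipeline determinism tests use 4–6 phantoms at 400×400; adapter
  fidelity uses 20 phantoms at 800×800 — sizes chosen to exercise the
  geometry at multiple scales while keeping the suite quick.

## Known limitations

- Single connected component per class is assumed (true of OD/OC);
  multi-component regions and holes are out of scope.
- The adapter is row-based, so extremely flat regions (< 3 occupied rows)
  cannot produce a polygon.
- Mosaic clipping uses polygon intersection, which can change the vertex
  count and ordering of partially clipped annotations.
- Greedy matching is optimal in TP count for the small instance sizes
  verified; no optimality claim is made for hundreds of overlapping boxes
  per image, which does not occur in this two-structure domain.
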