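"""ROI cropping and detection-style augmentations with exact label transforms.

The fixed-fraction ROI keeps rows 0.25-0.65 and columns 0-0.5 of the frame
(where the optic nerve head sits in standard fundus photographs).  The
letterbox, mosaic and mixup augmentations each carry the polygon vertices
through the same geometric transform as the pixels.
"""

import numpy as np

from cupdisc import (
    AugConfig,
    PhantomSpec,
    compute_roi_window,
    crop_roi,
    generate_phantom,
    letterbox,
    mask_to_annotations,
    mixup,
    mosaic,
    vcdr_from_annotations,
)

window = compute_roi_window(1634, 1634)
print(f"ROI window of a 1634x1634 fundus image: rows [{window.row_start}, {window.row_end}), "
      f"cols [{window.col_start}, {window.col_end})")

# place the phantom inside its frame's default ROI window
spec = PhantomSpec(
    image_height=800, image_width=800,
    disc_center=(200, 360), disc_semi_axes=(150, 120),
    cup_center=(200, 360), cup_semi_axes=(60, 50),
    seed=11,
)
rgb, mask = generate_phantom(spec)
anns = mask_to_annotations(mask)
print(f"\nvCDR before any transform: {vcdr_from_annotations(anns).vcdr:.4f}")

cropped, cropped_anns = crop_roi(rgb, anns, compute_roi_window(800, 800))
print(f"after ROI crop to {cropped.shape[1]}x{cropped.shape[0]}: "
      f"{vcdr_from_annotations(cropped_anns).vcdr:.4f}")

boxed, boxed_anns, record = letterbox(cropped, cropped_anns, 640)
print(f"after letterbox to 640x640 (scale {record.scale:.3f}, "
      f"pad ({record.pad_x:.0f}, {record.pad_y:.0f})): "
      f"{vcdr_from_annotations(boxed_anns).vcdr:.4f}")
# vCDR is a ratio of vertical extents, so crop and letterbox leave it
# unchanged — the transforms are exact on the labels.

rng = np.random.default_rng(0)
config = AugConfig(canvas_size=640, seed=0)
canvas, mosaic_anns = mosaic([(boxed, boxed_anns)] * 4, config, rng)
print(f"\nmosaic canvas {canvas.shape[1]}x{canvas.shape[0]} with "
      f"{len(mosaic_anns)} surviving polygons after quadrant clipping")

blended, blended_anns = mixup((boxed, boxed_anns), (canvas, mosaic_anns), config, rng)
print(f"mixup blends pixels (Beta(32,32) weight near 0.5) and concatenates labels: "
      f"{len(blended_anns)} polygons")
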