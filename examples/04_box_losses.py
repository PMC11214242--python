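"""The IoU-family bounding-box regression losses with full term breakdowns.

CIoU penalizes centre distance and aspect-ratio mismatch on top of overlap;
EIoU replaces the coupled aspect term with separate width/height penalties;
Focal-EIoU reweights EIoU by IoU^gamma so well-overlapping boxes dominate.
"""

import json

from cupdisc import BBox, ciou, eiou_loss, focal_eiou_loss, iou

pred = BBox(0, 0, 2, 2)
gt = BBox(1, 1, 3, 3)
print(f"pred {pred} vs gt {gt}")
print(f"IoU = {iou(pred, gt):.6f}  (exact 1/7)")

breakdown = eiou_loss(pred, gt)
print("\nEIoU breakdown:")
print(json.dumps({k: round(v, 6) for k, v in breakdown.as_dict().items()}, indent=2))
# l_iou = 6/7 (overlap term), l_dis = 2/18 (centre distance over enclosing
# diagonal), l_asp = 0 (same width and height); value is their sum.

focal = focal_eiou_loss(pred, gt, gamma=0.5)
print(f"\nFocal-EIoU (gamma=0.5) = IoU^0.5 * L_EIoU = {focal.value:.6f}")

disjoint = ciou(BBox(0, 0, 2, 2), BBox(4, 0, 6, 2))
print(f"\ndisjoint same-shape pair: CIoU = {1 - disjoint.value:.3f} "
      "(negative: the centre-distance penalty acts even at zero overlap)")
print(f"but Focal-EIoU = {focal_eiou_loss(BBox(0, 0, 2, 2), BBox(4, 0, 6, 2)).value:.3f} "
      "— the IoU^gamma weight suppresses non-overlapping pairs entirely")
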