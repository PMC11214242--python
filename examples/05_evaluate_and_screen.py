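"""Detection evaluation at IoU > 0.5 and vCDR-based glaucoma screening.

Predictions are matched to ground truth per class, one-to-one, greedily by
descending box IoU with a strict 0.5 threshold; precision, recall and F1
follow from the TP/FP/FN counts.  The vCDR of each image is the cup's
vertical diameter over the disc's; a ratio above 0.5 flags glaucoma risk.
"""

from cupdisc import (
    Detection,
    JitterRanges,
    PhantomSpec,
    compute_metrics,
    generate_dataset,
    mask_to_annotations,
    match_detections,
    vcdr_from_annotations,
)

base = PhantomSpec(
    image_height=800, image_width=800,
    disc_center=(400, 400), disc_semi_axes=(150, 120),
    cup_center=(400, 400), cup_semi_axes=(72, 60),
    seed=5,
)
items = generate_dataset(8, base, JitterRanges(disc_axes=0.1, cup_axes=0.25), seed=5)

tp = fp = fn = 0
print("image  vdd(px)  vdc(px)   vCDR   risk   true-ratio")
for i, (_, mask, spec) in enumerate(items):
    anns = mask_to_annotations(mask)
    dets = [Detection.from_annotation(a) for a in anns]
    m = match_detections(dets, dets)  # self-match: the noise-free ceiling
    tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    r = vcdr_from_annotations(anns)
    print(f"{i:5d}  {r.vdd:7.1f}  {r.vdc:7.1f}  {r.vcdr:.4f}  {str(r.glaucoma_risk):5s}  "
          f"{spec.true_vcdr:.4f}")

from cupdisc import MatchResult

metrics = compute_metrics(MatchResult(tp=tp, fp=fp, fn=fn))
print(f"\npooled over {len(items)} images: precision = {metrics.precision:.3f}, "
      f"recall = {metrics.recall:.3f}, F1 = {metrics.f1:.3f}")
# Matching converted ground truth against itself yields F1 = 1.0 — the
# evaluation chain adds no error of its own; measured vCDR tracks the true
# ellipse ratio to within the ~1 px rasterization quantization.
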