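# cupdisc

Building blocks for optic-disc / optic-cup (OD/OC) instance-segmentation
pipelines on retinal fundus images, aimed at glaucoma screening.

Glaucoma risk is commonly screened by the **vertical cup-to-disc ratio**,

```
vCDR = VDC / VDD
```

where VDC and VDD are the vertical diameters (in pixels) of the optic cup
and optic disc; a vCDR above 0.5 flags elevated risk. Detection-style
segmentation models (the YOLO family) need polygon annotations, a region
of interest around the optic nerve head, box-regression losses and
IoU-thresholded metrics. This package implements that surrounding
machinery as a tested library plus a thin CLI:

- **`phantoms`** — synthetic fundus phantoms: RGB pseudo-fundus images
  plus grayscale label masks in the REFUGE convention (cup = 0,
  disc = 128, background = 255) with exactly known ellipse geometry, so
  every other module is testable without clinical data.
- **`adapter`** — mask → polygon conversion: per-row leftmost/rightmost
  boundary extraction, stride-15 row subsampling (bottom row always kept,
  preserving vertical extents exactly), clockwise angular ordering, and
  YOLO-segmentation label I/O (normalized coordinates, 6 decimals).
- **`preprocessing`** — the fixed-fraction ROI crop (rows 0.25–0.65,
  columns 0–0.5 of the frame by default) and letterbox / mosaic / mixup
  augmentations, each with the exact induced transform on label vertices.
- **`box_losses`** — the IoU family with full intermediate terms:

  ```
  CIoU        = IoU − ( ρ²(b, b^gt) / ((w^c)² + (h^c)²) + αv )
  L_EIoU      = (1 − IoU) + ρ²/((w^c)²+(h^c)²) + (w−w^gt)²/(w^c)² + (h−h^gt)²/(h^c)²
  L_Focal-EIoU = IoU^γ · L_EIoU
  ```

  with `v = (4/π²)(arctan(w^gt/h^gt) − arctan(w/h))²`,
  `α = v/((1−IoU)+v)`, and enclosing box `(w^c, h^c)`.
- **`evaluation`** — greedy one-to-one matching at box IoU > 0.5 (strict),
  precision / recall / F1 from TP/FP/FN, and the vCDR computation with the
  \> 0.5 risk flag.

## Worked example

```python
>>> from cupdisc import BBox, eiou_loss, focal_eiou_loss
>>> eiou_loss(BBox(0, 0, 2, 2), BBox(1, 1, 3, 3)).value
0.9682539682539684
>>> focal_eiou_loss(BBox(0, 0, 2, 2), BBox(1, 1, 3, 3), gamma=0.5).value
0.36596560085020413
```

The two unit squares overlap with IoU = 1/7, so the EIoU loss is
`6/7 + 2/18 + 0 ≈ 0.9683` (overlap + centre-distance + aspect terms) and
the focal variant damps it by `(1/7)^0.5`.

End-to-end from the shell (`cupdisc --help` lists all subcommands):

```bash
cupdisc simulate -n 8 --seed 5 -o data/            # phantoms + masks + specs
cupdisc convert --masks data/ -o labels/           # masks -> YOLO-seg labels
cupdisc evaluate --predictions labels/ --ground-truth labels/ \
        --image-size 800x800 -o report/            # pooled F1 = 1.0
cupdisc vcdr --labels labels/ --image-size 800x800 -o vcdr.csv
```

A typical `vcdr.csv` row reads `phantom_0006,261.00,145.00,0.555556,true,ok`:
a 261 px disc with a 145 px cup gives vCDR 0.556, above the 0.5 screening
line, so the risk flag is set. The `examples/` directory contains one
narrative script per capability; each prints the numbers it computes and a
line on what they mean.

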