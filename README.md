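# pestdet

Data engineering, anchor optimization, architecture accounting and
evaluation for detecting insect pests in light-trap images.

Light traps photograph many nocturnal insects at once against a bright
panel. The resulting detection datasets are hard in three specific ways:
targets are tiny (per-class mean relative scale of roughly 0.1–0.6 % of the
image side), class counts are extremely imbalanced (from about a hundred
instances for a rare scarab to over fifty thousand for a common one), and
insects frequently overlap. `pestdet` implements the data-side and
model-specification-side machinery for a YOLOv3-based detector tuned to
this regime, for anyone building or auditing such a pipeline:

- **`pestdet.voc`** — Pascal VOC XML reading/writing, dataset collation
  (keep the nine configured maize-pest classes, drop empty images),
  per-class statistics (image/instance counts, average relative scale under
  both the √area and raw-area readings), and deterministic 8:2 train/val
  splitting.
- **`pestdet.augment`** — copy-paste instance augmentation: crop instances
  of rare classes, filter blurry (Laplacian-variance) and sticky
  (overlapping) crops, then paste them into sparse background images so that
  a pasted box never overlaps anything (IoU exactly 0) and pasted objects
  are spread apart (farthest-of-k-candidates placement). Used to raise
  per-class instance counts to targets while the validation/test images stay
  untouched.
- **`pestdet.enhance`** — online batch enhancement: random scale and aspect
  distortion, horizontal flip, and gray-bar letterboxing applied jointly to
  pixels and boxes, as a pure function of (input, params, seed).
- **`pestdet.anchors`** — k-means anchor clustering under the 1−IoU distance
  (Euclidean selectable), the **linear anchor stretch**
  `x₁′ = 0.5·x₁`, `x₉′ = β·x₉`,
  `xᵢ′ = (xᵢ−x₁)/(x₉−x₁)·(x₉′−x₁′)+x₁′`, `yᵢ′ = xᵢ′·yᵢ/xᵢ`
  that spreads concentrated anchors back over the three detection scales, a
  β-sweep utility, scale assignment, and anchor–GT match statistics.
- **`pestdet.arch`** — declarative specs of baseline YOLOv3 (Darknet-53,
  residual multiplicities 1,2,8,8,4, FPN neck, three heads) and the
  small-target variant (second residual block expanded to 4 units; in each
  head two DBLs wrapped into a parameter-neutral residual unit), with exact
  trainable-parameter counting, shape inference, single-branch pruning and
  backbone freeze scheduling.
- **`pestdet.evaluation`** — greedy detection–GT matching, precision/recall,
  all-point-interpolated AP and mAP at IoU 0.5.
- **`pestdet.synth`** — deterministic synthetic trap scenes reproducing the
  regime's statistics (small textured blobs, imbalance, occlusion), so
  everything above is testable offline.

## Worked example

Exact architecture accounting (no data, no training):

```sh
$ pestdet build-model --variant improved --classes 9 --report-params --report-shapes
stem                928
stage1           39,232
stage2          403,200
stage3        2,923,008
stage4       11,678,720
stage5       25,704,448
branch1      15,780,906
fpn1            131,584
branch2       4,023,850
fpn2             33,024
branch3       1,012,522
total        61,731,422
detect_head_213: 13x13x42
detect_head_238: 26x26x42
detect_head_263: 52x52x42
```

The improved variant totals 61,731,422 trainable parameters; the baseline
(`--variant baseline`) totals 61,566,814. The difference, 164,608, is
exactly the closed-form cost of the two extra 128-channel residual units
(`2 × (128·64 + 2·64 + 64·128·9 + 2·128)`) — the head's DBL→residual swap
costs nothing. Each head emits 42 channels: 3 anchors × (9 classes + 5).

Anchor clustering and stretching on a concentrated synthetic size sample:

```python
import numpy as np
from pestdet import anchors as anc
from pestdet.synth import generate_box_sample

sizes = generate_box_sample(
    2000, [(6, 8, 0.25, 5.0), (12, 14, 0.25, 3.0), (20, 24, 0.25, 1.0)], seed=7
)
aset = anc.cluster_anchors(sizes, k=9, metric="iou", seed=0)
print("anchors:", " ".join(f"{w:.1f}x{h:.1f}" for w, h in aset.anchors))
stretched = anc.linear_stretch(aset, anc.StretchParams(beta=7.0, first_scale=0.5))
print("stretched:", " ".join(f"{w:.1f}x{h:.1f}" for w, h in stretched.anchors))
```

```
anchors: 4.2x9.2 5.2x5.8 5.9x8.0 7.3x10.9 8.2x7.0 9.9x16.7 12.6x11.3 15.3x17.7 21.7x25.4
stretched: 2.1x4.6 10.2x11.5 16.4x22.4 28.6x42.7 36.5x31.1 50.7x85.6 73.9x66.4 97.0x112.6 151.7x177.8
```

The nine clustered anchors span barely 4–26 pixels — they would all land in
one effective scale band. After the stretch (β = 7) they cover 2–178 pixels,
giving all three detection branches distinct, usable templates while every
anchor keeps its aspect ratio. `anc.sweep_beta` tabulates a score callback
(for example `anc.mean_best_iou(sizes)`) over β = 1…10 to choose the factor.

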