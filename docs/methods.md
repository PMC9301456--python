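# Methods

This note records the models, conventions and design choices behind
`pestdet`, in the order data flows through the toolkit.

## Coordinates and boxes

Internally every box is 0-based and half-open, `[xmin, xmax) × [ymin, ymax)`,
so `width = xmax − xmin` and two boxes that merely touch have IoU 0. Pascal
VOC files store 1-based inclusive coordinates; conversion happens only in
`pestdet.voc` at the I/O boundary (`internal xmin = voc xmin − 1`,
`internal xmax = voc xmax`). This keeps all area/IoU arithmetic free of
off-by-one corrections.

## Dataset collation and statistics

Collation keeps only the configured classes (the nine maize-pest indices
5, 6, 8, 13, 24, 29, 31, 32, 36 by default) and drops images left without
any target. Unregistered class tags in XML are dropped silently with a
counted warning — they are noise to be removed, not errors.

"Average relative scale" (GT size relative to image size) admits two
readings: the raw area ratio, and the linear ratio
`100 · sqrt(box_area / image_area)`. For plausible trap-camera resolutions
only the linear reading lands in the sub-percent band reported for this
kind of data, so it is the displayed default; both are computed and
exported, and the CSV carries both columns so the ambiguity stays visible.

`DatasetSummary` is additive over disjoint dataset unions: counts add
exactly, relative scales merge as instance-weighted means. The train/val
split (default 8:2) shuffles a lexicographically sorted path list under a
seeded generator, so it is independent of input order and filesystem
enumeration.

## Copy-paste instance augmentation

The balancing procedure crops every instance of a deficit class, filters
the bank, and pastes survivors into sparse backgrounds:

- **Sharpness filter.** The manual "discard blurry crops" step is replaced
  by a reproducible proxy: the variance of a Laplacian response over the
  grayscale patch (0 for flat patches, large for in-focus texture). The
  threshold is configuration, default 0 (no filtering), because absolute
  Laplacian variance depends strongly on image scale and texture.
- **Sticky flag.** A crop whose source box overlaps any other GT box
  (IoU > 0) carries neighbour pixels and is excluded by default.
- **Placement.** "No overlap, as far apart as possible" is realised by a
  farthest-candidate heuristic: per attempt, `candidate_count` uniform
  positions inside the margins are drawn; among those with IoU 0 against
  every existing and previously pasted box, the one maximising the minimum
  center distance wins. This is O(candidates × boxes), deterministic under
  a seed, and near-optimal in practice; a global optimiser would buy little
  against rectangular non-overlap constraints.
- **Flips.** Each enabled flip axis is applied independently with
  probability 0.5 before pasting. Crops are pasted at native size by direct
  rectangular copy — the crops *are* rectangular GT regions, so feathering
  would blur annotation-true pixels (a feathering option is deliberately
  absent rather than default-off, keeping the paste bit-exact).
- **Backgrounds.** Images with at most `background_max_objects` boxes
  (default 5), sparsest first. A background may be reused, but each use
  starts from the original pixels and produces one new image, bounding the
  density of any single output. How many crops go into one output image
  (`crops_per_image`, default 5) and the background threshold are free
  parameters of the procedure with no canonical values; both are exposed.

Balancing is only ever applied to the training pool; validation and test
images must reach evaluation without pasted instances, and the pipeline
keeps them on a separate path.

## Online enhancement

`random_enhance` draws a scale from `scale_range`, distorts width and
height independently by up to `aspect_jitter`, optionally flips, then
letterboxes onto a square `target_size` canvas filled with `gray_value`.
Because the final letterbox rescales content to fit, the scale draw changes
the resampling resolution (texture detail) while the aspect jitter is what
changes geometry; with neutral parameters the operation reduces exactly to
a plain letterbox. Boxes travel as float arrays through the same affine
map, are clipped to the canvas, and are dropped when a side falls below one
pixel. Defaults — gray 128, scale (0.25, 2.0), jitter 0.3, horizontal flip
at p = 0.5 — follow common YOLOv3 training practice; none are canonical and
all are configuration. The function takes an explicit seed and touches no
global RNG state, so training pipelines and tests share behaviour exactly.

## Anchor optimization

**Clustering.** GT `(w, h)` sizes are clustered by k-means (default k = 9)
under the YOLO convention of `1 − IoU` between size-aligned boxes; squared
Euclidean on `(w, h)` is selectable (delegated to scikit-learn). Under the
IoU metric the cluster mean is not the cost-minimising centroid, so Lloyd
iterations use mean updates but the recorded cost is never allowed to rise:
a worsening update is rolled back and the run stops. Initialisation is by
k-subsets of the data (all of them when there are few, seeded random
subsets otherwise), keeping the best run by cost. A consequence worth
naming: the returned centroids may be data points (medoid-like) when no
mean update improves on them, which is correct under the monotone-cost
contract. For tiny inputs the result provably matches exhaustive
enumeration over this candidate family (tested).

**Linear stretch.** With anchors sorted by width `x₁ ≤ … ≤ x_k`:

    x₁′ = first_scale · x₁          (default 0.5)
    x_k′ = β · x_k
    xᵢ′ = (xᵢ − x₁)/(x_k − x₁) · (x_k′ − x₁′) + x₁′    (interior i)
    yᵢ′ = xᵢ′ · yᵢ / xᵢ

The interior formula evaluated at the endpoints is consistent with the
endpoint definitions, so applying it to i = 2…k−1 and setting the endpoints
directly is equivalent and numerically exact. The height rule preserves
every anchor's aspect ratio identically, and the whole transform commutes
with uniform rescaling of the anchor set. Degenerate spread
(`x_k = x₁`) is rejected. The β-sweep applies the stretch over a grid
(default integers 1…10) and records a caller-supplied score; the packaged
score is the mean best size-aligned IoU against a GT sample. That score is
a stated proxy for ranking β without training — selecting β by trained mAP
is outside this package's scope.

**Scale assignment and matching.** Nine anchors split three-per-branch by
ascending *area* (the convention that reproduces the canonical COCO
grouping, where a tall narrow anchor belongs to the middle branch despite a
small width). Match statistics letterbox each GT to the network input,
tile each branch's anchors at the grid cell containing the GT center
(anchor centered on the cell center), and count templates whose positional
IoU with the GT exceeds a threshold. Counts are invariant to whole-stride
translations and scale linearly in the number of GT copies — which is
precisely why pasting copies of a small target multiplies its matched
anchors and improves its chance of being learned.

## Architecture accounting

Both specs are pure layer graphs. The baseline is standard YOLOv3:
Darknet-53 backbone (stem conv, five stride-2 downsampling convs, residual
blocks of 1, 2, 8, 8, 4 units; a unit is a 1×1 bottleneck DBL plus a 3×3
DBL with identity skip), an FPN neck with two upsample–concat merges, and
three branches of five DBLs + one DBL + a biased 1×1 detection conv with
`3 × (num_classes + 5)` output channels. The improved variant (a) expands
the second residual block (128 filters) from 2 to 4 units, retaining more
low-level spatial information for small targets, and (b) in every branch
wraps the second and third of the five pre-head DBLs into a residual unit —
the same two convolutions plus a parameter-free skip, applied identically
in all three branches since the swap is parameter-neutral wherever it is
placed. All downsampling is by stride-2 convolution; the layer vocabulary
contains no pooling at all.

Counting conventions, fixed because they are the standard framework
semantics and self-consistent with the accounting they produce: a conv
contributes `in·out·k²` weights; convs feeding a BatchNorm carry no bias;
detection convs carry `out` biases; BatchNorm contributes 2 trainable
parameters per channel (affine scale/shift — running statistics are
buffers). Under these rules the baseline at 9 classes totals 61,566,814
parameters and the improved variant 61,731,422; the difference is exactly
two 128-channel residual units, 164,608. The totals are cross-checked in
the tests against independent closed-form per-block sums.

Branch pruning restricts *decoding* to one head (default branch 3, the
stride-8 head that dominates detection of small pests) and leaves the graph
— and therefore the parameter count — untouched; it is idempotent. The
freeze schedule is plain data: backbone layers non-trainable for the first
`freeze_epochs` epochs (50 of 100 in the reference protocol), everything
trainable after. Training itself (loss, optimizer loop, pretrained weights)
is out of scope; the reference hyper-parameters are recorded in
`pestdet.config.DEFAULT_TRAINING` for downstream use, including an
unresolved discrepancy in the reported initial learning rate (0.002 vs
0.0002), which is carried as two fields rather than silently resolved.

## Evaluation

Matching is the de-facto VOC/COCO greedy rule per image and class:
detections in descending confidence, each taking its best-IoU unmatched GT
if that IoU exceeds the threshold (strictly; default 0.5), ties on IoU
breaking to the lower GT index. Pooled per-class labels form the PR curve;
confidence ties sort FP-before-TP, which makes the curve a pure function of
the label multiset (image order cannot matter) and coincides exactly with
the exhaustive-cutoff construction. AP is the all-point interpolated area
under the precision envelope — the literal integral of P(R), chosen over
11-point interpolation as the faithful reading of that integral. mAP is the
unweighted mean of per-class APs; "mean recall" is the unweighted mean of
final per-class recalls (curve-end recall, not at a fixed confidence
cutoff — a cutoff variant can be had by pre-filtering the detections).
Classes with neither GT nor detections are excluded from the means with a
warning rather than contributing a meaningless 0 or 1.

## Synthetic fixtures

`pestdet.synth` renders textured ellipses with per-class hues on a bright
noisy canvas and records their exact bounding boxes. The default
configuration reproduces the trap-data regime at a 1024-pixel canvas: nine
classes whose mean linear relative scales lie in the 0.11–0.57 % band,
abundance weights spanning 108 to 53,347 (the rarest class is ~0.07 % of
instances), twelve objects per scene, and a 10 % per-object occlusion
probability realised by centering a new object inside a previous one's box.
Size draws are log-normal with a unit-mean correction
(`exp(N(−σ²/2, σ))`) so configured means are true means.
`SceneConfig.small()` is a 256-pixel variant with proportionally enlarged
blobs for unit tests where per-pixel work on a large canvas is irrelevant.

What the fixtures deliberately do not emulate: insect morphology and
inter-species visual similarity, lens/illumination artefacts, and the
within-image spatial clustering of real trap photographs. Tests passing on
fixtures therefore establish the *mechanics* (bookkeeping, placement
constraints, geometry, determinism, metric arithmetic) — not detection
accuracy on real pests, which requires training on real data and is
explicitly out of scope. The per-class hue exists so a trivial
colour-threshold detector yields non-degenerate PR curves for evaluation
tests; its mAP on fixtures is a smoke signal, not a result.

## Numerical and determinism conventions

Every stochastic operation takes an explicit seed and builds its own
`numpy` generator; nothing touches global RNG state. The CLI fans a single
global seed out through fixed per-stage offsets (`pestdet.config`), so each
stage is reproducible in isolation. Letterbox transforms are stored as
`(scale, pad_x, pad_y)` and inverted exactly on float boxes; integer
quantisation is left to callers. Summary additivity holds to 1e-9 on the
weighted means and exactly on counts. Degenerate inputs fail loudly where
they would corrupt results (zero-size boxes, `x_k = x₁` anchor spread,
non-divisible-by-32 input sizes) and are skipped with logged warnings where
the source format makes them routine noise (degenerate VOC boxes, unknown
class tags, unreadable images).

## Problem sizes used in the checked runs

The test suite and acceptance checks run on synthetic datasets of 4–12
scenes (128–256 px) for pipeline mechanics, 100 scenes for the paste
invariants, 200 scenes for abundance calibration, and 400–4000 size draws
for clustering and sampling statistics; the clustering-vs-enumeration
oracle runs at n ≤ 8, k ≤ 3 where exhaustive enumeration is exact. The
architecture accounting is exact and size-independent.
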