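# Methods

`trapcount` detects and counts insect pests on yellow sticky-trap
images.  The pipeline has four stages: a saliency-map-based region
proposal generator, patch classification, improved non-maximum
suppression (INMS) with a merging strategy, and counting/evaluation.
A dual-path fusion rule combines the pipeline with an arbitrary
external detector.  This note records the model, the tunable
parameters, the numerical choices, and what the synthetic benchmark
does and does not demonstrate.

## Saliency map and activation regions

The image is converted to CIELAB (sRGB, D65).  The saliency score of a
pixel is the Euclidean distance between the image's mean LAB colour
and the Gaussian-blurred LAB colour at that pixel:

    S(r, c) = || I_mu − [L_blur(r,c), a_blur(r,c), b_blur(r,c)] ||_2

On a near-uniform trap the mean colour is essentially the card colour,
so small dark insects receive high scores.  Design choices:

- **Blur scale `sigma` (px, default 3).**  Unstated in the method's
  sources; 3 px preserves insects of ~10–40 px while suppressing
  pixel noise.  Exposed in the config, as is the boundary mode
  (edge replication, so a constant image has exactly zero saliency).
- **Normalisation.**  `S` is divided by its maximum (all-zero maps
  pass through), giving the mask threshold `alpha` a fixed [0, 1]
  meaning across images.  Default `alpha = 0.10`; thresholding is
  inclusive (`>=`), so `alpha = 0` activates every pixel.
- Pixel indexing is 0-based; boxes are half-open `[xmin, xmax) ×
  [ymin, ymax)`.

The binary mask is decomposed into connected components (default
8-connectivity, so thin appendages stay attached; 4-connectivity is
available).  Components whose bounding-box area is below
`beta = 30 px²` are discarded as non-target specks.  Each surviving
activation region carries its tight box and its pixel-count centroid
— the centroid rather than the box centre, because it is robust to
ragged components.

## Region proposals

Each region is gated background/foreground: during training by
overlap with annotations (`iogt(a, b_gt) = area(a ∩ b_gt)/area(b_gt)`,
foreground iff any value reaches `iogt_threshold = 0.5`), at inference
by the C1 patch classifier on the region crop.  A foreground region
emits its own box plus k "tune-up" boxes of preset scales centred on
the centroid, giving the object classifier several view fields of one
anchor.

**Tune-up scale ladder.**  Defaults are seven square scales
16, 19, 23, 27, 32, 38, 45 px — a geometric ladder with side ratio
~1.2.  The ratio is chosen so that any two detections of the same
insect at successive view fields overlap with IoU above the merge
threshold *even after earlier merges*: the merge step averages
coordinates, so a merged box lags behind the next rung, and a side
ratio above ~1.21 lets the running average fall out of reach (the
merged duplicate then survives suppression as a false positive).
Sparser ladders (e.g. three scales 24/32/44) were measured to produce
exactly this duplicate-detection failure on held-out synthetic scenes.
Scales are fully configurable, including rectangular ones.  Clipped
tune-up boxes smaller than 4 px² are dropped.

## Patch classifiers

C1 (background/foreground) and C2 (category) share one contract:
patch in, (label, confidence) out.  Two implementations ship:

- **`CNNPatchClassifier`** — the lightweight CNN: three same-padded
  convolution stages (kernel, stride, filters) = (7, 2, 40),
  (5, 2, 60), (3, 2, 120), each followed by 2×2 max-pooling, then
  dense layers of 100 and 50 units; sigmoid hidden activations and a
  softmax output head.  The input side is fixed to 64 px (crops are
  resized), which yields the integer spatial ladder
  64→32→16→8→4→2→1 and 120 flattened features; other sides are
  accepted only if every stage stays integral.  Training: softmax
  cross-entropy, adaptive moment estimation (β₁ = 0.9, β₂ = 0.999,
  ε = 1e−8), zero-mean Gaussian initialisation.  The published
  configuration initialises with standard deviation 1; that choice
  saturates sigmoid units badly, so the std is a parameter
  (`init_std`).  The trainability test uses 0.1, which trains to
  >95 % on separable colour patches within 200 steps; the default
  remains 1.0 for fidelity.  The network is implemented directly on
  numpy (im2col convolutions) and its gradients are verified against
  finite differences in the test suite.
- **`ColorRuleClassifier`** — a deterministic oracle that predicts
  from the mean colour of the central half of the patch; confidence
  is always 1.0.  Rules whose colour balls overlap are rejected at
  construction.  For the synthetic benchmark two oracles are used:
  C1 is a single broad rule (anything dark is foreground — robust to
  crops whose window mixes insect and card), while C2 uses tight
  per-class tolerances (14 RGB units).  The tolerance is deliberately
  below ~16.6, the closest approach of the black-insect-to-yellow-card
  mixing line to the moth colour; a looser C2 mislabels
  partially-filled views of dark insects as moths.

Crops that reach past the image border are padded with white pixels
([255, 255, 255]) so the apparent object size is preserved.  C2
training labels use IoU against annotations: a proposal takes the
class of its best-overlapping annotation if that IoU reaches
`iou_label_threshold = 0.5`, else "background".

## Improved non-maximum suppression

Conventional NMS greedily keeps the most confident remaining detection
and removes every other detection with IoU above the threshold
(class-agnostic — which is what allows a confidently wrong detection
to erase a correct one).  INMS first runs a merge loop: the working
set is sorted by ascending box area; the smallest box is merged into
the first same-class box (in that order) it overlaps above
`merge_iou_threshold`, the set is re-sorted, and boxes that overlap
nothing move to a holding set.  Merged geometry is the
confidence-weighted average of the coordinates (rounded half-up);
merged confidence is the noisy-OR `1 − (1−c₀)(1−c₁)`, so repeated
sightings strictly reinforce.  Conventional NMS and the confidence
threshold `gamma` are then applied to the held set.

Numerical determinism: area ties are broken by
(xmin, ymin, confidence), then the remaining coordinates, so the
result is independent of input order.  The merge phase is idempotent,
and `merge_iou_threshold = 0.35` by default: IoU between an elongated
region box and a square view field of the same insect commonly lands
at 0.40–0.49, so a 0.5 threshold leaves unmerged duplicates (this was
measured on held-out synthetic scenes; the merge threshold of the
original algorithm statement is not published).  `nms_iou_threshold`
and `gamma` default to 0.5.

## Counting, metrics and fusion

The count of an image is the number of post-INMS detections.  A
detection is correct for an annotation iff the labels match and
`iogt >= 0.5`; each detection is assigned to the annotation it covers
best, per annotation only the highest-IoGT correct detection is a true
positive and the rest are false positives.  DR = recall,
FDR = 1 − precision, and

    F1 = 2·DR·(1−FDR) / (DR + (1−FDR)),

with zero-denominator cases defined as 0.  Counting is scored by MAE
and MSE of per-image counts (absolute value applied in the MAE).

Dual-path fusion: an external detector's box is kept iff it overlaps
(IoU > 0) at least one detection of this pipeline; its confidence is
unchanged.  Whether the pipeline's own unmatched detections are also
emitted is an open reading of the original rule — the default emits
validated external boxes only, and `union_mode` adds the unmatched
pipeline boxes.

## Synthetic scenes

The generator emulates the essential features of trap images: a noisy
yellow card (RGB (230, 200, 40), Gaussian noise σ = 5), insects as
filled rotated ellipses with per-insect colour jitter in two classes
("diamondback moth" (60, 50, 40), "others" (20, 20, 20)), side lengths
12–36 px, tight-box annotations written as PASCAL VOC XML (1-based
inclusive, converted to the internal 0-based half-open convention on
read).  Scenes are 320×320 with 3–8 insects and a 60 px
centre-spacing minimum; all values are synthetic stand-ins, not
measurements.  Everything is deterministic given the seed; per-image
seeds derive from the master seed.

`adjacency_fraction` places that fraction of insects overlapping an
existing insect: centre distance is 75 % of the two ellipses' radial
supports along the connecting direction, so touching insects form one
contiguous blob, and clustered insects share their neighbour's class
(the documented miss mode is two conspecific insects fusing into one
activation region).  This reproduces the pipeline's characteristic
failure — one detection per blob, hence undercounting — which the
fusion rule then repairs using an external detector's boxes.

**What the benchmark does not show.**  The ellipse world has no wings,
legs, lighting, occlusion by debris, or camera blur; class separation
is purely chromatic, so the colour-rule oracle is an upper bound on
classifier behaviour, not a statement about trained-CNN accuracy on
photographs.  Passing synthetic recovery demonstrates the geometry of
the pipeline (proposal coverage, merging, suppression, counting,
fusion), not field performance.

## Problem sizes

The synthetic benchmark uses 30 scenes per condition (~190 insects);
the CNN trainability check uses 400 patches of 64 px and 200
optimisation steps.  These sizes give stable metrics while keeping
the whole suite fast on a single CPU.

## Known limitations

- The merge loop is greedy and order-deterministic but not globally
  optimal; pathological same-class chains can collapse to one box.
- Insects touching each other are undercounted by design of the
  connected-component proposal stage; fusion with a dense detector is
  the mitigation, not a fix.
- The numpy CNN is single-threaded and meant for small patches; it is
  a reference implementation of the published architecture, not a
  performance vehicle.
- VOC parsing accepts the LabelImg dialect only (one `bndbox` per
  object, integer coordinates).
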