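# Methods

## Problem and approach

Manual lesion delineations in dermoscopy are binary, but the true lesion
border is ambiguous: different annotators disagree mostly in a narrow band
around the contour. Training a segmentation network against hard 0/1
targets in that band rewards overconfidence. `softlabeler` replaces the
hard targets near the border with *soft* lesion-membership probabilities
derived from image structure, and trains with a collaborative objective
that keeps the hard labels as the primary signal.

The pipeline has two stages.

**Stage 1 — soft-label construction.** The image is over-segmented into
roughly `N` compact, color-homogeneous superpixels with SLIC (localized
k-means in CIELAB + (row, col) space, grid spacing `S = sqrt(H*W/N)`,
compactness `m`). Each superpixel is compared with the lesion contour of
the hard mask. Superpixels that do not touch the contour keep their hard
value (1 if all-lesion, 0 if all-background). Every pixel of a
contour-touching superpixel is remapped through a distance-based
membership function:

    f(x) = 1/2                        x on the contour
    f(x) = 1/2 (1 + d/(1+d))          x inside the lesion
    f(x) = 1/2 (1 - d/(1+d))          x outside the lesion

where `d` is the Euclidean distance (pixels) from `x` to the nearest
contour point. The mapping is monotone in `d` on each side, bounded in
(0, 1), symmetric about 1/2, and equals exactly 1/2 on the contour. The
contour is defined as the set of lesion pixels with at least one
4-connected background neighbour, so the contour belongs to the lesion
and thresholding the soft label at 0.5 (ties → lesion) reconstructs the
hard mask exactly — the construction adds graded uncertainty without
moving the decision boundary.

A superpixel counts as "touching the contour" when it contains a contour
pixel (equivalently, for connected regions, when it contains pixels of
both classes, plus the all-lesion regions whose border coincides locally
with the contour). The weaker both-classes test would leave stray contour
pixels at hard value 1 and break the exact-0.5 contour property.

**Stage 2 — collaborative training.** A segmentation network producing
per-pixel lesion probabilities `q` is trained with

    L = alpha * CE(p_hard, q) + beta * KL(p_soft || q)

Both terms use the binary two-outcome expansion (lesion and background
channels), averaged over pixels, in nats. `beta = 0` is the hard-label
baseline. The KL direction treats the soft label as the reference
distribution; since the entropy of `p_soft` is constant in `q`, the KL
term is gradient-equivalent to a cross-entropy against soft targets.

## Numerical choices

- **Distance transform.** `scipy.ndimage.distance_transform_edt` (exact
  Euclidean) against the contour pixel set; verified against an
  exhaustive O(pixels × boundary) minimum to 1e-9 in the tests.
- **Clamping.** Predictions and soft labels are clamped to
  `[1e-7, 1 - 1e-7]` before logarithms: kept-hard soft-label pixels are
  exactly 0/1, where KL is otherwise undefined.
- **SLIC.** Backed by `skimage.segmentation.slic` (CIELAB conversion with
  the sRGB/D65 convention, gradient-free grid seeding, 10 iterations,
  `m = 10` default, connectivity enforcement with `min_size_factor
  = 0.25`), then relabeled to contiguous ids `0..n_regions-1`. The
  realized region count stays within ±20% of the request on the fixtures
  (asserted in tests, including 1000 regions at the 500×375 working
  size). A `seed` argument exists for interface symmetry; SLIC itself is
  deterministic. The compactness value is exposed because no single value
  is canonical for dermoscopy; 10 is the standard default for 8-bit RGB.
- **Degenerate inputs.** Constant masks have no contour: boundary
  extraction returns an empty set, distance/soft-label generation raise a
  degenerate-mask error, and surface metrics report NaN sentinels rather
  than raising (overlap ratios with zero denominators likewise).
- **HD95 percentile.** 95th percentile with linear interpolation
  (`numpy.percentile`) of each directed nearest-neighbour distance list,
  then the max of the two directions, mirroring the max{d_AB, d_BA}
  structure of the classical Hausdorff distance.
- **Precision.** `TP/(TP+FP)` — the standard definition ("proportion of
  predicted positive samples").

## Metrics

Precision, sensitivity, IoU and Dice come from the pixel confusion
matrix; Dice ≡ 2·IoU/(1+IoU) is asserted as an identity. ASD is the
symmetric mean nearest-neighbour distance between the two contour point
sets; HD95 the robust Hausdorff distance above. Contours use the same
4-connectivity rule as stage 1, so one boundary convention holds
package-wide. Distances are in pixel units (configurable spacing is out
of scope; no physical spacing is defined for the synthetic fixtures).

## Synthetic fixtures

The generator emulates the structure the method assumes rather than
photorealistic dermoscopy: a single 4-connected, irregular, roughly
elliptical lesion on textured skin. Masks are star-convex blobs — radius
profile `r(θ) = r0 (1 + roughness · smooth_noise(θ))` with band-limited
harmonics (wavenumbers 2–6), rasterized around a random centre; the
radius is rescaled until the realized area fraction falls inside the
requested range (default 0.1–0.4 of the image, truncated to what
geometrically fits the frame). Star-convexity guarantees a single
connected component cheaply. Defaults: 500×375 frame (the working size of
the label-construction stage), border roughness 0.3 (irregular borders
are the regime the method targets), lesion/skin contrast 0.5 with a 5 px
smooth falloff at the border (the blurred-edge look), background noise
std 6/255 with 8 px correlation length. Optional artifacts: dark Bézier
hair strokes spanning the frame and a dark corner vignette. Everything
derives from one integer seed; identical configs give byte-identical
outputs.

What the fixtures do **not** have: real annotator noise, color
constancy shifts, bubbles, vessels, multi-component lesions, or any
relationship between texture and the lesion boundary beyond the contrast
step. A green test on these fixtures establishes that the label
construction, losses, metrics and training loop behave as specified — not
that the method improves segmentation of real dermoscopy.

## Training at desk scale

The network is a small U-shaped fully convolutional net written in NumPy
(no deep-learning framework is assumed by the environment): one 3×3
conv + ReLU per level, 2×2 max-pool down, nearest-neighbour upsample +
skip concatenation up, 1×1 conv + sigmoid head; explicit im2col
forward/backward passes, verified against central finite differences; a
hand-written Adam optimiser.

Desk-scale defaults were chosen once for a single-CPU budget: 96×96
inputs, depth-3 widths (8, 16, 32), batch 8, 20 epochs, learning rate
0.01, early stopping on a 20% validation carve-out with patience 5,
augmentation by random flips and right-angle rotations. Right angles (not
arbitrary rotations) keep image, hard mask and soft label in exact
register, so the augmented soft label still re-thresholds to the
augmented hard mask — asserted as an invariant. The learning rate is
higher than the full-scale recipe's 0.001 because the tiny network under
mean-pixel gradients otherwise stays near the degenerate all-background
prediction within the epoch budget; `FULL_SCALE` preserves the published
recipe (batch 40, lr 0.001, Adam, 20 epochs, 80/20 split) for reference.
The benchmark comparison trains each loss-weight arm on identical splits,
initializations and batch orders per seed, so arms differ only in
(alpha, beta).

`n_segments = 100` for 96×96 benchmark fixtures keeps the per-superpixel
area (~90 px) of the same order as 1000 superpixels at 500×375 (~190 px).

## Known limitations

- The NumPy network is orders of magnitude slower than a GPU framework;
  the trainer is a desk-scale demonstration of the loss design, not a
  production training loop.
- Soft labels use the global distance field, not distances clipped to
  each superpixel; the two agree near the contour, which is where the
  remapping matters.
- Region counts from SLIC can drift below the ±20% band on pathological
  inputs (e.g. extreme aspect ratios); the contract is asserted on the
  supported fixture family.
- HD95's percentile convention (per-direction, linear interpolation) is
  one of several in circulation; comparisons across toolkits should check
  the convention first.
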