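# Methods

## The task and the model

Panoptic segmentation assigns every pixel of a panoramic dental radiograph
both a semantic class and, for countable objects (teeth), an instance
identity. `panodent` implements this as direct set prediction with a mask
transformer: the network emits a fixed-size set of N (mask, class) pairs

  ŷ = {(m̂ᵢ, p̂ᵢ(c))}ᵢ₌₁..N,

where each m̂ᵢ is a soft mask at output stride 4 and p̂ᵢ is a distribution
over the real classes plus the "no object" class ⌀. The ground truth of an
image is a set of K ≤ N non-overlapping class-labelled masks
y = {(mᵢ, cᵢ)}ᵢ₌₁..K. There are no region proposals, anchors or per-pixel
class maps to decode; masks and classes are read off the output heads
directly.

### Dual-path architecture

Two streams process the image jointly:

* **Pixel path** — a small residual CNN (stem stride 2, three residual
  stages reaching strides 4, 8 and 16; each stage's output is projected by a
  1×1 convolution to the shared feature width D).
* **Memory path** — N learned object-query vectors of width D ("global
  memory"); each query comes to represent one candidate segment.

The paths communicate inside *dual-path transformer blocks* through four
attention flows: the memory is updated by one attention whose keys/values
are the concatenation of memory and pixel tokens (this fuses
memory-to-memory and memory-to-pixel attention; expressivity is unchanged,
one pass is saved); pixel features read the memory back through
pixel-to-memory feedback attention; and pixel-to-pixel self-attention is
factorized axially — a height-axis pass followed by a width-axis pass — so
its cost is linear per axis instead of quadratic in pixels. Every attention
and feed-forward sub-layer is a pre-norm residual
(`x + sublayer(LN(x))`), and output projections of fresh attention layers
are zero-initialized, so an untrained block is exactly the identity; this is
asserted by tests. Fixed 2-D sinusoidal position codes are added only to
attention *inputs* (and to the mask head's input), never to the residual
streams, which preserves that identity contract.

The decoder is hourglass-style: it traverses the stride schedule
(16 → 8 → 4) L times, merging scales by bilinear resizing plus summation
with the backbone skip feature; dual-path blocks sit at the stride-16
visits, residual conv blocks elsewhere. Intermediate pyramid features are
only aggregation state, never predictions.

### Output heads

* **Class head**: two fully connected layers and a softmax map each memory
  vector to p̂ᵢ over C real classes plus ⌀.
* **Mask head**: memory passes through 2 FC layers to give f ∈ R^{N×D}; the
  stride-4 decoder output passes through 2 convolutions to give the
  normalized pixel feature g ∈ R^{D×H/4×W/4}. Masks are the product f·g.
  Both factors are L2-normalized (f per row, g per pixel) and the product is
  scaled by a learnable temperature (initialized at 10) before a per-pixel
  softmax across the N slots. The per-slot normalization makes the
  non-overlapping-masks property structural: slot scores at each pixel form
  a probability vector, so the pixel-to-mask argmax is well-posed.
* **Auxiliary heads**: semantic logits over things + stuff classes, and a
  per-pixel L2-normalized embedding map used by the instance-discrimination
  loss.

Default widths: N = 40 (> 32 teeth + margin), D = 64, L = 2, 4 attention
heads. Inputs indivisible by 16 are zero-padded bottom/right and the
stride-4 outputs cropped back to ⌈H/4⌉×⌈W/4⌉ (bottom/right rather than
symmetric padding keeps the crop aligned to the stride grid).

## The PQ-style loss

Each ground-truth/prediction pair is scored by

  sim(yᵢ, ŷⱼ) = p̂ⱼ(cᵢ) · Dice(mᵢ, m̂ⱼ),

a product of recognition quality and segmentation quality: 1 iff class and
mask both match exactly, 0 if the class is wrong or the masks disjoint.
Ground truth is assigned to slots by maximum-total-similarity bipartite
matching (Hungarian algorithm on the negated similarity matrix; an
exhaustive-enumeration oracle verifies optimality in the tests). For the
matched pairs,

  L_pos = Σᵢ [ p̂_σ(i)(cᵢ) · (−Dice(mᵢ, m̂_σ(i)))
             + Dice(mᵢ, m̂_σ(i)) · (−log p̂_σ(i)(cᵢ)) ],

i.e. a dice loss weighted by class correctness plus a cross entropy weighted
by mask correctness. The weight factors are detached from the gradient by
default (they act as weights, not objectives); a flag re-enables their
gradients for ablation. Unmatched slots are trained towards ⌀:

  L_neg = Σ_{unmatched j} −log p̂ⱼ(⌀),

and the two terms are balanced as L_PQ = α·L_pos + (1−α)·L_neg with
α = 0.75 by default (positives weighted higher, as is common when positive
examples are scarce relative to the N−K negatives).

Numerical choices: soft Dice uses ε = 1e-6 denominator smoothing;
probabilities inside logs are floored at 1e-8; a perfect prediction
contributes exactly −1 per matched mask (so L_pos = −K at the optimum),
which the tests assert. Ground-truth masks are area-averaged (not
nearest-neighbor) onto the stride-4 grid before comparison so the soft Dice
stays meaningful; an optional variant evaluates the matched Dice on scores
bilinearly upsampled to image resolution against the binary masks
(`LossWeights.dice_full_resolution`, off by default — it did not improve
recovery in our experiments and makes steps slower).

### Auxiliary losses (weight 1.0 each by default)

1. **Instance discrimination** — each in-mask pixel embedding is pulled
   toward its own instance's mean embedding and pushed from the others via a
   softmax over e·μ_k/τ (τ = 0.3; at most 4096 pixels per image, subsampled
   deterministically and evenly per instance). With one instance there are
   no negatives and the loss is 0.
2. **Mask-ID cross entropy** — per-pixel cross entropy of the N-slot
   distribution against the matched slot of the segment covering the pixel
   (majority coverage > 0.5 at stride 4); uncovered pixels are excluded.
3. **Semantic segmentation loss** — mean per-pixel cross entropy over the
   semantic classes; the target class is the one with the largest summed
   coverage, with ties broken towards the lowest class index so the result
   is independent of segment ordering.

The total loss is permutation-invariant to both ground-truth ordering and
slot relabeling (matching absorbs permutations); this is property-tested.

## Inference

Slots whose argmax class is ⌀ are dropped; remaining slots below the class
confidence threshold (default 0.4) are removed. Mask scores are bilinearly
upsampled to image resolution and every pixel takes the argmax slot, voided
when the winning score falls below the pixel threshold (default 0.4).
Upsampling scores *before* the argmax (rather than upsampling an integer id
map) places mask boundaries at interpolated score crossings instead of on
stride-4 block edges; the argmax keeps labels integral. Finally, pixels
claimed by no instance take the semantic argmax class and become one
segment per stuff class; empty segments are pruned. Exact class-probability
ties break towards the lowest class index.

## Class vocabulary

By default one thing class (`tooth`, category 1) and one stuff class
(`background-tissue`, category 2). The class head covers things only (+ ⌀);
stuff enters through the semantic head and the panoptic merge, and stuff
ground-truth segments do not take part in the set matching. A 32-way
numbered-tooth vocabulary (`Vocabulary.numbered_teeth()`) is available but
off by default.

## The synthetic phantom

The generator emulates the *structure* of panoramic radiographs, not their
physics: up to 32 teeth placed along two mirrored arches (superellipse
cross-sections with random eccentricity, rotation following the arch
tangent, optional root notches), later teeth clipped against earlier ones so
ground truth stays non-overlapping, and one background-tissue segment
covering every remaining pixel (so K = teeth + 1 and the masks tile the
image). Appearance: a low-frequency tissue field, a brighter jaw band,
per-tooth intensity jitter, optional high-intensity restoration blobs inside
teeth and an appliance wire across the arch (both alter appearance only and
are *not* separate segments), then global contrast compression, Gaussian
blur and noise. Everything derives from one integer seed;
the same configuration is bit-identical across runs, and per-image seeds of
a dataset are spawned deterministically from the dataset seed.

Defaults: 256×512 images, 32 teeth, tooth height 48–72 px (teeth spanning
roughly a quarter to a third of image height, as in real panoramics),
restoration probability 0.6 and appliance probability 0.25 per image
(approximating the category mix reported for public panoramic datasets),
noise σ 0.03, blur σ 1.0, contrast factor 0.55–0.9. Desk-scale test
conditions use 64×128 images with 6 teeth of 16–22 px, the same relative
scale.

What passing tests on phantoms does *not* show: robustness to real
radiographic phenomena (occlusion and superposition of anatomy, exposure
variation, implants, deciduous teeth, true X-ray noise statistics). The
phantom establishes that the architecture, loss and pipeline can recover
known non-trivial instance layouts — touching instances included — not
clinical performance.

## Problem sizes and training defaults

The package is CPU-first and single-process. The built-in demonstrations
and tests train a reduced model (N = 12, D = 32, L = 1, backbone widths
8/16/24/32) on four 64×128 phantoms with Adam (lr 1.5e-3, cosine decay to
5%, batch 2, ≤ 2000 steps); this recovers mean matched soft Dice ≈ 0.93 and
pixel F1 ≈ 0.89 on the training images across seeds. Matched soft Dice here
is the conventional one — un-thresholded predicted scores against binary
ground truth (rasterized at the stride-4 grid); soft-vs-soft Dice is not
used as a recovery metric because it is bounded by Σm²/Σm < 1 even for an
exact prediction. The residual gap to the interpolation-limited F1 ceiling
(≈ 0.95 at this scale) comes from boundary cells: the dice-loss optimum is
binary per stride-4 cell, which quantizes boundaries to about half a cell.

## Known limitations

* The pixel F1 of a stride-4 model is resolution-limited; small teeth at
  coarse image sizes lose proportionally more boundary accuracy.
* Matching cost is K×N dense Dice; fine for K ≤ 32, not tuned beyond.
* The density-based inference variant (DBSCAN grouping of embedding
  vectors, `postprocess(..., use_clustering=True)`) is provided but off by
  default: it needs per-dataset tuning of its density radius and cannot
  separate touching instances whose embeddings have not yet been pulled
  apart by training. The argmax pathway is the reference decoder.
* Training is deliberately desk-scale; no accelerator support, no
  augmentation, no schedule search.
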