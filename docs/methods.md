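# Methods

This note documents the models, procedures and numerical choices behind
`weeddet`, and what its tests do and do not demonstrate.

## Setting

Site-specific weed management needs detectors that localize both crops and
weeds in top-down field images. Two structural difficulties dominate: the
object counts are heavily unbalanced (on the order of 17 crop plants per 3
weeds), and weeds are much smaller than crops, so single-scale features miss
them. The toolkit implements the two corresponding remedies — copy-paste
augmentation of the weed class at pixel level, and a detector whose
multi-scale fusion is learned per position — at a "desk scale" where every
stage is exhaustively testable on one CPU.

## Synthetic field scenes

`synthdata` paints scenes rather than loading field imagery: a brown soil
base (RGB 118/84/58) with Gaussian texture noise (default σ = 5 intensity
units), elliptical green crops and small multi-lobed green weeds. Defaults
emulate the statistics of an annotated sugarbeet corpus at reduced
resolution: 192×144 px scenes (the field corpus is 1296×966), 17 crops and
3 weeds per default scene, crop radii 7–10 px strictly above weed radii
2.5–4.5 px. The scale gap is enforced by a validation rule because it is the
phenomenon the ASFF head addresses.

Vegetation colors are sampled from ranges constrained so the excess-green
index 2G − R − B is strictly positive on plants and non-positive on
noise-free soil; this is what makes a vegetation-prior seed (maximum excess
green) valid for region growing. Ground-truth boxes are computed from the
painted masks, so they are tight by construction: every box edge touches at
least one vegetation pixel.

Placement uses rejection sampling (≤ 400 attempts per object) with two
constraints: pairwise box IoU ≤ 0.05 and a minimum box-gap
(`min_object_separation`, default 2 px). Corpus generation fixes aggregate
class counts exactly: the total object budget (images × objects-per-image)
is rounded down to the largest multiple of the reduced ratio, then
partitioned across images as evenly as possible with the remainder assigned
at random (seeded). Twenty images at ten objects each with ratio 17:3 give
exactly 170 crops and 30 weeds.

What the generator does **not** model: photorealism, growth stages,
illumination variation, occlusion between plants, motion blur, or the
400-image discrepancy between a raw corpus selection and its enhanced
subset. Tests passing on these scenes show the pipeline's bookkeeping and
numerics are right; they say nothing about accuracy on real field imagery.

## Copy-paste augmentation

Region growing uses a **fixed criterion**: a pixel joins the region when its
Euclidean RGB distance to the *seed pixel's* color is at most a threshold
(default 60). With a fixed criterion the grown region is exactly the
connected component of a thresholded boolean image, which makes the result
independent of visiting order and lets the production path use component
labeling (`scipy.ndimage.label`) while the tests check it against an
explicit breadth-first flood fill. A running-mean criterion would be
order-dependent and oracle-hostile; the threshold and connectivity (default
8) are configuration because the underlying method is conventionally cited
without parameters.

Patch extraction runs one region growth per weed box, confined to the box,
seeded either manually or at the box's maximum excess-green pixel. Empty
segmentations are *reported* (as failed box indices), never silently
dropped.

Pasting replaces pixels under the patch mask only — hard replacement, no
blending or illumination matching — so the bookkeeping is exact: pasting k
patches adds exactly k weed boxes, no pixel outside pasted masks changes,
and original annotations are preserved verbatim. Placement is rejection
sampling (≤ 100 attempts) against a pasted-box IoU bound (default 0.05)
versus all existing boxes.

The split applies ratios (default 8:1:1) with one hard constraint: synthetic
images and their source originals go to train, because a synthetic image
shares plants with its source and would otherwise leak across splits. Exact
split sizes are consequently *not* a contract — only the total, the ratio
targets on the unconstrained remainder, and the leakage invariant are.

## The detection blocks

**Transformer encoder.** Feature-map cells are flattened to tokens; a
multi-head self-attention sub-layer and an MLP sub-layer act with residual
connections in pre-norm order. Positional embeddings are a toggle, default
off at desk scale — without them the block is exactly permutation
equivariant, which is a testable property; with 3×3 bottom-level grids the
positions add little. The block replaces the bottleneck of the last CSP
stage of the backbone, where the resolution (and hence the attention cost)
is lowest; the number of inserted blocks is configuration.

**Involution.** The K×K spatial kernel at each position is generated from
the input feature vector at that position by a bottleneck head (1×1
channel reduction by ratio r, SiLU, 1×1 expansion to K·K·G weights) and
shared across all channels of a group — spatially specific, channel
invariant, the inverse symmetry of convolution. A 1×1 involution
degenerates to learned per-position scaling; the CFFI uses exactly this
degenerate form, and the tests pin its closed form.

**CFFI.** A 1×1 convolution reduces the top backbone map to the reference
width (768 at full scale, scaled by the width multiple), a 1×1 involution
aggregates spatial information on the reduced map, and the two results are
concatenated (2 × width channels). The block bridges backbone and neck so
the channel reduction to the lateral pathway loses less semantic content.
The CFFI output replaces the top-level lateral input of the neck.

**ASFF.** Each head level receives all three neck outputs rescaled to its
grid: identity at the same level; 1×1 channel projection then nearest
(default, bit-stable; bilinear optional) interpolation for upsampling;
3×3 stride-2 convolution one octave down; stride-2 max-pooling before that
convolution two octaves down. A 1×1 control convolution over the
concatenated rescaled maps emits three logit maps; a per-position softmax
yields the fusion weights, which therefore lie in [0, 1] and sum to one
(checked at 1e-6 absolute). The logit source is a design choice — the
softmax itself is the defined part.

## The detector

A YOLO-style single-stage network: CSP backbone (stride-2 convolutions and
C3 blocks), PANet-style top-down/bottom-up neck, anchor-based heads at
strides 8/16/32 with 3 anchors per level and (5 + n_classes) outputs per
anchor. Full-scale reference channels (64…1024; 768 for CFFI) scale by the
width multiple (default 0.125, minimum 4, multiples of 4); default input is
96 px. There is no batch normalisation — convolutions carry biases — which
keeps forward passes batch-consistent and training runs exactly
reproducible without running statistics.

Decoding follows the standard sigmoid parameterisation: center
(2σ(t) − 0.5 + grid) · stride, size (2σ(t))² · anchor, confidence
σ(obj) · σ(class). Assignment matches a truth box to anchors within a w/h
ratio factor of 4 on its cell and the two nearest neighbour cells. The loss
is mean(1 − CIoU) over assigned anchors, BCE objectness against the
assignment indicator with per-level balance (4.0/1.0/0.4), and BCE
classification; gains are box 1.0, obj 1.0, cls 0.5 — the box term carries
full weight because on short CPU runs a small box gain lets objectness
dominate and localization never converges.

Training is plain SGD with momentum 0.9 (default lr 0.05), gradients
clipped to a global norm of 5 — the attention blocks occasionally emit
sharp early gradients and clipping keeps one learning rate usable across
the whole ablation grid. No pretraining, no mosaic or other augmentation
tricks inside the trainer. All randomness flows from explicit seeds;
two runs with the same seeds produce identical loss curves.

Numerical guards: CIoU adds 1e-7 to unions, enclosing diagonals and aspect
ratios; its aspect coefficient is detached, as is conventional; decoded
boxes whose float32 size underflows to zero are dropped; the training loop
aborts with the offending component named if any loss term goes non-finite.

## Metrics

Matching is greedy in descending confidence (ties broken by input order,
stable): a detection takes the unmatched truth of highest IoU if that IoU
reaches the threshold, each truth is matched at most once, unmatched truths
are false negatives. AP uses the all-points precision-envelope
interpolation — the exact discretization of the integral definition, rather
than 11- or 101-point sampling. mAP is the plain mean of defined per-class
APs; a class with no ground truth has *undefined* AP and is excluded, not
counted as zero. The 0.5:0.95 variant includes both endpoint thresholds.

## Problem sizes

The test suite and examples run the training smoke test on 50 synthetic
96×96 scenes for 30 epochs (about a minute), the ablation grid for one
epoch per configuration, and all oracle equivalences on ≤ 10×10 fixtures.
These sizes are the package's chosen desk scale: large enough that training
measurably improves held-out mAP over an untrained model, small enough that
the whole suite runs in well under a minute of overhead per module.

## Known limitations

* Desk-scale training does not and cannot reproduce field-grade accuracy
  numbers; the end-to-end assertions are directional (loss decreases,
  trained beats untrained), not absolute.
* The numpy engine is float32 and single-threaded; bitwise determinism
  holds within one platform/BLAS, not necessarily across platforms.
* Region growing assumes the patch is color-separable from its local
  background, which the green-dominance of the synthetic scenes guarantees
  but real imagery may not.
* The conventional translate/rotate/scale augmentation re-tightens boxes to
  transformed corner hulls, which over-covers rotated objects slightly —
  acceptable for its role as a comparison baseline.
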