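# weeddet

A desk-scale toolkit for crop/weed object-detection research — the setting
where site-specific weed management needs a detector that finds many large,
round crop plants and few small, irregular weeds in top-down field imagery.

The toolkit packages the full experimental loop so that every stage runs in
seconds on one CPU and is reproducible bit-for-bit from a seed:

* **`weeddet.synthdata`** — synthetic top-down field scenes with exact
  ground truth: soil-textured background, green-dominant crop/weed blobs at
  a configurable (default 17:3) class imbalance, written as PNG + YOLO-txt
  labels + a manifest.
* **`weeddet.augment`** — pixel-level copy-paste augmentation: region-growing
  weed segmentation, a weed-patch bank, randomized pasting into originals
  (17:3 → 17:9 with two pastes per existing weed), class-ratio accounting,
  and a train/val/test split that pins synthetic images *and their source
  originals* to the training set.
* **`weeddet.nnblocks`** — the three architectural blocks as standalone,
  shape-contracted modules: a transformer encoder over feature-map cells,
  the involution operator and the CFFI bridge (parallel 1×1 convolution and
  1×1 involution, concatenated), and adaptively spatial feature fusion
  (ASFF) with per-position softmax weights.
* **`weeddet.model`** — a width/depth-configurable YOLO-style detector (CSP
  backbone, PANet-style neck, three-scale anchor head) with independent
  toggles for the three blocks, plus decoding, class-wise NMS, a composite
  CIoU/BCE detection loss and a deterministic SGD training loop.
* **`weeddet.metrics`** — IoU, greedy confidence-ordered matching,
  precision/recall/F1, all-points-interpolated AP, mAP@0.5 and
  mAP@0.5:0.95.
* **`weeddet.cli`** — `weeddet synth|augment|split|train|detect|eval|ablate`.

Everything neural runs on a small self-contained numpy reverse-mode
autodiff engine (`weeddet.autodiff`); there is no deep-learning framework
dependency.

## The core quantities

For a class with true positives TP, false positives FP and false negatives
FN:

```
precision = TP / (TP + FP)        recall = TP / (TP + FN)
F1 = 2 · precision · recall / (precision + recall)
AP = ∫₀¹ precision(recall) d(recall)      mAP = (1/N) Σ_classes AP
```

AP uses the all-points precision-envelope discretization of the integral;
mAP@0.5:0.95 averages mAP over IoU thresholds 0.50, 0.55, …, 0.95.

ASFF fuses three rescaled pyramid maps per position (i, j) at level l:

```
y_ij = α_ij · x¹→ˡ_ij + β_ij · x²→ˡ_ij + γ_ij · x³→ˡ_ij
α, β, γ = softmax(λ_α, λ_β, λ_γ)   so   α+β+γ = 1,  α,β,γ ∈ [0,1]
```

with the λ logit maps produced by a 1×1 control convolution.

## Worked example

```
$ python examples/02_copy_paste_augmentation.py
before: (17, 3)
patch bank: 6 segmented weeds
after : (17, 9)
```

Ten scenes at the corpus imbalance hold 170 crops and 30 weeds (17:3).
Pasting two segmented weed patches per existing weed into each image adds
60 weed annotations and no crop annotations, landing the augmented corpus
at exactly 17:9 — the bookkeeping the augmentation exists to achieve.

```
$ python examples/04_train_and_evaluate.py
model: 538889 parameters
loss: 7.602 -> 1.078
held-out mAP@0.5: 0.0026 (untrained) -> 0.1126
```

Thirty epochs of the full model (transformer + CFFI + ASFF) on 50
synthetic 96×96 scenes: the loss falls by a factor of seven and held-out
mAP@0.5 rises from chance level.  Desk-scale CPU training is a correctness
exercise, not a benchmark — see `docs/methods.md` for what these numbers
do and do not show.

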