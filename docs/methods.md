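# Methods

This note records the models, procedures and numerical choices behind
`histolearn`, including the places where the design was genuinely open and
what the synthetic experiments can and cannot establish.

## Data model and splits

A dataset is a directory tree of RGB images grouped by optical
magnification tier (40X/100X/200X/400X) and tumor class
(benign/malignant), optionally with a histological-subtype subdirectory.
The scanner is dialect-configurable (`mag-class` and `class-mag` level
orders), orders records lexicographically by path, and skips non-image
files and unparseable directories with a logged warning and a counter
rather than failing.

The train/test split is stratified by (magnification, class) with
round-half-up rounding per stratum, so per-tier test sets are well defined
even though stratification is a package choice rather than a requirement
of the protocol being reproduced. Splitting is image-level; the BreakHis
collection has patient structure that image-level splitting ignores, so
accuracies measured under it can be optimistic relative to patient-
disjoint evaluation. The initial labeled pool is a uniform random 20% of
the training split (16% of all data under an 80/20 split), drawn globally
rather than per stratum.

The package ships the published per-(subtype, magnification) sample counts
of the BreakHis collection as a reference fixture for accounting checks.
The benign cells sum to 2,320 while the accompanying narrative total is
2,480; the discrepancy exists in the source material and is reported
as-is — the summary operation always reports what is on disk.

## Preprocessing and augmentation

Images are resized (700×460 → 350×240 by default), cropped to 224×224
(random crop for training, center crop for evaluation and
pseudo-labeling), and standardized per image and per channel:
(x − μ_c)/(σ_c + ε) with ε = 1e-7, so a constant channel maps to zeros.
Statistics are computed in float64 to make the operation exact on constant
inputs and invariant to pixel ordering. Per-channel-per-image (rather than
per-image scalar) standardization is an interpretation choice; it removes
slide-level stain-intensity offsets per channel.

Geometric augmentation applies, in fixed order with seeded random draws:
fractional shift (default up to ±10% of each side), horizontal and
vertical flips (probability 0.5 each), and rotation (default ±15°), all
magnitudes configurable. Mixup draws λ ~ Beta(α, α) per pair (default
α = 0.2) against a random permutation of the batch, applying the same λ
to images and one-hot labels. Mixup and geometric augmentation apply only
to labeled training batches; evaluation and pseudo-labeling always see
unmixed center-cropped images, because absorption decisions must be made
on the data distribution the confidence is calibrated for.

## Architecture and parameter accounting

The backbone is the standard 50-layer bottleneck residual network (stem
64 channels; stage widths 64/128/256/512 with expansion 4; block counts
3/4/6/3; stage strides 1/2/2/2 after the strided stem and pool). The
truncated variant keeps conv1–conv3 only and emits 28×28×512 on a
224×224 input. The naive-inception block runs 1×1, 3×3 and 5×5
convolutions of widths (F1, F3, F5) plus a passthrough 3×3 stride-1
max-pool in parallel, all same-padded, concatenating to F1+F3+F5+512
channels.

Counting convention (fixed by matching the published full-depth total of
23,788,418 exactly): all convolutions carry biases; each batch-norm
channel contributes four parameters — γ, β and the moving mean/variance —
all included in full totals; the moving statistics are excluded from
trainable-only totals. The baseline head flattens the 7×7×2048 stage-5
output into a biased 2-unit dense layer (200,706 parameters).

The branch widths are pinned by exhaustive closed-form search against the
published 3,649,506 budget over F1, F3, F5 ∈ [1, 512] and head variants
(flatten vs global-average pooling × branch-conv bias on/off × head
batch-norm off/on), returning the first exact match in lexicographic
order: flatten head, biased branch convolutions, head batch-norm on,
widths (2, 221, 1). Two caveats are inherent: the search recovers *a*
configuration consistent with the budget, not necessarily the original
authors' (whose widths are unpublished); and no solution exists without
head batch-norm under this convention, which is itself weak evidence that
the audited model normalized the concatenated features. A default of
(64, 64, 64) is provided for all non-audit uses.

Freeze configurations 1–4 form a nested ladder over blocks
{inception, head} ⊂ +{conv3} ⊂ +{conv2} ⊂ +{conv1}; the inception block
and head are always trainable. A frozen batch-norm layer runs in
inference mode even during training and never updates its moving
statistics, which is what makes the freeze contract bit-exact.

## Optimization

The layer engine is a compact numpy implementation (im2col convolutions,
explicit backward passes, Adam with β₁ = 0.9, β₂ = 0.999); every layer's
analytic gradient is checked against central-difference numerical
gradients in the test suite at tolerance 1e-7. Training is single-
threaded-deterministic given the config seed. Supervised training uses
batch size 16 and learning rate 1e-3 at desk scale (the full-size
transfer-learning recipe uses batch 128 at the same rate); fine-tuning
uses the stepwise decay lr(e) = max(lr_min, lr_max · 0.8^e) with defaults
lr_max = 5×10⁻⁵, lr_min = 1×10⁻⁵, interpreted as starting at lr_max and
decaying monotonically to the floor — the source figure is qualitative
about step placement. There is no early stopping, validation-based model
selection, or class-imbalance correction by default.

## Self-training loop

Per round: train on the labeled pool (augmented + mixup), predict the
unlabeled pool, accept predictions with confidence strictly greater than
the threshold (default 0.90; "beyond 0.90" is read as strict inequality),
absorb them with their pseudo-labels, and record history. Defaults are 11
rounds of one epoch each; both knobs are configurable, and the desk-scale
experiments use three epochs per round so each round's accuracy is
measured after the optimizer has settled on the enlarged pool rather than
mid-transient. Pseudo-labels are frozen once assigned — absorbed records
are never re-labeled. Confidence is the maximum of the 2-class softmax;
exact ties resolve to the first class index. A single Adam instance
persists across the warm-up and all rounds, so moment estimates are not
reset when the pool grows.

The loop accepts an `initial_epochs` warm-up that fits the model to the
initial labeled pool before any pseudo-labeling. The reference protocol
begins from a pretrained backbone already trained on the labeled data; a
model trained from random initialization needs this phase because an
unconverged softmax classifier emits high-confidence predictions at
chance accuracy, and with frozen pseudo-labels a single premature
absorption round poisons the pool irreversibly. Desk-scale experiments
use 30 warm-up epochs; with the default of 0 the first round's training
is the only initial fit, which is appropriate when starting from
pretrained weights.

Terminology note: the procedure is often grouped with self-supervised
contrastive learning in the surrounding literature, but it contains no
pairwise contrastive loss; it is confidence-thresholded pseudo-label
self-training, and the package names it accordingly.

## Evaluation

Confusion matrices are 2×2 in (benign, malignant) order, rows true.
F1 = 2PR/(P+R) per class; zero-denominator precision/recall/F1 are
reported as 0 with a warning. ROC curves and AUC are one-vs-rest per
class with trapezoidal integration (equivalent to the Mann–Whitney pair
statistic with midpoint tie handling), delegated to scikit-learn and
cross-checked against exhaustive pair enumeration in the tests; a
single-class truth vector yields NaN AUC with a warning. The headline F1
convention treats malignant as the positive class. Reports are computed
per magnification tier and assembled into one table; a missing tier drops
its row with a warning.

## Synthetic data generator

Each image is a pink stroma background with a Poisson number of elliptical
hematoxylin-toned "nuclei" (lognormal radii, σ = 0.25, random orientation
and eccentricity, soft edges), additive Gaussian pixel noise
(σ = 0.04), and a per-tier radius multiplier (0.6/0.85/1.2/1.7 for
40X/100X/200X/400X) mimicking optical zoom. Class separability is one
scalar δ: the malignant class multiplies nucleus density by (1 + δ) and
radius by (1 + 0.25·δ) and adds within-nucleus chromatin texture of
amplitude 0.06·δ. At δ = 0 the class-conditional distributions are
identical by construction; δ = 2 gives malignant nuclei three times the
benign density and is the "clearly separable" condition used in the
experiments. Defaults: 12 images per (tier, class) cell, 64×64 pixels,
benign density 14 nuclei per 64×64 field, mean radius 3 px, δ = 1.5.
Images are generated deterministically from (seed, class, tier, index).

The generator emulates layout, class imbalance in difficulty, and
magnification structure; it does not attempt visual realism, stain
physics, subtype structure, patient correlation, or the label noise and
staining variability of real slides. Passing tests on it establish that
the pipeline's mechanics are correct and that the self-training loop
extracts value from unlabeled data when the class signal is real; they
say nothing about accuracy on real histopathology.

## Desk-scale experiment sizes

Tests use a proportionally shrunk model (stem 8 channels, stage widths
4/8/16/32, one block per stage, inception widths (4, 4, 4),
global-average-pool head) on 64×64 images — the full-size path is covered
by exact shape and parameter arithmetic. The paired self-training
comparison uses 300 images (60 test, 240 train, 48 initially labeled),
δ = 2, 30 warm-up epochs, 11 rounds × 3 epochs, batch 16, lr 1e-3, five
paired seeds, with the labeled-only baseline given the identical total
epoch budget; the chance-level check at δ = 0 averages five seeds of 80
training/120 test images. These sizes were chosen so the full suite runs
in minutes on one CPU while keeping test-set noise small relative to the
asserted margins.

## Known limitations

- The numpy engine is single-threaded and desk-scale; it is not a
  replacement for a GPU framework at 224×224 with thousands of images.
- Pretrained backbone weights are supported as a concept (freeze ladder,
  warm-up) but no weight download is implemented; all experiments start
  from seeded random initialization.
- Image-level splitting (above) and the unresolved benign-count
  discrepancy in the published table are inherited from the source
  protocol and documented rather than fixed.
- The pinned inception widths are budget-consistent, not author-verified.
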