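# Methods

## Problem and model

`dexaseg` segments the two forearm bones — ulna (label 1) and radius
(label 2) — against background (label 0) in dual-energy X-ray (DEXA)
forearm radiographs. Each subject contributes a low-energy (~45 kV) and
a high-energy (~75 kV) image of the same anatomy; one model handles
both. Accurate bone masks are the precondition for areal bone mineral
density computation, which is out of scope here.

The segmenter is an encoder–decoder convolutional network. The encoder
is five residual blocks separated by four 2×2 max-poolings; each
residual block stacks two residual units, and each unit runs
[3×3 conv → BN → ReLU → 3×3 conv → BN] on its main path with a
[1×1 conv → BN] projection shortcut, an elementwise add and a final
ReLU — four 3×3 and two 1×1 convolutions per block. Channel widths
double per stage from `base_channels` (default 32: 32→512). The decoder
mirrors it with four stages of [2×2 stride-2 transposed convolution →
concatenation with the matching encoder feature → two (3×3 conv → BN →
ReLU)]. A 1×1 convolution maps the final 32 feature channels to 3
classes, followed by a per-pixel softmax. The ablation baseline swaps
each residual encoder block for the plain two-convolution block and is
otherwise identical; at equal `base_channels` it has strictly fewer
parameters.

Two wiring details are not fixed by the block-level description and are
explicit package choices: the projection-shortcut residual unit is the
standard ResNet wiring consistent with the 4+2 convolution census, and
pooling follows each of the first four encoder blocks. All convolutions
use 'same' padding, so inputs need height and width divisible by 16;
`segment_image` reflect-pads other sizes and crops back. Convolution
weights use He initialization; BN starts at γ=1, β=0.

## Loss

Training minimizes the Generalized Dice loss over softmax
probabilities P and one-hot ground truth G:

    L = 1 − 2 Σ_c w_c Σ_m P_cm G_cm / Σ_c w_c Σ_m (P²_cm + G²_cm),
    w_c = 1 / ((Σ_m G_cm)² + ε),  ε = 1e−8.

The inverse-squared-volume weights rebalance the heavy class skew
(background dominates; the ulna is the smallest class). ε sits only in
the weight denominator: it bounds the weight of a class absent from an
image and is the sole regularization point — no ε is added to the main
fraction, so a perfect prediction scores exactly 0 up to ε effects.
Weights are computed per image and a batch's loss is the mean of
per-image losses, matching the per-image definition of M.

## Training engine

No GPU framework is used: `dexaseg.nn` is a self-contained NumPy layer
stack (convolution as kernel-tap matmuls, batch normalization with
running statistics, 2×2 max-pooling, 2×2 stride-2 transposed
convolution, softmax) with hand-written backward passes and an Adam
optimizer. Layers preserve the input dtype, so gradient correctness is
pinned by float64 finite-difference tests at every layer and
end-to-end through the loss (relative agreement ≤1e−4, typically
≤1e−6). Training runs in float32.

## Protocol

The training protocol is: Adam (β₁=0.9, β₂=0.999), initial learning
rate 1e−3 multiplied by 0.98 every 5 epochs (lr(e) = 1e−3·0.98^⌊e/5⌋),
mini-batch 16 with per-epoch reshuffling, 500 epochs by default.
Rather than an in-run early stop, the full epoch budget is spent and
the checkpoint with the highest validation Dice (mean of per-image
ulna and radius Dice on argmax masks) is selected, ties to the
earliest epoch.

Augmentation draws, per sample per epoch, a translation in ±60 px,
scaling in [0.9, 1.1] per axis, rotation in ±20°, all applied as one
composed affine (rotate about the center, then scale, then translate;
bilinear for the image, nearest-neighbor for labels, background fill),
plus an image-only gamma in [0.5, 1.5]. Uniform sampling over each
interval is the maximum-entropy reading of stated ranges; the low- and
high-energy images of a subject are augmented independently.

Cross-validation is subject-level: subjects are shuffled by seed and
cut into five near-equal folds; rotation r tests on fold r, validates
on fold (r+1) mod 5 and trains on the remaining three (the 3/1/1
split). Both images of a subject always share a partition, so no
subject leaks between train and test.

## Evaluation and comparison

Per image and class, Dice = 2|P∩G|/(|P|+|G|) and Jaccard = |P∩G|/|P∪G|
are computed on hard argmax masks; they satisfy J = D/(2−D) exactly.
When a class is absent from both masks the undefined 0/0 is scored 1.0
(absent-class agreement); `strict_empty` drops such records instead.
Tables report mean ± sample (n−1) standard deviation across images.

Two methods are compared by a paired one-tailed t-test on per-image
scores, paired by (subject, energy) — the finest pairing unit the
tables support — one cell per (metric, class), significance at
p < 0.05, no multiple-testing correction. The t CDF p-value is
cross-checked in tests against an exhaustive sign-flip permutation
oracle. Identically-zero differences are a degenerate cell, reported
as such rather than given an arbitrary p.

## Phantom generator

Real DEXA forearm data cannot ship with the package, so the phantom
module generates paired low/high-energy images with exact ground
truth. Each subject is two disjoint slanted cylindrical capsules —
the radius thicker and tapered, the ulna thinner with a half-disc
distal bump standing in for the styloid process, the hardest real
sub-structure — over an elliptical soft-tissue column, rendered by
Beer–Lambert projection I = exp(−μ_soft·t_soft − μ_bone(E)·t_bone)
plus Gaussian noise, clipped to [0, 1]. Defaults μ_bone_low = 2.5,
μ_bone_high = 1.4, μ_soft = 0.3 encode the physical ordering
(low-energy bone attenuation > high-energy > soft tissue) and the
strong bone/soft-tissue contrast characteristic of DEXA; bone pixels
are therefore darker at low energy, and higher attenuation always
means a darker pixel. Geometry is jittered per subject (pose, widths,
styloid radius) from an RNG stream keyed by (seed, subject index), so
datasets are bit-reproducible and extensible without reshuffling.

The phantoms emulate class imbalance (background ≥ 60 %, each bone
1–20 % of the frame), dual-energy contrast, pose variation and noise.
They do not emulate soft-tissue texture, scatter, beam hardening,
uneven exposure, or anatomical shape diversity beyond the jittered
primitives — so passing phantom tests demonstrates that the pipeline
is correct and trainable, not that clinical-grade accuracy transfers
to real radiographs.

## Desk-scale problem sizes

The package's self-contained runs use reduced sizes chosen once as a
single-CPU working point: a 128×96 canvas (divisible by 16; 768×576
mimics the study geometry), `base_channels=8`, and two standard
exercises — an overfit sanity run (8 noise-free phantom images, 150
epochs, no augmentation; training Dice reaches ≥0.95 for both bones
and the 10-epoch moving average of the loss is non-increasing) and an
ablation harness (40 phantom subjects, one CV rotation, 12 epochs per
model, no augmentation, matching the ablation protocol of training
both encoder variants identically). At this scale the comparison
harness demonstrates validity of the statistics, not the full-scale
ordering of the two variants: with only a dozen epochs the smaller
plain-U-Net encoder typically converges faster than the
parameter-heavier residual encoder, so the one-tailed p-values land
near 1 on phantoms. No conclusion about the full protocol follows
from either direction.

## Known limitations

* The NumPy engine is single-threaded except for BLAS matmuls; it is
  sized for desk-scale experiments, not 500-epoch full-resolution
  training.
* Batch statistics make training-mode forward passes batch-size
  dependent; evaluation always uses running statistics.
* The phantom's smooth geometry makes segmentation easier than
  clinical data; reported phantom Dice values are not comparable to
  values on real DEXA images.
* Only grayscale PNG/TIFF input is supported; no DICOM.
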