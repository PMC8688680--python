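# dexaseg

Automatic segmentation of the two forearm bones — **ulna** and
**radius** — in dual-energy X-ray (DEXA) forearm radiographs, the
image-analysis step that precedes bone mineral density measurement for
osteoporosis diagnosis. The package is aimed at medical-imaging
researchers who want a self-contained, CPU-only, fully reproducible
implementation of the residual U-Net approach to this problem: the
network, the class-imbalance-aware loss, the training protocol,
subject-level cross-validation, per-class evaluation metrics, and the
paired statistical comparison between methods — all exercisable
end-to-end on a built-in synthetic dual-energy phantom generator, so no
clinical data are required.

## The method

Pixels are classified into background (0), ulna (1) and radius (2) by
an encoder–decoder network. The encoder stacks five residual blocks
(each two residual units: 3×3 conv–BN–ReLU–3×3 conv–BN on the main
path, a 1×1 conv–BN projection shortcut, add, ReLU — four 3×3 and two
1×1 convolutions per block) separated by four 2×2 max-poolings, with
channel widths 32→64→128→256→512. The decoder mirrors it with four
2×2 transposed convolutions, skip concatenations with the encoder
features, and two-convolution blocks, ending in a 1×1 convolution to 3
classes and a per-pixel softmax. A plain-U-Net baseline (identical but
with non-residual encoder blocks) is provided for ablation.

Training minimizes the Generalized Dice loss over softmax
probabilities P against one-hot truth G,

$$L = 1 - \frac{2\sum_c w_c \sum_m P_{cm}G_{cm}}{\sum_c w_c \sum_m (P_{cm}^2 + G_{cm}^2)},\qquad w_c = \frac{1}{(\sum_m G_{cm})^2 + \varepsilon},$$

whose inverse-squared-volume weights keep the small bone classes from
being swamped by background. The protocol is Adam, learning rate
1e−3 × 0.98^⌊epoch/5⌋, batch 16, per-epoch shuffling, affine+gamma
augmentation, and best-validation-Dice checkpoint selection under
subject-level five-fold cross-validation (3 folds train / 1 validation
/ 1 test). Evaluation reports per-class Dice 2|P∩G|/(|P|+|G|) and
Jaccard |P∩G|/|P∪G| as mean ± SD across images, and methods are
compared with a one-tailed paired t-test per (metric, class) cell at
p < 0.05.

Everything runs on plain NumPy/SciPy: `dexaseg.nn` is a compact CNN
engine with hand-written, finite-difference-verified backpropagation
and Adam — no GPU framework needed.

## Worked example

Train the residual segmenter on noise-free phantoms and evaluate it
(about two minutes on one CPU):

```python
import numpy as np
from dexaseg import PhantomParams, ResUNetSegmenter
from dexaseg.phantom import generate_arrays
from dexaseg.metrics import evaluate_pair, aggregate

params = PhantomParams(n_subjects=4, seed=0, noise_sigma=0.0)
X, y, subjects, energies = generate_arrays(params)   # 8 images, 128x96

model = ResUNetSegmenter(base_channels=8, epochs=150, augment=False, random_state=0)
model.fit(X, y)
print(f"mean ulna+radius Dice on training images: {model.score(X, y):.4f}")

records = []
for pred, truth, sid, energy in zip(model.predict(X), y, subjects, energies):
    records.extend(evaluate_pair(pred, truth, sid, energy))
print(aggregate(records).to_string(index=False))
```

which prints

```
mean ulna+radius Dice on training images: 0.9931
 class  metric     mean      std       formatted
radius    dice 0.988933 0.003833 0.9889 ± 0.0038
radius jaccard 0.978134 0.007496 0.9781 ± 0.0075
  ulna    dice 0.997329 0.002198 0.9973 ± 0.0022
  ulna jaccard 0.994681 0.004369 0.9947 ± 0.0044
```

i.e. the network memorizes the eight phantom images almost perfectly —
Dice near 1 for both bones with the ulna (including its styloid-process
bump) slightly easier than the radius boundary at this scale. Phantom
scores say nothing about clinical accuracy; see `docs/methods.md` for
what the phantoms do and do not emulate.

The same workflow is available from the shell:

```bash
dexaseg generate-phantoms --n-subjects 10 --out data/ --seed 1
dexaseg train --manifest data/manifest.csv --out run/ --epochs 20 --base-channels 8
dexaseg audit --base-channels 32        # JSON layer census of the network
dexaseg compare --a run_a/test_metrics.csv --b run_b/test_metrics.csv --direction a_gt_b
```

`dexaseg audit` reports, for the default build: 5 residual blocks,
4 max-poolings, 4 decoder conv-blocks, 4 transposed convolutions,
4 skip connections, four 3×3 + two 1×1 convolutions per residual
block, and a head mapping 32 channels to 3 classes.

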