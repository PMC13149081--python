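# cestmix

Spatial-spectral deep learning for CEST-MRI glioma analysis: automated tumor
segmentation and noninvasive genotype prediction (IDH mutation, MGMT promoter
methylation) from multi-offset chemical exchange saturation transfer (CEST)
images, together with a synthetic multi-pool phantom that makes the whole
pipeline testable without clinical data.

## Who this is for

CEST MRI acquires a stack of saturation-weighted images at many frequency
offsets; per voxel, the normalized signal S/M0 across offsets forms a
Z-spectrum whose dips (amide protons at +3.5 ppm, relayed NOE at −3.5 ppm, a
broad semi-solid MT background, creatine near +2.0 ppm, glucose-related
exchange near +1.2 ppm) report on tissue metabolism. Gliomas and their
molecular subtypes perturb these pools, so a volume carries joint
spatial-spectral structure: morphology in-plane, metabolism along the offset
axis. This package is for researchers who want to exploit both domains at
once rather than segmenting on spatial features and then quantifying spectra
inside an ROI.

## The model

The core network is a four-stage U-Net-shaped encoder/decoder whose encoder
stages are stacks of **Mixing Blocks**. Each block runs two branches in
parallel on the layer-normalized input `x`:

* a window-based multi-head self-attention branch (W-MSA, 4×4 windows) that
  aggregates spatial context while sharing parameters across spectral
  channels, and
* a depthwise 3×3 convolution branch that filters each spectral channel
  independently.

Bi-directional interactions couple the branches: the conv branch emits a
per-channel gate `σ(W₂ GELU(W₁ GAP(c)))` applied to the attention output, and
the attention branch emits a per-pixel gate `σ(w·a)` applied to the conv
output. Gated outputs are concatenated and fused by a two-layer GELU MLP back
to the stage width, with a residual connection. Stage depths are
D = (2, 2, 4, 2) with 2× downsampling and channel doubling between stages; a
1×1-convolution softmax head emits N = 2 per-pixel class probabilities.

The same architecture serves both tasks. Segmentation trains on whole
images against expert-style binary masks with a class-weighted
cross-entropy + soft-Dice loss (weights 9:1). Genotype prediction trains on
48×48 patches extracted from tumor regions with a sliding window
(stride 12), where the overlap is

```
Overlap = (1 − stride/size) × 100%          (75% at 48/12)
```

At inference, patch-wise probability maps are cropped (crop = stride),
stitched by averaging, and summarized per patient by the probability mean
over the N ROI pixels,

```
P_mean(C) = (1/N) Σᵢ Pᵢ(C)
```

and by pixel-wise majority voting at threshold 0.5.

Because no GPU framework is assumed, the network and its training loop
(SGD with momentum, weight decay, linear-warmup + cosine-annealed learning
rate, gradient-norm clipping, early stopping) are implemented in pure numpy
with hand-derived backpropagation (`cestmix.nn`); every layer's gradient is
verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
from cestmix import PhantomConfig, generate_phantom, dice
from cestmix.models import MixBranchNetSegmenter, records_to_seg_arrays

records = generate_phantom(PhantomConfig(
    n_patients=16, image_size=64, seed=7,
    tumor_radius_range=(8.0, 13.0), noise_sigma=0.01))
train, holdout = records[:12], records[12:]

X, y = records_to_seg_arrays(train)
seg = MixBranchNetSegmenter(base_width=8, learning_rate=0.1, batch_size=8,
                            max_epochs=200, patience=150, seed=42).fit(X, y)

Xh, yh = records_to_seg_arrays(holdout)
scores = [dice(p, t) for p, t in zip(seg.predict(Xh), yh)]
print(f"held-out Dice: {np.mean(scores):.3f}")
```

This trains the reduced network (base width 8, ≈280k parameters) on 12
synthetic patients and prints

```
held-out Dice: 0.996
```

meaning the predicted tumor masks overlap the ground-truth masks almost
perfectly on the four unseen patients. The analogous genotype run
(`MixBranchNetGenotypeClassifier` + `cestmix.pipeline.predict_cohort`)
reaches 100% held-out patient-level accuracy with P_mean ≈ 0.998 on phantoms
with the default genotype effect sizes.

A command-line surface wraps the library:

```
cestmix simulate --out cohort/ --seed 1
cestmix patch-stats --mask cohort/P000_mask.nii.gz --size 48 --stride 12
cestmix train-seg --data cohort/ --out run/
cestmix infer --volumes cohort/ --seg-model run/segmentation.npz --geno-model run/idh.npz --out preds/
cestmix run --out run/   # simulate → split → train → infer → evaluate
```

## Layout

```
src/cestmix/
  phantom.py      multi-pool Lorentzian phantom, Rician noise, B0 shift
  quant.py        MTRasym (APTw) and bounded multi-pool Lorentzian fitting
  patching.py     sliding-window grids, overlap formula, crop-and-stitch
  nn/             numpy layers, W-MSA, Mixing Block, the full network
  models.py       sklearn-style estimators for both tasks + spectral MLP baseline
  training.py     losses, LR schedule, early stopping, patient-level splits
  pipeline.py     two-stage inference, P_mean, majority vote
  evaluation.py   Dice/IoU/ACC/SEN/SPE/F1/AUC, bootstrap CIs, Wilcoxon, Holm, CoV
  io.py, cli.py   NIfTI + sidecar I/O, checkpoints, command-line surface
docs/methods.md   model assumptions, parameter choices, limitations
```
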