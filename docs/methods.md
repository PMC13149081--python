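# Methods

## Phantom forward model

Each voxel's Z-spectrum is a flat baseline minus a sum of Lorentzian
saturation pools,

    Z(Δω) = 1 − Σ_p A_p (Γ_p/2)² / ((Γ_p/2)² + (Δω − δ_p)²),

with amplitude `A` (fraction of M0), center `δ` and FWHM `Γ` in ppm. This is
an end-effect model: saturation-pulse physics (power, duration, exchange
rates, Bloch–McConnell dynamics) is deliberately not simulated; the pools
are placed where the corresponding resonances appear in vivo (water 0,
amide +3.5, relayed NOE −3.5, broad MT centered −1, creatine +2.0,
glucose-related +1.2 ppm). The acquisition grid defaults to 41 evenly spaced
offsets from −5.0 to +5.0 ppm (0.25 ppm spacing) plus a saturation-free M0
reference nominally at 100 ppm; spectra are stored as S/M0.

Tissue presets (package constants, configuration rather than claims):

| pool    | gray matter | white matter | tumor (base) |
|---------|------------:|-------------:|-------------:|
| water   | 0.80        | 0.78         | 0.85         |
| MT      | 0.055       | 0.090        | 0.070        |
| APT     | 0.030       | 0.034        | 0.060        |
| NOE     | 0.040       | 0.070        | 0.035        |
| Cr      | 0.008       | 0.007        | 0.012        |
| glucose | 0.006       | 0.005        | 0.012        |

White matter carries the strongest NOE (myelin) and MT background; the tumor
water pool is deepened to reflect elevated free-water content (edema), which
gives every genotype combination a clear direct-saturation contrast against
both normal tissues — the phantom is built to be an *easy*, high-contrast
segmentation target so that recovery failures indicate implementation
defects rather than borderline task difficulty. Amplitude sums are validated
to stay below 1 at every grid offset.

Genotype effects are additive shifts on the tumor APT/NOE amplitudes:
IDH-mutant +0.030 APT / −0.010 NOE, MGMT-methylated −0.015 APT / +0.005 NOE.
The IDH direction (mutant = higher APT) follows one reading of the glioma
CEST literature; published evidence is mixed, so the direction is a single
config flag (`idh_direction`) rather than a hard-coded assumption. Both
labels are assigned independently and balanced exactly, so each task sees
the other's shift as biological nuisance variability — which makes the MGMT
task (smaller effect, confounded by the larger IDH shift) intrinsically
harder, mirroring the real ordering of task difficulty.

Geometry: a brain ellipse split into a white-matter core and gray-matter
ring; tumors are thresholded smoothed-noise blobs around a random in-brain
center, reduced to their largest connected component. Degradations:
per-channel Rician noise `sqrt((v+n₁)² + n₂²)` (no inter-offset noise
correlation), and B0 inhomogeneity as a smooth random field `f` under the
convention that the observed spectrum is the stored spectrum sampled at
`offset − f` (linear interpolation, edge clamping flagged per pixel). The
whole cohort is a pure function of its config including the seed.

## Quantification

MTRasym(Δω) = Z(−Δω) − Z(+Δω), with linear interpolation for off-grid
targets (the default grid is dense); APTw is MTRasym at 3.5 ppm. The
multi-pool Lorentzian fit is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) on `1 − Z`:
amplitudes in [0, 1), widths in [0.1, 60] ppm, centers fixed at nominal pool
positions except water (±0.3 ppm), tolerances 1e-14 so a noiseless spectrum
is recovered essentially to machine precision. Fixed-center fitting is the
most stable choice at this scale; these features exist as inputs for
external classifiers and for the forward/inverse consistency check against
the phantom.

## Network

Channels-last numpy implementation with hand-derived backprop for every
layer (dense/1×1 conv, full and depthwise 3×3 conv via im2col/shift
accumulation, LayerNorm over channels, exact GELU, sigmoid, softmax,
space-to-depth down/up-sampling equivalent to 2×2 stride-2 (transposed)
convolutions, and windowed multi-head attention). Gradients are validated
against central finite differences in the test suite.

Design points the source description left open, resolved as follows:

* **Widths.** Stage widths are `(w, 2w, 4w, 8w)` from a configurable base
  width (default 32; the recovery experiments use 8). A literal
  `(2C, 4C, 8C, 16C)` channel-expansion mode exists for fidelity runs; the
  base-width form avoids awkward head divisibility at C = 41.
* **Heads / FFN.** Heads per stage default to `max(1, width/16)`; FFN
  expansion ratio 4 — the usual hybrid-block conventions.
* **Mixing Blocks in the encoder only**; the decoder uses plain
  double-convolution blocks (3×3 conv → LayerNorm → GELU, twice) with skip
  concatenation. A placement switch puts single Mixing Blocks in the decoder
  for the alternate reading.
* **Interaction direction**: conv → channel gate → attention output and
  attention → spatial gate → conv output, with a reversal switch. The
  channel gate uses a 4× bottleneck MLP after global average pooling.
* **Residual connections** wrap each Mixing Block — not stated in the
  architecture description but required for trainability at depth 10.
* **Window padding.** Attention pads its input with zeros to a window
  multiple and crops the output, so any input divisible by 8 works at all
  four resolutions.
* Ablation variants (attention-only, conv-only, no-interaction) are
  config switches over the same constructor; the parameter census orders
  conv-only < no-interaction ≤ full.

## Training

SGD with momentum 0.9 and weight decay 1e-4, class-weighted binary
cross-entropy (computed on the foreground softmax probability, equivalent to
two-class cross-entropy) plus a global soft-Dice term (α = β = 1 for
segmentation; the Dice term is dropped for genotype patches, where it is an
overlap objective without meaning), linear warmup over 10 epochs
(factor 0.001) then cosine annealing to 0.001 of the base rate, early
stopping on the validation metric with patience 30 and minimum improvement
1e-5, rotation/flip augmentation, inverse-class-frequency weights for
genotype, and patient-level stratified splits (15% holdout + k-fold by
largest-remainder apportionment and per-class round-robin dealing; seed 42).
`TrainConfig` defaults carry the full-scale protocol (base rate 1e-4, batch
8/128, 500 epochs).

Two additions stabilize the pure-numpy optimizer at reduced scale: per-offset
channel z-scoring of the input stack (fitted on the training set and stored
on the estimator) and global gradient-norm clipping at 1.0. Without the
channel-wise scaling the small APT/NOE amplitude differences are buried in
the water-dip variance and SGD converges to a constant map. The reduced-scale
runs also use a larger base learning rate (0.1 segmentation / 0.05 genotype):
at a few hundred optimizer steps the full-scale 1e-4 cannot leave the
initialization basin.

For genotype patches, pixels outside the tumor mask are excluded from the
loss and from P_mean (and patches with no ROI pixel are dropped): the
label is a patient-level attribute, so background pixels carry no class
information. Majority voting uses foreground probability ≥ 0.5 per pixel and
a strict-majority patient rule; an exact half ties to 0, and exact 0.5/0.5
segmentation ties break to background. Empty predicted segmentations exclude
the patient from genotype metrics with an explicit tally.

## Statistics

Dice, IoU, accuracy, sensitivity, specificity, positive-class F1 (class 1 =
mutant/methylated), and rank-based AUC (Mann–Whitney with midrank ties).
Both-empty masks score Dice = IoU = 1 by convention. Bootstrap CIs are
stratified percentile intervals at the patient level (B = 2000, strata =
genotype class for prediction tasks, unstratified for segmentation). The
paired Wilcoxon signed-rank test drops zero differences, midranks ties, and
uses the exact sign-flip null (computed by convolution over doubled
midranks, identical to full 2ⁿ enumeration) up to 25 informative pairs,
switching to the normal approximation with continuity and tie corrections
above. Holm–Bonferroni step-down adjustment preserves input order. CoV is
100·SD/mean with the n−1 SD.

## Problem sizes and what the tests show

The recovery experiments use 64×64 phantoms (12 train / 4 held out) for
segmentation and 96×96 phantoms with large tumors (24 / 6) for genotype, a
base width of 8, 200 and 80 epochs respectively — sizes chosen so the whole
cycle runs comfortably on a single CPU while leaving the architecture,
losses, pipeline and statistics identical to the full-scale configuration.
The phantom emulates offset-resolved contrast, tissue heterogeneity,
genotype-dependent spectral shifts, Rician noise and B0 displacement; it
does **not** emulate partial-volume mixtures, motion, B1 variation,
inter-patient anatomical variability, coil profiles, or the preprocessing
chain (registration, denoising, B0 correction) applied to clinical data.
Passing recovery tests therefore demonstrates that the implementation
learns and propagates the intended spatial-spectral signal — not that the
method attains any particular performance on clinical cohorts.

## Known limitations

* The numpy network is single-threaded and float32; full-scale (240×240,
  base width 32) training is supported but slow.
* Exact Wilcoxon enumeration is limited to 25 informative pairs by the
  convolution length; beyond that the normal approximation is standard but
  approximate.
* The Lorentzian fit fixes non-water centers; strongly shifted pools (large
  uncorrected B0) bias amplitudes rather than moving centers.
* Tumor blobs are single connected components on one slice; multifocal or
  non-mass-like lesions are out of scope.
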