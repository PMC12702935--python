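# Methods

## The model

`iap_transunet` implements a U-shaped hybrid segmentation network for 2-D
images with per-pixel class labels. The design follows the TransUNet
lineage — a CNN encoder whose deepest feature map is tokenised and
processed by a transformer, a cascaded up-sampling decoder with skip
connections, and a 3×3 convolutional segmentation head — extended by three
structural refinements that can be toggled independently:

- **ECA** (efficient channel attention): each channel is re-weighted by a
  sigmoid gate computed from the global-average-pooled channel descriptor
  through a k-tap 1-d convolution, with

      k = |log2(C)/γ + b/γ|_odd ,   γ = 2, b = 1.

  `|t|_odd` is resolved by flooring and rounding up to the next odd
  integer, never below 1; this is the single tie-break point (e.g. C = 8,
  where t = 2 is equidistant from 1 and 3, resolves to 3) and reproduces
  k = 5 for C ∈ {256, 512, 768, 1024}. The 1-d convolution is weights-only
  with zero "same" padding of (k−1)/2. ECA gates follow the stem, each of
  the four residual stages, and each decoder convolution block (one gate
  per stage, not one per individual convolution — per-layer placement
  inside a separable convolution would gate between its two stages, which
  the block structure does not call for). `eca_placement="block"` moves
  the encoder gates to after every residual block for the stricter
  reading of embedding attention throughout the CNN.
- **CBAM-ASPP** bottleneck: at the encoder/decoder junction, the token map
  is refined by atrous spatial pyramid pooling — parallel 3×3 convolutions
  at dilation rates [1, 2, 4, 8], channel-concatenated and fused by a 1×1
  convolution with batch norm and ReLU — followed by CBAM: a channel gate
  σ(MLP(F_avg) + MLP(F_max)) with one shared two-layer perceptron
  (reduction 16, floored at one hidden unit), then a spatial gate from a
  7×7 convolution over the concatenated channel-wise mean and max maps.
  Channel-before-spatial is the default order, matching the defining formulas and
  the original CBAM design; `cbam_spatial_first=True` gives the opposite
  reading of the prose description. No image-level pooling branch is
  included by default (`global_pool_branch` adds the classic DeepLab one).
- **Separable decoder**: decoder 3×3 convolutions are replaced by
  depthwise-separable convolutions (per-channel Dk×Dk stage, then 1×1
  cross-channel stage, no nonlinearity between, biases off before
  normalisation), which is exactly a standard convolution with the rank-1
  kernel K[n,m] = P[n,m]·D[m]. The cost model for a stride-1 square map of
  side Df is Dk²·M·N·Df² (standard) vs Dk²·M·Df² + M·N·Df² (separable),
  quotient 1/N + 1/Dk². The depthwise group count of the first decoder
  convolution is exposed (`first_decoder_groups`; default full depthwise)
  for the group-number ablation.

All eight on/off combinations of the three toggles instantiate the
structural ablation grid, from the plain baseline (all off) to the full
model (all on).

## Architectural choices the sources leave open

- **Encoder presets.** The text dimensioning (embedding 512, MLP 2048)
  conflicts with a 12-head split: 512/12 is not integral. The
  `paper-text` preset therefore runs 8 heads (d_head = 64, the standard
  per-head width); the `wide` preset is the ViT-Base-like 768/3072 with
  12 heads. Both presets are first-class and the test suite covers both.
- **CNN pyramid.** ResNet-50 stage layout (3/4/6/3 bottleneck blocks).
  Down-sampling happens in the stem (7×7, stride 2) and in the stride-2
  first block of stages 1–3; stage 4 runs at stride 1 so the deepest map
  is at 1/16 — the token grid of a 16-pixel patch — with skips taken at
  1/2 (stem), 1/4 (stage 1) and 1/8 (stage 2). No max-pool stem: strided
  residual blocks do the same job with one fewer special case. Batch norm
  by default, group norm by flag. No pretrained weights: initialisation
  is He-uniform, fully determined by the build seed.
- **Transformer.** Pre-norm layer arrangement with a closing layer norm
  (the standard ViT form; post-norm by flag), d_k = d_v = dim/heads,
  sinusoidal positional encoding as the default with learned embeddings
  by option, dropout 0.1 by default and 0 in all tests and desk presets.
- **Decoder.** Four stages of bilinear 2× up-sampling (half-pixel
  convention), skip concatenation where a skip exists, and a 3×3
  convolution block; bilinear-then-conv rather than transposed
  convolution avoids checkerboard artifacts. Stage widths follow the
  ladder (256, 128, 64, 16): the first decoder convolution maps the
  embedding to 256 at 1/16 and the stages emit 128, 64, 16, 16.
- **Width multiplier.** `width_multiplier` thins the CNN stage widths and
  the transformer dims (rounded to a multiple of the head count), in the
  spirit of MobileNet's α. It deliberately does *not* scale the decoder
  ladder: the ladder is its own explicit config field, and scaling it to
  a 4-channel full-resolution stage starves the head of capacity — at
  desk scale this showed up as slow, seed-sensitive convergence.

## Objective and metrics

Training minimises L = (L_CE + L_Dice)/2: the pixel-mean cross entropy
and the soft Dice loss 1 − mean_c (2|X_c∩Y_c| + ε)/(|X_c| + |Y_c| + ε)
with ε = 1e−5 in numerator and denominator, averaged over all classes
including background (exclusion by flag). Both are computed from logits
via a numerically stable log-softmax; a plain-NumPy probability-space
implementation of the same formulas serves as the reference path and the
two are asserted to agree.

Evaluation reports the per-class Dice coefficient 2|A∩B|/(|A|+|B|)
(both-empty → 1, single-empty → 0) and the symmetric Hausdorff distance
in pixel units between boundary point sets (8-connectivity erosion
difference; boundary and full-mask point sets give identical distances
since interior points never attain the max-min, and this is asserted on
fixtures). An empty point set makes the distance undefined: it is
reported as NaN, excluded from means and counted, never silently zero.
Aggregation is per image; a per-volume protocol for stacks of slices
carrying case identifiers is out of scope here.

## The phantom generator

`phantoms.generate_phantom` renders one background class plus 3–8 organ
classes as randomly placed, sized and oriented ellipses, by default with
a low-order (modes 2–4) Fourier perturbation of the boundary radius.
Later-drawn organs overwrite earlier ones; a placement is accepted only
if every class keeps at least 8 visible pixels, so all classes are
present in every phantom, and 100 failed attempts raise a generation
error. Per-class intensities are evenly spaced in [0.35, 0.95] over a
0.08 background with a per-phantom jitter of std 0.02; additive Gaussian
noise (σ = 0.03 by default) is applied and the image clamped to [0, 1].
Defaults: 64×64, 4 classes. With σ = 0 and zero jitter the label map is
exactly recoverable by nearest-intensity thresholding, which the tests
use to validate the generator/metric plumbing end to end.

What the generator emulates is the *statistical shape* of multi-organ
CT/MRI slices — a few compact structures of differing size, intensity and
boundary smoothness on a dark background. What it does not emulate:
imaging physics (bias fields, beam hardening, partial-volume effects),
anatomical priors on organ position, inter-slice 3-d continuity, or
class-dependent texture. Passing the desk-scale tests therefore shows the
architecture, objective and pipeline are implemented correctly and can
fit and generalise on data of this structure; it does not certify
clinical-grade accuracy on real CT/MRI.

Augmentation follows the standard protocol for this model family:
horizontal and vertical flips each with probability 0.5 and a rotation
drawn uniformly from [−10, 10] degrees — bilinear for images, nearest
neighbour for labels (which therefore can never invent a class), about
the image centre with zero padding. The draw order (h-flip, v-flip,
angle) is fixed so a seed fully determines the transform.

## Training protocol and problem sizes

The optimiser is SGD with momentum 0.9, learning rate 0.01 and coupled L2
weight decay 1e−4; the learning rate is constant by default (the lineage's
polynomial decay is available by flag). The reference protocol's batch
size 24 at 256×256 is kept as documentation; the desk preset used
throughout the tests is batch 4 at 64×64 with width multiplier 0.25,
single-channel input, dropout 0.

Problem sizes used by the test suite and the acceptance script, chosen so
the whole pipeline runs on one CPU core in minutes:

- overfit check: 4 fixed phantoms, full-batch SGD, at most 300 steps with
  early stop when the combined loss falls below 0.1 (typically ~100
  steps);
- recovery check: 200 training phantoms with augmentation, 20 epochs of
  batch 4 (1000 steps), evaluated on 50 held-out phantoms from the same
  generator;
- block oracles: random tensors up to (2, 64, 16, 16) against scipy- or
  loop-based re-implementations.

## Numerical choices

- All network arithmetic is float32; metric and reference-loss functions
  are float64.
- Sigmoid is computed in the two-branch form that never exponentiates a
  large positive argument; softmax and log-softmax subtract the row
  maximum.
- Cross entropy on probabilities clips at 1e−12 before the log; the
  logits path uses log-softmax directly.
- Batch-norm runs on batch statistics during training (momentum 0.1
  running averages for evaluation, unbiased variance in the running
  estimate); the max-reduction gradient splits evenly across ties.
- The engine's backward pass is exact reverse-mode differentiation;
  gradient correctness is pinned by finite-difference checks in the test
  suite.
- Seeds: every stochastic component (initialisation, shuffling,
  augmentation, phantom placement) draws from a `numpy` Generator derived
  from an explicit seed; model build, training run and dataset are pure
  functions of (config, seed).

## Known limitations

- CPU-only NumPy execution: throughput is adequate for desk-scale
  experiments (≈0.3 s per optimiser step on the desk preset on one core),
  not for 256×256 × batch-24 training runs.
- The per-volume evaluation protocol used for clinical CT/MRI benchmarks
  (metrics per patient volume, HD in millimetres via voxel spacing) is
  not implemented; metrics are per image in pixel units.
- `GroupNorm2d` is provided as a batch-size-independent alternative but
  the shipped defaults and all reported numbers use batch norm.
- Checkpoints store raw parameter arrays keyed by module path; renaming
  modules breaks old checkpoints.
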