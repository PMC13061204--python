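# Methods

## The model

`hacrnet` implements a single-image super-resolution CNN for 2-D MRI slices.
Given a low-resolution slice `I_LR` in [0, 1], the network predicts a x2 or
x4 super-resolved slice `I_SR`:

```
F1   = SA(F') ⊙ F',  F' = CA(F) ⊙ F,  F = PReLU(Conv3x3(I_LR))     (HAM)
F_k  = CAAM_k(F_{k-1}),  k = 1..N                                   (deep stack)
I_SR = Conv3x3(PixelShuffle(Conv3x3(Conv3x3(F_N) + F1)))            (head)
```

* **HAM (hybrid attention module).** Channel attention `CA` is a
  squeeze-style gate, `sigmoid(W2 PReLU(W1 GAP(F)))`, with reduction ratio
  `ca_reduction`; spatial attention `SA` is a single-channel sigmoid mask
  from a 1x1 reduction, a 7x7 convolution (wide receptive field — anatomy
  spans larger areas in MRI than in natural images), PReLU, and a 1x1
  projection, broadcast over channels.
* **CAAM (context-aware aggregation module).** A pre-activated residual
  block feeds a shared 3x3 convolution; its output runs in parallel through
  an MFAB and a CRAB, whose outputs are concatenated, projected back to C
  channels by a 1x1 fusion convolution, and added to the module input.
  Zeroing the fusion projection makes a CAAM an exact identity — the basis
  of several tests.
* **MFAB (multiscale feature aggregation block).** Two pre-activated
  branches (3x3→3x3 and 3x3→1x1) are summed, re-weighted by a pooled channel
  attention, and added to a 1x1 "high-frequency" path.
* **CRAB (channel retention attention block).** A squeeze-excitation-style
  gate whose bottleneck keeps a deliberately wide intermediate width
  `crab_width >= C/2` (classical SE uses ~C/16), so the pooled channel
  descriptor is never aggressively compressed: `h ⊙ mask + h` with a
  four-layer 1x1 descriptor path `C → Cw → Cw → Cw → C`.
* **Head.** One PixelShuffle stage (Conv 3x3 C→4C, shuffle x2) for scale 2;
  two cascaded stages for scale 4 (a single-stage x4 head is available via
  `cascade_upsampler=False`).

All convolutions are stride-1 with same-size zero padding and biases; all
activations are PReLU with per-channel learnable slopes (initial 0.25).

### Width calibration

The architecture's published description fixes N = 10 modules and a total of
1,674k trainable parameters but leaves the base width C, the attention
reduction ratios, and the CRAB bottleneck width open.
`model.calibrate_config` resolves them by exhaustive search: it enumerates
candidate `(C, ca_reduction, sa_reduction, crab_width)` tuples, counts
parameters through the same shape enumeration the builder uses, and returns
the candidate nearest the target (ties toward smaller C, then smaller Cw).
Over a grid of C in 32..64, ratios in {2, 3, 4, 6, 8, 16}, and every integer
Cw in [C/2, 3C/2], exactly one candidate rounds to 1,674k:

```
C = 46, ca_reduction = 2, sa_reduction = 2, crab_width = 51   → 1,674,251
```

This is frozen as `REFERENCE_CONFIG` (and the `ModelConfig` defaults).  The
small reduction ratio and the wider-than-C bottleneck are consistent with
the architecture's channel-retention rationale; ratios restricted to
multiples of 8 cannot reach the printed total at all (counts jump from
1.56M at C = 44 to 1.70M at C = 48).

### Initialization

Weights use Kaiming fan-in normal initialization with the PReLU gain, from a
seeded generator, with two standard refinements for residual SR networks:

* **near-zero fusion projections** (weights scaled by 0.01): each CAAM
  starts close to the identity, so the 10-deep residual stack does not
  amplify noise at initialization; the scale is kept nonzero so gradients
  reach both branches from the first step (exact zero would block them);
* **ICNR** for the sub-pixel convolutions: the r² sub-pixel groups share
  initial weights, so PixelShuffle starts as a nearest-neighbour upsampler
  and produces no checkerboard artifacts.

Both choices shorten the early optimization transient substantially at desk
scale and are common practice for this family of architectures.

## The numerics engine

No tensor-autodiff framework is a dependency; the package ships a compact
reverse-mode engine (`hacrnet.nn`) on numpy: a tape-recording `Tensor`, an
im2col convolution whose throughput is bounded by BLAS, PReLU/sigmoid/
pooling/PixelShuffle/concatenation primitives, and Adam with standard bias
correction.  Every operation's gradient is verified against central finite
differences in the test suite, and every block's forward pass against an
independent shift-and-multiply reference implementation.  An inference
context (`nn.no_grad`) disables tape recording, which matters at full slice
resolution where retained convolution buffers would cost gigabytes.

## Degradation protocol

LR inputs are synthesized from HR slices by a 3x3 Gaussian blur with
sigma = 1 followed by bicubic downsampling at x2 or x4; intensities are
min-max normalized to [0, 1] per volume *before* degradation.  Unstated
details resolved as package choices:

* bicubic dialect: cubic convolution kernel with a = -0.5 (Catmull-Rom),
  configurable; plain point sampling with no kernel widening on
  downscale — anti-aliasing is the blur stage's job;
* borders reflect for both blur and resampling (no dark rims at the brain
  boundary);
* normalization is per-volume (preserves inter-slice contrast), and happens
  before LR generation.

Because the dialect and border handling of the original experiments are
unknown, absolute PSNR values against *other* bicubic implementations can
differ by a few hundredths of a dB; all comparisons inside this package use
the same resampler for both the pipeline and the baseline.

## Metrics

PSNR = 10 log10(peak²/MSE) with peak = 1 on [0, 1] images (equivalent to the
8-bit (2ⁿ-1)² form after rescaling).  Identical pairs yield an infinite
sentinel, excluded from aggregates with a logged count.  SSIM uses the
canonical form with an 11x11 Gaussian window (sigma 1.5), k1 = 0.01,
k2 = 0.03, sample statistics per window, averaged over fully valid window
positions; it is cross-checked against scikit-image to 1e-6.  Evaluation is
full-slice, no border crop, grayscale.  LPIPS is exposed only as a plugin
interface (the caller supplies a pretrained feature backend and channel
weights); without a backend the metric is reported as absent, never as 0.
Aggregates are mean and sample SD across slices.

## Synthetic phantoms

`data.generate_phantom` emulates what matters to a super-resolution loop at
desk scale: piecewise-smooth tissue regions (soft-edged ellipses with
distinct mean intensities over [0.25, 0.85] on a dark background),
fine-grained band-limited texture (Gaussian-filtered white noise,
correlation length 1.2 px, amplitude 0.10 inside the foreground — MRI
parenchyma texture is fine-grained, and fine structure is exactly what
distinguishes learned SR from interpolation), a smooth multiplicative bias
field (amplitude 0.08, emulating coil inhomogeneity), and additive Gaussian
noise (SD 0.003, a high-SNR reference acquisition).  The generator is a pure
function of its config; family member k uses seed `seed + k`.

What the phantoms do **not** emulate: real anatomy (no cortical folding,
ventricles, or pathology), Rician noise statistics, k-space acquisition
artifacts, partial-volume effects, or multi-contrast relationships.  Tests
passing on phantoms therefore demonstrate that the implementation learns and
evaluates correctly, not that the architecture reaches any particular
quality on clinical data.

## Training

The L1 objective (mean absolute deviation) is optimized with Adam
(beta1 = 0.9, beta2 = 0.999, eps = 1e-8).  The `paper` profile carries the
published settings: learning rate 1e-4, batch 32 full slices, 250 epochs, no
learning-rate schedule, weight decay, gradient clipping, or augmentation.
The `desk` profile is the package's CPU-scale configuration used by the test
suite and the acceptance script: model C = 16, N = 4 at x2; 64x64 phantoms;
batch 8; learning rate 3e-3 (at a few hundred steps the published 1e-4 is an
accelerator-scale setting — Adam's per-parameter step is roughly the
learning rate, so 1e-4 cannot traverse the distance from initialization in a
desk-scale budget); step budget 400.  Model selection tracks the best
validation-set mean PSNR.  Checkpoints are npz weight blobs with a JSON
config sidecar; loading with a mismatched config reports the first
mismatched key.

Single-pair overfit sanity checks use a two-phase protocol: 1,000 steps at
the desk rate, then up to 1,000 steps at a tenth of it.  Each phase is a
plain constant-rate `fit` call (there is still no scheduler); the drop is
needed because Adam on an L1 objective oscillates with amplitude set by the
learning rate, which puts a floor of roughly the rate itself on the
achievable loss.

## Problem sizes

The suite and the acceptance script run desk-scale workloads chosen as the
package's own study conditions: 200 training + 40 held-out phantom pairs at
64x64, a few hundred optimization steps, full-resolution (256x256) passes
only where a single forward suffices.  The reference 1,674k-parameter model
is built and counted exactly but trained only at desk scale.

## Known limitations

* The engine is single-process numpy: throughput is roughly two orders of
  magnitude below a GPU framework, so published-scale training (250 epochs
  of batch-32 256² slices) is out of desk reach by design.
* FLOP/MAC figures are reported informatively under a stated convention and
  are not comparable to published totals whose convention is unknown.
* The x4 head defaults to two cascaded x2 stages; the alternative
  single-stage head changes the parameter count.
* `scale` must divide the input dimensions exactly; no implicit cropping.
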