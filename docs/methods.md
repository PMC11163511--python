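# Methods

This note records the model as implemented, the defaults and why, what
the synthetic data does and does not emulate, and the numerical and
design choices made where the design was genuinely open.

## Model

**Encoder.** A four-stage pre-activation residual network: a 7×7
stride-2 stem followed by three residual blocks, each entered through a
stride-2 convolution (no pooling anywhere), giving feature maps at
scales 1/2, 1/4, 1/8, 1/16. Residual units are bottlenecks in
GN→ReLU→conv order (kernels 1×1, 3×3, 1×1) with an identity shortcut; a
1×1 projection shortcut (applied to the pre-activated input, the
ResNetV2 convention) is used where shape changes. Group-norm group
counts must divide the channel count; presets use `min(32, channels)`.
The downsampling schedule (stem /2, then /2 per block) is a choice: it
yields the 14×14 bottleneck at 224×224 input that the token count
N = 196 presumes, the standard hybrid-CNN+ViT layout. Stage widths are
not dictated by the architecture description either; the `full` preset
uses the ResNet-50 convention (64/256/512/1024, units 3/4/6, bottleneck
expansion ×4) and `tiny` uses 8/16/32/64 with single units and
expansion ×2.

**Transformer bridge.** The deepest map is patchified (P = 1 by
default, i.e. one token per spatial position; P > 1 uses a P×P stride-P
linear projection) to D-dimensional tokens, plus a learnable 1-D
position embedding. The embedding is created for the preset's reference
grid and bilinearly interpolated when the runtime bottleneck grid
differs, so the model accepts any input size divisible by 16. L
pre-norm layers follow: `x += MSA(LN(x)); x += MLP(LN(x))` with GELU
and `mlp_ratio·D` hidden units. Attention uses the per-head scale
`1/√(D/h)`; softmax is stabilised by row-max subtraction. There is no
class token, no final LayerNorm (keeping the stack exactly the identity
at zero weights, a property the tests rely on), and dropout defaults to
0 for determinism. The bridge output *replaces* the deepest encoder
feature (mapped back to its channel count by a 3×3 conv on the token
grid) rather than being concatenated with it — the simplest reading of
"bridge between encoder and decoder". Full preset: D=768, h=12, L=12;
tiny: D=64, h=4, L=2.

**MSFF units and nested decoder.** Each fusion node is a conv block
(3×3 conv + BN + ReLU) followed by a modified Inception-ResNet stage:
branches 1×1, 1×1→3×3 and 1×1→3×3→3×3 (each conv followed by BN, no
activation inside the branches — the only ReLU is after the residual
add), concatenated and restored to the node width by a *linear* 1×1
projection so the residual add is well-typed, scaled by α ∈ [0, 1]
(default 1). Branch width defaults to `max(out_channels/2, 4)`. The
decoder is the standard UNet++ grid over the four scales: node (i, j)
for j ≥ 1, i + j ≤ 3 concatenates all previous features of its row with
the bilinearly ×2-upsampled node below-left (bilinear rather than
transposed convolution, avoiding checkerboard artifacts). There is no
deep supervision; a single 1×1 head on X[0][3] (at scale 1/2) is
bilinearly upsampled ×2 to the input resolution. With
`enable_msff=False` nodes are plain conv blocks; with
`enable_transformer=False` the bridge is absent — both arms are
structurally honest (zero parameters of the removed component).

## Compute core

The package carries its own reverse-mode autodiff engine on float32
NumPy arrays (`polypseg.nn`): a tape-recording `Tensor` with the exact
op set the model needs — broadcasting arithmetic, batched matmul,
reductions, im2col convolution, separable bilinear/nearest resampling
(whose adjoint is the transposed interpolation matrix), softmax, and
norm layers composed from primitives. Every operation is verified
against central-difference gradients in the test suite. SGD implements
`v ← μv + g; p ← p − lr(v + wd·p)`; weight decay is applied only to
convolution/linear weights, never to norm scales/shifts or biases.

## Training recipe and defaults

| parameter | default | note |
|---|---|---|
| epochs | 200 | reference recipe; tests/acceptance cap iterations instead |
| batch size | 8 | not specified by the protocol; configurable |
| base LR | 5e-3 | polynomial decay per *iteration* |
| poly power | 0.9 | the semantic-segmentation convention; the schedule name alone does not fix it |
| momentum / weight decay | 0.9 / 1e-4 | |
| λ₁, λ₂ | 0.5, 0.5 | BCE and Dice weights |
| BCE clamp ε | 1e-7 | probabilities clamped before logs |
| threshold | 0.5 | sigmoid output → binary mask |

`total_iters = epochs × batches_per_epoch` (or `max_iterations` if
smaller), and the LR hits exactly 0 at the final iteration. When no
validation set is supplied, 10 % of the training set is held out for
best-checkpoint selection (configurable; 0 disables it and the train
set itself is used). Runs are seeded end-to-end: weight init, shuffling
and augmentation derive from the seed; determinism is promised on the
same machine/library versions, not bit-exactly across platforms.

**Augmentation** (defaults): rotation uniform in ±20° with reflective
borders (avoiding black corners that would act as spurious features),
horizontal/vertical flips at p = 0.5, Gaussian blur of the image only
(p = 0.5, σ ∈ [0.1, 2.0]), then resize to the network input size
(224×224 reference). The transform names fix less than this: the flip
and blur probabilities and the blur σ range are this package's
defaults, documented rather than inferred. Geometry is shared between
image and mask; the mask is always resampled nearest-neighbour and
stays binary. Rotation is applied before resizing. Per-sample streams
are keyed by (seed, crc32(sample id), epoch) so augmentation is
independent of iteration order.

**Metrics.** Per-image Dice/IoU/precision/recall from pixel confusion
counts, then arithmetic means (the common per-image protocol on polyp
benchmarks; global pooling across pixels is the other reading and is
not used). Degenerate images: both masks empty → all metrics 1;
exactly one empty → affected ratios 0. This rewards correct negatives
without NaNs.

## Synthetic data

The generator emulates the statistics that matter for exercising the
architecture: one to three smooth foreground blobs (randomly deformed
ellipses — Fourier-perturbed radius, random aspect and orientation)
that are brighter and redder than a textured pink background, union
area fraction rejection-sampled into a configured range
(default 5–30 %), plus vignetting, low-frequency texture, pixel noise
and specular highlight distractors. Masks are the *exact* analytic
point-in-region rasterisation of the blob union, so tests can verify
them independently. Defaults (224×224, 1–3 blobs) reflect typical
single-polyp endoscopy frames; the smoke-training condition uses 8
images at 96×96.

What it does **not** emulate: real mucosal texture and vasculature,
motion blur, fluid/bubbles, instrument occlusion, flat/sessile polyps
with low contrast, inter-annotator boundary uncertainty. Passing the
learning smoke therefore shows the architecture, losses, gradients and
recipe work end-to-end — not that the tiny preset would reach
benchmark-level accuracy on clinical data.

## Numerical choices and edge cases

- Mask binarisation threshold 127 on 8-bit masks; nearest-neighbour
  mask resampling everywhere. Nearest 2×2→1×1 follows skimage's
  half-pixel mapping (picks the lower-right sample); frozen in a test
  as the contract.
- Softmax row-max subtraction; BCE clamp gradient is straight-through
  inside the clamp interval and zero outside.
- Dice loss smoothing +1 in numerator and denominator, so empty-vs-empty
  is 0 loss; it converges to `1 − Dice(counts)` as pixel count grows.
- Norm ε = 1e-5 (GN/BN/LN). BatchNorm running-stat momentum 0.1; a
  fresh BN in eval mode scales by `1/√(1+ε)`.
- Non-finite training loss aborts with the LR and batch ids.
- Checkpoints: `.npz` weights + JSON sidecar (full model config, its
  hash, seed, history); loading validates the hash.
- Problem sizes in tests and the acceptance script (tiny preset, 8–20
  synthetic images at 32–96 px, ≤300 iterations) are chosen so the
  whole suite runs on one CPU core in minutes while still training to
  mDice ≥ 0.9 on its fixtures.

## Known limitations

- CPU-only and unoptimised relative to framework implementations; the
  full preset (≈108 M parameters) builds and runs but is not intended
  for real training at this scale.
- No pretrained weights: the reference protocol initialises the bridge
  from ImageNet-pretrained ViT; here everything trains from scratch, so
  benchmark numbers from the literature are out of reach by design.
  A name-mapping import hook could be added without touching the
  architecture.
- Single-class (binary) segmentation only; no deep supervision, no
  windowed attention, no video/real-time path.
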