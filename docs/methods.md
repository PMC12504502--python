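# Methods

## The model

`mfel` implements a dual-task segmentation network for lesion images (gland
histology, dermoscopy): a **reconstruction branch** trained by self-supervision
feeds pixel-level detail into a **segmentation branch**, and both are optimized
jointly.

### Reconstruction branch

During training the input image `I` is split by its ground-truth mask `M` into
a foreground image `I_f = I ⊗ M` and a background image `I_b = I ⊗ (1 − M)`;
the split is exactly conservative (`I_f + I_b = I`). Three encoders with a
shared architecture but independent weights produce three-level feature
pyramids from `I_f`, `I_b` and `I`. At each level an **adaptive feature
modulation** block concatenates the three features on channels, global-average
pools, and passes the pooled vector through two parallel 1×1-conv streams to
emit per-channel calibration parameters `(α, β)` applied as

    F̂ = (1 + α) · F + β

to the whole-image feature. Three mirror decoders reconstruct `I_f`, `I_b` and
`I` under mean-absolute-error losses `L_f`, `L_b`, `L_s`; their sum is the
reconstruction loss `L_rec`.

The output layers of the modulation streams are **zero-initialized**, so
calibration starts as the exact identity. This matters because the mask — and
therefore the foreground/background split and the calibration inputs — exists
only at training time. At inference the whole-image encoder's pyramid passes
to the segmentation branch uncalibrated, which is exactly the `α = β = 0` case;
zero initialization keeps the training-time and inference-time feature
distributions aligned at the start of training. Running the reconstruction
decoders at test time (e.g. from a predicted mask) is deliberately not done.

### Segmentation branch

A fourth encoder (same architecture, own weights) extracts a semantic pyramid
from the image. At each level a **bi-directional fusion** block computes paired
cross-attentions between the segmentation feature and the (calibrated)
reconstruction feature:

    Attn_seg = softmax(Q_s K_rᵀ / √d),   Attn_rec = softmax(Q_r K_sᵀ / √d)

Each stream retrieves the other stream's values, the retrieval is projected by
a 1×1 conv and added residually to the stream's own feature, and the two
enhanced features are concatenated and reduced by a 1×1 conv. The √d
temperature is the numerically stabilized choice; a config flag
(`attention_scale: d`) switches to a raw `d` divisor for strict-fidelity runs.

The deepest fused feature is flattened to a row-major raster token sequence,
layer-normalized, and split into **four contiguous quarters**. One
weight-shared **selective state-space scan** runs over each quarter:
per-channel discretization step `Δ = softplus(x W_Δ + b_Δ)`, input-dependent
`B_t`, `C_t` of size `state_dim`, diagonal negative `A` (S4D-real
initialization), skip coefficient `D`, recurrence

    h_t = exp(Δ_t A) h_{t−1} + (Δ_t B_t) x_t,   y_t = C_t h_t + D x_t.

Each quarter adds a learnable `γ`-scaled residual (`γ` initialized to 1), the
quarters are re-concatenated, layer-normalized, and linearly projected back to
the channel dimension. A U-Net-style decoder over the fused pyramid ends in a
1×1 conv + logistic nonlinearity giving the per-pixel foreground probability;
predictions binarize at 0.5.

### Loss

All components combine with unit weights:

    L_rec  = L_f + L_b + L_s
    L_mask = L_bce + L_dice          (BCE + soft Dice on the probability map)
    L_total = L_rec + L_mask

L1 terms use mean reduction by default so `L_rec` and `L_mask` stay
commensurate without extra weights; `reduction: sum` is available. BCE clamps
probabilities at 1e-7; soft Dice uses ε = 1e-6.

## Architectural choices left open by the design

- **Encoder stage** = two (3×3 conv → per-channel spatial normalization →
  ReLU) blocks followed by 2×2 average-pool downsampling; three stages with
  channels (32, 64, 128) by default. Decoders mirror with bilinear 2×
  upsampling, skip concatenation from the matching level, and a 3×3 conv.
  This is the minimal U-Net-style realization of the published block diagram,
  which names no backbone.
- **Normalization** is instance-style (per channel over space) because the
  engine optimizes sample-by-sample with gradient accumulation over the
  mini-batch; it behaves identically in training and inference.
- Cross-attention is **single-head** with `d` equal to the level's channel
  count; modulation streams use hidden width equal to the channel count.
- The printed fusion equation references one undefined attention symbol and
  one never-introduced feature symbol; we resolve it as the standard
  cross-retrieval pattern (each stream's query retrieves the *other* stream's
  values, residual added to that stream's own feature), the only internally
  consistent reading of "each feature guides the other".
- The token split is over **sequence positions** (contiguous raster quarters),
  not channels; the four branches share scan weights.
- `state_dim` defaults to 16; `Δ` positivity via softplus with bias −3
  (initial step ≈ 0.05).

## Optimization regime

Adam (β₁ = 0.9, β₂ = 0.999), batch size 4, 150 epochs by default. The learning
rate ramps linearly from 1e-5 to 1e-3 over the first 5 warm-up epochs, then
cosine-anneals back to 1e-5 by the last epoch:

    lr(t) = lr_final + ½ (lr_init − lr_final)(1 + cos(π t)),

`t` the post-warm-up epoch fraction. The schedule updates once per epoch. The
warm-up length (5) and the warm-up starting rate (`lr_final`) are package
choices. No augmentation, weight decay, or gradient clipping by default; all
three are exposed in the config.

The whole network runs on a small reverse-mode autodiff engine over numpy
(`mfel.autograd`): stride-1 convolutions via im2col + BLAS matmuls (input
gradients as transposed convolutions, so no scatter-adds), dense-matrix
bilinear resampling, a fused softmax, and a sequential selective scan (the
scan only ever runs on the deepest level's tokens, where sequences are short;
the four branch quarters are batched through one scan). Training runs in
float32 — the standard precision for this model class — while the library
default for analysis ops is float64; a `precision` config switches both ways.
Everything is deterministic: one integer seed derives separate streams for
weight initialization and batch shuffling, and fixed-seed runs are bitwise
reproducible on one platform. Checkpoints carry weights, Adam moments, the
shuffle-RNG state and a config hash, making resume trajectory-preserving.

## Ablation switches

`ablation` in the config selects: `full`; `no_fiir` (reconstruction branch
disabled entirely — the segmentation branch sees only its own pyramid and
`L_rec ≡ 0`); `afm_summary` / `afm_concat` (adaptive modulation replaced by
elementwise addition / channel-concat + 1×1 conv of the three features);
`bfm_summary` / `bfm_concat` (cross-attention fusion replaced the same way for
the two streams); `no_mamba` (the state-space block bypassed with the
identity). Disabled parameters receive no gradients.

## Synthetic fixtures

`generate_fixtures(FixtureSpec(...))` emulates the statistical shape of
dermoscopy/histology data without any download: 1–2 wobbly-ellipse lesions
per image (radially perturbed ellipses), a darker lesion interior
(mean-intensity contrast 0.35) with fine texture against a smoother, brighter
background, Gaussian blending of the image across the lesion boundary
(σ = 1.5 px, emulating diffuse margins; the *mask* stays crisp), additive
Gaussian pixel noise (σ = 0.02), and optional dark curvilinear strokes
emulating hairs crossing skin lesions. Each sample draws from independent
seeded substreams, so toggling distractors or noise never changes the base
image or mask, and identical specs are bit-identical across runs.

What the fixtures do *not* emulate: natural color statistics, specular
highlights, rulers/color-calibration patches, resolution diversity, and the
intra-class variability of real lesions. Passing the convergence and harness
tests therefore demonstrates that the architecture, losses, and optimization
are implemented coherently and can fit a separable segmentation task — not
that the model reaches any particular accuracy on clinical benchmarks.

## Desk-scale problem sizes

The test suite and the acceptance script run everything on one CPU at reduced
size, as the package's own desk-scale presets: 64×64 fixtures with encoder
channels (8, 16, 32) for the convergence run (400 epochs × 2 steps = 800 Adam
steps on 8 images) and the ablation smoke runs; 32×32 with channels (4, 8, 16)
for determinism/resume checks. The full-size defaults (256×256, channels
(32, 64, 128), 150 epochs) are what the CLI uses on real datasets. Note that
cross-attention at the first pyramid level is quadratic in the flattened
spatial length; at 256×256 inputs the level-1 attention maps are large, and
CPU memory/time make the full-size configuration practical only for small
datasets.

## Numerical conventions and degenerate inputs

- Masks binarize at 0.5 after any resize; binarization is idempotent.
- Metrics on a sample with `TP = 0`: all four are 0 if any prediction or
  ground-truth foreground exists, 1 if both masks are empty (the standard
  benchmark convention; the source material is silent here).
- Dataset metrics aggregate per image and average arithmetically (the
  dermoscopy-benchmark convention); a global-pooled variant (one confusion
  matrix over all pixels) is reported alongside for transparency.
- An empty mask at load time warns but does not fail; a non-binary mask where
  a binary one is required raises.
- Attention rows are exactly stochastic up to floating-point summation;
  `softmax` subtracts the row maximum before exponentiation.

## Known limitations

- Sequential (non-parallel) scan and pure-numpy convolutions: throughput is
  desk-scale; reproducing published benchmark numbers on GLAS/ISIC/PH2 would
  require the full datasets and GPU-scale training, and is out of scope.
- Single-head attention and per-epoch (not per-step) learning-rate updates
  are fixed simplifications.
- The reconstruction branch is training-only by design; no test-time variant
  with predicted masks is provided.
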