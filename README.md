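# mfel — reconstruction-guided lesion segmentation

`mfel` is a small, self-contained implementation of a dual-task network for
binary lesion segmentation in medical images (gland histology, dermoscopy).
Segmentation networks extract high-level semantics but lose pixel-level
detail — texture, edges, boundary structure. `mfel` recovers that detail with
a **self-supervised reconstruction branch** trained jointly with the
segmentation branch:

- the ground-truth mask `M` splits the image `I` into foreground `I ⊗ M` and
  background `I ⊗ (1 − M)`; three encoders + three decoders reconstruct the
  foreground, background and whole image under L1 losses;
- an **adaptive feature modulation** block pools the three feature pyramids
  per level and emits per-channel calibration `(α, β)`, applied as
  `F̂ = (1 + α)·F + β` to the whole-image feature;
- a **bi-directional fusion** block lets the segmentation and reconstruction
  features attend to each other (`softmax(Q Kᵀ/√d)` both ways, residual
  retrieval, 1×1-conv fusion) at every pyramid level;
- the deepest fused feature runs through a **multi-branch selective
  state-space block**: the raster token sequence is split into four quarters,
  each scanned by one weight-shared selective SSM
  (`h_t = e^{ΔA} h_{t−1} + ΔB x_t`, `y_t = C h_t + D x_t`) with a γ-scaled
  residual, then re-projected;
- training minimizes `L_total = (L_f + L_b + L_s) + (L_bce + L_dice)` with
  unit weights, Adam, and a warm-up + cosine learning-rate schedule
  (1e-3 → 1e-5).

At inference no mask exists: the whole-image pyramid passes to the
segmentation branch uncalibrated (the modulation layers are zero-initialized,
so this is exactly the `α = β = 0` case the branch was initialized in).

The entire network — convolutions, cross-attention, the selective scan, Adam,
backpropagation — runs on a compact reverse-mode autodiff engine over numpy
(`mfel.autograd`); there is no deep-learning framework dependency. Everything
is seeded and bitwise reproducible, and a built-in synthetic fixture
generator produces dermoscopy-like blob lesions so the whole pipeline runs
with no external data.

## Worked example

```python
from mfel import FixtureSpec, generate_fixtures, MFEL, TrainConfig

samples = generate_fixtures(FixtureSpec(n_samples=8, size=64, seed=7))
model = MFEL(TrainConfig(epochs=40, warmup_epochs=5, batch_size=4,
                         working_size=64, stage_channels=(8, 16, 32), seed=0))
result = model.fit(samples)
print(result.summary())
metrics = result.evaluate(samples)["mean"]
print({k: round(v, 3) for k, v in metrics.items()})
```

Output of this exact snippet:

```
Dual-task lesion segmentation fit
=============================================
ablation variant            full
epochs / batch size         40 / 4
optimizer steps taken       80
working resolution          64
encoder stage channels      (8, 16, 32)
trainable parameters        139699
seed                        0
---------------------------------------------
Lf (first -> last epoch)    0.4375 -> 0.3178
Lb (first -> last epoch)    0.2538 -> 0.1580
Ls (first -> last epoch)    0.1933 -> 0.0964
Lrec (first -> last epoch)  0.8846 -> 0.5722
Lbce (first -> last epoch)  1.0416 -> 0.4150
Ldice (first -> last epoch) 0.6704 -> 0.4770
Lmask (first -> last epoch) 1.7119 -> 0.8920
Ltotal (first -> last epoch)2.5965 -> 1.4642
=============================================
{'precision': 0.754, 'recall': 1.0, 'f1': 0.856, 'iou': 0.753}
```

Every loss component falls: the three reconstruction L1 terms (`Lf`, `Lb`,
`Ls`) shrink as the branch learns pixel detail, and the mask losses (BCE +
soft Dice) drop as the segmentation head locks onto the lesions. After only
80 optimizer steps the model reaches a training IoU of ~0.75 on the eight
fixtures (recall saturates first; precision follows as boundaries tighten);
the longer convergence run in the test suite (800 steps) pushes the mean
training IoU above 0.9. Precision/recall/F1/IoU are pixel metrics per image,
averaged over images.

The same pipeline is scriptable from the shell:

```bash
mfel make-fixtures --out data --n-samples 8 --size 64 --seed 7
mfel train --data data --out run --config config.yaml
mfel evaluate --ckpt run/checkpoint.npz --data data --out eval
mfel predict  --ckpt run/checkpoint.npz --images data/images --out preds --gt data/masks
```

`predict` writes binary mask PNGs plus error overlays (missed lesion pixels
tinted green, false alarms red) when ground truth is supplied.

## Ablation variants

`TrainConfig(ablation=...)` reproduces the component-removal variants:
`no_fiir` (no reconstruction branch), `afm_summary`/`afm_concat` (modulation
replaced by addition / concat+1×1), `bfm_summary`/`bfm_concat` (cross-attention
fusion replaced the same way), `no_mamba` (state-space block bypassed). See
`docs/methods.md` for the full model description and design rationale.

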