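# polypseg

Binary segmentation of colorectal polyps in endoscopy images with a
hybrid CNN–transformer nested-UNet, implemented end-to-end in NumPy on a
small built-in reverse-mode autodiff engine.

Automatic polyp segmentation supports colonoscopy screening: polyps vary
widely in size, shape and appearance, so the architecture combines three
ideas:

- **Pre-activation residual encoder** (ResNetV2-style, group norm +
  ReLU + conv, strided convolutions instead of pooling) producing a
  feature pyramid at 1/2, 1/4, 1/8, 1/16 of the input resolution.
- **Transformer bridge**: the 1/16 bottleneck map is cut into patch
  tokens (P = 1 over a 14×14 grid at 224×224 input → N = 196 tokens)
  with a learnable position embedding and mixed by L pre-norm layers of
  multi-head self-attention, `SA(Q,K,V) = softmax(QKᵀ/√d)V`, to model
  long-range dependencies the convolutional receptive field misses.
- **Nested (UNet++) decoder of MSFF units**: a dense grid of nodes
  `X[i][j] = MSFF(concat(X[i][0..j−1], up₂(X[i+1][j−1])))` narrows the
  encoder–decoder semantic gap. Each multi-scale feature fusion (MSFF)
  unit is a conv block (3×3 conv + BN + ReLU) followed by a modified
  Inception-ResNet stage with three parallel branches (1×1; 1×1→3×3;
  1×1→3×3→3×3), residual scaling α and a final ReLU:
  `out = ReLU(x + α·Proj[b₁(x), b₂(x), b₃(x)])`, α = 1 by default.

Training minimises `L = λ₁·L_bce + λ₂·L_dice` (λ₁ = λ₂ = 0.5, Dice loss
with +1 smoothing) with momentum SGD (0.9, weight decay 1e-4) and
polynomial LR decay `5e-3·(1 − t/T)^0.9`. Evaluation reports per-image
Dice `2TP/(2TP+FP+FN)`, IoU `TP/(TP+FP+FN)`, precision and recall,
averaged over images (mDice, mIoU).

Both ablation arms of the architecture are first-class: the transformer
bridge and the MSFF stages can each be disabled, structurally removing
their parameters.

A synthetic-data module generates endoscopy-like fixtures (deformed
elliptical "polyps" on textured pink mucosa with vignetting and
specular highlights, with analytically exact masks), so the whole
pipeline trains and evaluates offline with no downloads.

## Worked example

```python
import numpy as np
from polypseg import PolypSegmenter
from polypseg.data import SyntheticConfig, generate_synthetic_dataset

pairs = generate_synthetic_dataset(
    SyntheticConfig(n_images=8, image_size=(96, 96), seed=42))
X = np.stack([p.image for p in pairs])   # (8, 96, 96, 3) uint8
y = np.stack([p.mask for p in pairs])    # (8, 96, 96) in {0, 1}

est = PolypSegmenter(preset="tiny", epochs=150, batch_size=4,
                     val_fraction=0.0, max_iterations=300, seed=1)
est.fit(X, y)
print(f"train mDice: {est.score(X, y):.3f}")
```

prints

```
train mDice: 0.965
```

i.e. after 300 iterations of the recipe the tiny preset (encoder widths
8/16/32/64, bridge D=64, L=2, h=4) segments its eight training fixtures
with mean Dice 0.965 at threshold 0.5. `est.evaluate(X, y)` returns the
full per-image report (mDice, mIoU, precision, recall);
`est.predict_proba` yields probability maps.

The same workflow is available from the shell:

```bash
polypseg gen-fixtures --n 20 --seed 1 --size 96 --out data/
polypseg train --data data/ --preset tiny --input-size 96 --epochs 50
polypseg eval --checkpoint runs/<run>/best.npz --data data/ --input-size 96
polypseg predict --checkpoint runs/<run>/best.npz --out preds/ data/images/*.png
```

`--no-transformer` and `--no-msff` select the ablation arms. Every run
directory contains the expanded YAML config, seed, CSV training log and
checkpoints, enough to replay the run.

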