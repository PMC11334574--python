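# wheatcount

Count-supervised counting of dense small objects in field images — wheat
ears in canopy photographs, grains on a tabletop — using only per-image
totals as supervision: no bounding boxes, no density maps.

The model regresses the count `Ĉ` directly from the image:

* a truncated **VGG-style backbone** (ten 3×3 convolutions, three 2×2
  max-pools) maps a 3×512×512 image to a 512×64×64 feature map `M_b`;
* **channel + spatial attention** refines it,
  `M_cb = σ(FC(maxpool_s M_b) + FC(avgpool_s M_b)) ⊙ M_b`,
  `M_f = σ(conv[maxpool_c M_cb; avgpool_c M_cb]) ⊙ M_cb`;
* a **multiscale mixer stage** slices `M_f` into 16×16, 8×8 and 4×4 tiles
  (16, 64, 256 patches), projects each tile to a token, runs N = 4
  token/channel-mixing MLP layers per scale, concatenates the 336 tokens
  and mixes again;
* a **counting head** predicts a set of K counts and averages:
  `x1 = ReLU(FC1(T_all))`, `x2 = FC2(Dropout(x1))`, `Ĉ = ReLU(mean x2)`.

Training is SGD + momentum with L1 loss and a multi-step learning-rate
schedule, checkpointing the epoch with the best validation MAE. Evaluation
reports MAE, RMSE and R² (optionally stratified at 40 objects/image), and
gradient-weighted attention maps visualise what the count responds to, per
mixer scale. A seeded synthetic field-image generator with exact count
labels makes every stage testable on a laptop — no dataset download, no
GPU; the numerical core is a small gradient-checked autodiff over NumPy.

## Worked example

```python
import numpy as np
import wheatcount as wc
from wheatcount.benchmarks import DESK_PREPROCESS, desk_synth_config, desk_train_config

# 150 synthetic ear-field images, 128 px, exact count labels
wc.generate_dataset(150, desk_synth_config(seed=3), "fields")
x, y = wc.load_arrays(wc.load_manifest("fields/manifest.csv"), DESK_PREPROCESS)
xtr, ytr, xte, yte = x[:120], y[:120], x[120:], y[120:]

model = wc.assemble_model(wc.ModelConfig.tiny(seed=1))   # 1/16-width variant
result = wc.train(model, (xtr, ytr), (xte, yte), desk_train_config(seed=11))

print(wc.evaluate(model, (xte, yte)).to_text())
print("training-mean baseline MAE:",
      round(float(np.mean(np.abs(yte - ytr.mean()))), 2))
```

A run of this script (a few minutes on one CPU) prints:

```
N = 30
MAE  = 3.25
RMSE = 4.04
R^2  = 0.78
training-mean baseline MAE: 7.28
```

The trained model's MAE of 3.25 ears against a baseline of 7.28 shows the
network is reading the images rather than predicting the average count;
R² = 0.78 means it tracks the per-image variation (the package's standard
benchmark at 200 training images does better still, around MAE 2.0–2.7). Longer scripts for data
generation, training, metrics/table arithmetic and attention overlays live
in `examples/`, and a thin CLI (`wheatcount generate|train|eval|cam`)
wraps the same API for shell use.

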