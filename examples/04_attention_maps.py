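"""Gradient-weighted attention maps for the count regressor.

Backpropagating the predicted count to a feature layer and weighting the
activations by their average gradients shows where the network "looks".
Each mixer scale is inspected separately: coarser slicings attend more
broadly than finer ones.
"""

import numpy as np
from PIL import Image

import wheatcount as wc
from wheatcount.benchmarks import DESK_PREPROCESS, desk_synth_config
from wheatcount.gradcam import compute_cam, layer_tags, overlay

sample = wc.render_field(8, desk_synth_config(5), np.random.default_rng(5))
x = wc.preprocess(sample.image, DESK_PREPROCESS)

model = wc.assemble_model(wc.ModelConfig.tiny(seed=1))
print(f"predicted count (untrained net): {model.predict(x[None]).count[0]:.2f}")

for tag in layer_tags(model):
    cam = compute_cam(model, x, tag)
    support = (cam > 0.5).mean()
    Image.fromarray(overlay(sample.image, cam, alpha=0.5)).save(
        f"attention_{tag}.png")
    print(f"{tag:9s}: cam in [{cam.min():.2f}, {cam.max():.2f}], "
          f"above-0.5 support {100 * support:.1f}% of pixels")
# The support percentages typically shrink from coarse (mpm8) to fine (mpm4)
# slicings; overlays are written alongside this script.
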