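# Methods

## The problem and the modelling idea

Counting dense small objects in field images — wheat ears in canopy
photographs, grains scattered on a table — is usually attacked with
location supervision: bounding boxes (detection) or dot annotations turned
into density maps. Both are expensive to annotate, and both degrade when
objects overlap heavily. `wheatcount` implements the count-supervised
alternative: the network is trained with nothing but the per-image total
`C` and regresses the count directly. No boxes, no density maps, and hence
no label geometry to adjust when images are resized.

The network has four stages:

1. **Backbone.** The first ten 3×3 convolutions of the classical VGG16
   layout (widths 64,64 | 128,128 | 256,256,256 | 512,512,512, ReLU after
   every convolution, no batch norm) with a 2×2 stride-2 max-pool after
   each of the first three blocks. A 3×H×W image maps to a 512-channel
   H/8 × W/8 feature map `M_b`; at the default 512×512 input this is
   512×64×64. A width multiplier scales every channel count so that a
   1/16-width variant trains in minutes on one CPU.

2. **Channel + spatial attention.** Channel attention pools `M_b` spatially
   (max and average), passes both descriptors through one shared two-layer
   bottleneck (reduction ratio r, ReLU between the layers), sums, and
   squashes with a sigmoid:

       M_c = σ(FC(maxpool_s(M_b)) + FC(avgpool_s(M_b))),   M_cb = M_c ⊙ M_b.

   Spatial attention pools `M_cb` over channels (max and average), stacks
   the two planes and convolves them with a single k×k kernel:

       M_s = σ(conv([maxpool_c(M_cb); avgpool_c(M_cb)])),  M_f = M_s ⊙ M_cb.

   Both stages multiply by sigmoid outputs, so |M_f| ≤ |M_b| elementwise —
   a property the tests assert. The module has a pass-through mode
   (`cbam: false`) for ablations. Defaults r = 16 and k = 7 follow the
   original attention-module design; the tiny variant uses r = 4 because
   its channel counts are small.

3. **Multiscale mixer perception.** `M_f` is sliced into non-overlapping
   p×p tiles at several sizes (default p = 16, 8, 4 on the 64×64 map,
   giving 16, 64 and 256 patches — `n_p = (side/p)²` always). Each branch
   flattens its tiles, projects them with an independent linear map to a
   shared embedding dimension d, and applies N mixer layers. A mixer layer
   is two pre-norm residual sublayers: token mixing (LayerNorm, transpose,
   MLP across the patch axis, transpose back, residual add) and channel
   mixing (LayerNorm, MLP across the embedding axis, residual add). Token
   mixing is equivariant to channel permutations and channel mixing to
   token permutations; both laws are property-tested. The branch token
   matrices are concatenated along the token axis, coarse to fine
   (16 + 64 + 256 = 336 tokens), and mixed again by a merge stack of N
   further mixer layers.

4. **Counting head.** The merged token matrix is flattened per image and

       x1 = ReLU(FC1(flatten(T_all))),  x2 = FC2(Dropout(x1)),
       Ĉ  = ReLU(mean(x2)),

   i.e. the head predicts a set of K counts and averages them; the terminal
   ReLU guarantees Ĉ ≥ 0 for any weights and inputs. Ground-truth counts
   are treated as real-valued targets; predictions are rounded only for
   display.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| input side | 512 px | divisible by 8 (backbone stride) and by 8·16 (coarsest slice); all images are bilinearly rescaled to it |
| slice sizes | 16, 8, 4 | three fields of view on the stride-8 map; every size must divide the feature side |
| mixer depth N | 4 | per branch and for the merge stack |
| embedding d | 512 | equals backbone channels; all branches share d so they can concatenate |
| token / channel MLP hidden | 256 / 1024 | no canonical value; chosen once, configurable |
| head FC1 hidden, K, dropout | 1024, 64, 0.5 | declared defaults |
| optimiser | SGD, momentum 0.9, lr 1e-4, batch 16, MultiStepLR | the full-scale training protocol; L1 loss for robustness to dense outlier images |

## Numerical core

No GPU framework is used: the package carries a compact tape-based
reverse-mode autodiff over NumPy (`wheatcount.nn`) with exactly the ops the
model needs — stride-1 zero-padded convolution (shifted-slice column
matrices plus BLAS, with numba-compiled loops taking over on large spatial
grids; the tests assert the two paths agree), 2×2 max pooling, linear
layers, LayerNorm, inverted dropout, sigmoid/ReLU, and the four pooling
reductions the attention stages use.
Every operator's analytic gradient is checked against central finite
differences in the test suite, and each architectural stage is additionally
checked against an independent explicit-loop oracle. Arithmetic is float32;
oracle tolerances are 1e-5 (1e-9 for the metric formulas, which are
float64).

Two initialisation choices stabilise the terminal-ReLU head: FC2 weights
are scaled by 0.05 and its bias starts at +1, so initial predictions are
small positive numbers rather than being clamped to zero (a clamped head
receives zero gradient for every sample and can never recover).
`TrainConfig.clip_norm` optionally clips the global gradient norm; the
desk-scale recipe uses 1.0 because L1-loss gradients at count scale are
large relative to a 1/16-width network.

## Synthetic data: what it emulates, what it does not

The generator is the package's substitute for field photography, built so
every stage is testable without any download.

* **ear_field** — oriented ellipses (length 24–44 px at 512, scaled with
  image size) with speckle texture on a green-brown canopy with elliptical
  clutter streaks. Counts follow a clipped, rounded Gaussian; defaults
  mean 42, sd 20, clip [0, 190], matching the per-image marginals of the
  large public wheat-head collections (their full histogram is not
  published, so sd is a free emulation parameter).
* **grain_scatter** — small kernels on a plain or gray-striped background;
  counts mean 40, sd 10, clip [11, 68], with explicit zero-count
  background images as negative samples.

Labels are exact by construction (the label is the number of instances the
renderer actually placed), placement rejects candidates overlapping more
than an `occlusion` fraction (default 0.3; at 0 the one-pixel-dilated
occupancy test guarantees instances are disjoint connected components),
and generation is a pure function of (config, seed). Instance positions go
to a debug sidecar that no model code reads, preserving the count-only
premise. The images are deliberately not photorealistic: no perspective,
growth stages, illumination fields or soil texture. Passing tests
therefore demonstrate that the architecture, optimisation and evaluation
machinery work end to end on images with the right statistical skeleton
(dense, small, variable-count, cluttered) — they say nothing about
accuracy on real field photographs.

## Desk-scale benchmarks

Real-data training of the full model is a multi-hour GPU job; the
package's own acceptance surface is a desk-scale protocol chosen once:

* **Data.** 128 px ear-field images, counts ~ clipped N(20, 8²) in
  [0, 45]; 200 training and 50 held-out images (the overfit check uses 8).
  Inputs are centred with mean = std = 0.5 rather than the ImageNet
  statistics, since these runs are from scratch.
* **Model.** `ModelConfig.tiny()`: width multiplier 1/16, slices (8, 4),
  d = 64, N = 2, head 256/K=16, attention reduction 4.
* **Recipe.** SGD lr 0.01, momentum 0.9, batch 16, 32 epochs, MultiStepLR
  milestones at 3/4 and 15/16 of the run (24, 30) with γ = 0.1,
  gradient-norm clip 1.0. Shorter schedules learn on most seeds but
  occasionally stall near the constant-mean predictor before escaping; the
  32-epoch schedule escapes reliably. The held-out set doubles as the
  validation set for best-epoch selection, a simplification this benchmark
  accepts and states.
* **Checks.** (a) With dropout disabled the model memorises the 8 images:
  final training L1 far below 10% of the first epoch's. (b) Trained per
  the recipe, the median held-out MAE over three seeds beats the
  predict-the-training-mean baseline by well over 30% (typical runs:
  baseline ≈ 5.6–6.7, model ≈ 1.8–2.4, improvements around 60–66%).
  Training is stochastic, so the benchmark is defined as a 3-seed median.

## Attention visualisation

Gradient-weighted activation maps are adapted to regression: the scalar
whose gradients are propagated is the predicted count itself. For a tagged
layer with activations A_k, channel weights are the spatially averaged
gradients ∂Ĉ/∂A_k and the map is ReLU(Σ_k w_k A_k), bilinearly upsampled
and min-max normalised to [0, 1] (all-zero maps stay zero rather than
dividing by zero). Mixer-branch token matrices are reshaped to their
(side/p)×(side/p) grid first so each scale is visualisable; on isolated
objects the coarse branch's above-threshold support is at least the fine
branch's, asserted as a ranked-area property on seeded fixtures.

## Degenerate inputs and tie-breaks

* `R²` follows its definition literally, may be negative, and raises on
  constant true counts instead of returning NaN; an empty density stratum
  is omitted from stratified reports rather than reported as NaN.
* Box-annotation strings reduce to counts only; the `no_box` sentinel and
  empty strings mean zero, malformed tokens raise naming the offender.
* Slicing rejects sizes that do not divide the feature side at build time;
  the renderer raises a capacity error when a requested count cannot be
  packed under the overlap limit.
* Max-pool and channel/spatial max attention break ties by first index
  (argmax), matching the loop oracles.
* Display rounding is half-up to 2 decimals for metrics and averages, 1
  for percentages; raw values are kept internally.

## Known limitations

* CPU-only: the full 512-px model runs forward in tens of seconds per
  image and is not practically trainable here; training-protocol claims at
  full scale are therefore untested beyond geometry and gradient checks.
* The synthetic renderer's realism gap (above) bounds what the benchmarks
  can establish about field performance.
* Several hidden dimensions (mixer MLP widths, head sizes) have no
  canonical published values; the defaults here are declared choices, so
  parameter counts are not directly comparable with other implementations
  of the same architecture family.
* Pretrained backbone weights can be loaded from an `.npz` checkpoint but
  no download or conversion tooling is included.
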