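# Methods

This document states the model behind `ssimcut`, the conventions every
computation uses, and the limits of what the package claims. Every empirical
number cited here is recomputed by the test suite or by
`scripts/acceptance.py`; nothing is hard-coded.

## Problem and model

Given a convolutional classifier with `n` convolutional layers (ordered by
depth) and an input image, we ask: *after a short amount of training, how many
of those layers are learning features the earlier layers do not already
express?* The premise is that a layer which has learned something new "looks
at" different image structure than its predecessors, and that this is visible
in gradient-based visualizations of the layer.

### Guided backpropagation

For layer `l` with forward activations `f_l`, guided backpropagation (GBP)
propagates a backward signal `R` from the layer of interest to the input,
applying at every rectifier

```
R_l = (f_l > 0) · (R_{l+1} > 0) · R_{l+1}
```

i.e. the signal survives only where the forward activation was positive *and*
the incoming backward signal is positive. The backward pass is seeded at the
chosen convolution's rectified output:

* `seed_mode="ones"` (default) — an all-ones seed, visualizing the layer as a
  whole. This is the mode the cut-curve analysis uses, because the analysis
  is about the layer's collective receptive behavior, not a single feature.
* `seed_mode="max_channel"` — seeds only the most strongly activated feature
  map, for inspecting individual features.

If a convolution has batch normalization between it and its rectifier, the
seed point is the rectifier output (the batch-norm is part of the layer's
forward computation).

**Rendering.** The input-space gradient `g` is mapped to an image by
`g / (std(g) + 1e−8) · 0.1 + 0.5`, clipped to `[0, 1]`. Zero gradient renders
as uniform mid-gray 0.5: gray regions are regions of the image that do not
drive the layer. The scaling is global per visualization, so the mapping is
monotone in gradient magnitude and scale-invariant.

### SSIM between visualizations

Pairs of layer visualizations are compared with the structural similarity
index using fixed conventions: 7×7 uniform (non-Gaussian) windows, sample
covariance, `K1 = 0.01`, `K2 = 0.03`, `data_range = 1.0`. RGB images are
scored per channel and averaged (`channel_mode="per_channel_mean"`, default);
a `"luminance"` mode converting to gray first is also available. All pairwise
scores form the symmetric matrix `S` with unit diagonal and entries in
`[−1, 1]`; these invariants are validated (tolerance `1e−9`) whenever a
matrix is produced inside the analysis.

### The cut curve

For a cut position `k ∈ {1, …, n−1}`,

```
C_k = (1 / (k (n − k))) · Σ_{i ≤ k} Σ_{j > k} s_ij
```

is the mean similarity across the cut. An equivalent row-sum form, with
`M_i = Σ_j s_ij`,

```
C_k = (Σ_{i ≤ k} M_i − Σ_{i ≤ k} Σ_{j ≤ k} s_ij) / (k (n − k))
```

is implemented separately (`cut_value_rowsum`) and held to agree with the
double sum to `1e−12` by the acceptance suite (measured `~4e−16`). The first
difference `ΔC_k = C_{k+1} − C_k` quantifies saturation; the *flat-condition
residual* `r_k = M_{k+1} − 2 Σ_{i ≤ k+1} s_{i,k+1}` is exposed as a
diagnostic — near-zero `r_k` means layer `k+1` is as similar to the layers
before it as after it, the regime where the curve is locally flat. It is
approximate (the derivation ignores the prefactor's variation in `k`) and is
never used for decisions.

Curves from several images are averaged pointwise (`mean_cut_curve`); the
default sampling protocol is one random test-split image per class
(`SSIMCutAnalysis.from_dataset`).

### Elbow detection and verdicts

`recommend_depth` evaluates two criteria and always reports both:

* **chord_distance** (default) — the `k` maximizing the absolute
  perpendicular distance from `(k, C_k)` to the chord joining the curve's
  endpoints. Ties break toward smaller `k`.
* **delta_threshold** — the smallest `k` with `ΔC_k < τ · max_j ΔC_j`,
  `τ = 0.1`. Because it takes the *first* difference below threshold, an
  early local dip in the curve can trigger it well before the true knee;
  this is why it is reported alongside rather than used as the default.

Verdicts: `degenerate` if the curve's range is below `1e−9` (e.g. an
untrained or constant model), `still_rising` if no difference falls below the
threshold (every extra layer still adds dissimilar features — consider deeper
candidates), otherwise `depth_sufficient` with `k*` from the selected method.
A recommendation requires `n ≥ 4`.

On planted two-block similarity matrices (within-block similarity 0.9, cross
0.2, symmetric Gaussian noise with sd 0.05, `n ∈ {10, 20, 30}`), the
recommendation recovers the planted boundary in ≥ 95% of 200 seeded trials
(measured 199/200 in the test suite, 200/200 in the acceptance script).
Boundaries are planted in the central half of positions `[n/4, 3n/4]`; a cut
at the extreme edge is not a meaningful depth recommendation, and the chord
criterion is geometrically biased away from the endpoints of the curve.

## The CNN engine

No deep-learning framework is required: models run on a compact NumPy layer
graph (`ssimcut.nn`) with exact, explicitly written forward and backward
passes — 3×3 same-padding convolution (im2col), batch normalization, ReLU
(with the guided mode above), 2×2 max pooling (gradient split among tied
maxima), global average pooling, a dense head, and residual addition.
Correctness is held to finite-difference gradient checks in the test suite.
Training uses Adam (learning rate `1e−3`), minibatch 16, softmax
cross-entropy, and one extra augmented batch per epoch (flips, zoom, shear).

Two seeded, deterministic model families are provided:

* `shallow` — a plain conv–BN–ReLU stack of `conv_layers ≥ 2` layers, widths
  8→16→32, pooling after every second convolution while the map is larger
  than 8×8.
* `residual` — a stem plus `block_count − 1` residual groups
  (conv–BN–ReLU–conv–BN with identity or 1×1-projection shortcut, ReLU after
  the merge), emulating block-truncated residual classifiers. Projection
  convolutions are not counted toward depth by default.

**Batch-norm momentum.** Running moments use momentum 0.5 rather than the
common 0.9/0.99. The workflow evaluates and visualizes models after a single
short epoch (~16 minibatches on the default dataset); slow-adapting running
statistics still reflect initialization at that point and collapse
eval-mode predictions even when train-mode accuracy is high. With momentum
0.5 the statistics converge within the first epoch. GBP always runs in
inference mode, so its batch-norm backward is the plain affine gradient with
the trained scale.

## Synthetic data

Real plant datasets are large, external, and slow to train on; the package
ships a generator whose images have the gross statistics the method relies
on: a textured soil-colored background, green rosette-shaped foreground whose
structure differs by class, smooth lighting variation, and pixel noise.

Defaults (the study conditions used by the tests and acceptance script):
3 classes × 100 images at 64×64, `background_mode="lighting_patches"` (a
smooth multiplicative low-frequency field, amplitude 0.25), per-class rosette
with `3 + class_id` elliptical lobes, hue jitter 0.03, Gaussian pixel noise
sd 0.01, stratified 80/10/10 train/test/validation split. Every image carries
a ground-truth foreground mask (anti-aliased alpha > 0.5). `uniform` and
`grainy` background modes support controlled experiments.

`segment_green` reproduces the common field preprocessing step (keep pixels
with G exceeding R and B by a margin, blacken the rest); on the generator's
images it agrees with the ground-truth mask on ≥ 99% of pixels outside a
1-pixel band around the mask boundary (measured 100%).

All problem sizes in the package — 64×64 images, hundreds of images, up to
~13 convolutional layers, single-epoch training — are a deliberate
desk-scale choice so that the complete workflow (generate → train candidates
→ analyze → select) runs in minutes on one CPU while exercising the same
mathematics as a full-scale study.

## Numerical choices

* Similarity matrices are computed on the upper triangle and mirrored, so
  symmetry is exact by construction; the diagonal is set to 1.
* Cut values use vectorized block sums; acceptance holds them to `1e−12`
  against a brute-force double loop (measured `~1e−16`).
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the same seeds give bit-identical datasets, initial weights,
  training trajectories, and reports (asserted end-to-end in the tests).
* Checkpoints are `.npz` archives of all parameters and batch-norm buffers.

## Limitations

* The cut curve is a heuristic: it indicates where layer visualizations stop
  diversifying, not a guarantee of optimal depth for generalization.
* The elbow criteria disagree on curves with early dips (the worked example
  in the README shows chord `k = 6` vs delta-threshold `k = 1`); both are
  reported so disagreement is visible rather than silently resolved.
* Observations that depend on stochastic training — saturation of the deep
  model's curve tail and stability of the curve shape between epochs 1 and
  3 — are computed and logged by the acceptance suite (both held in 3 of 3
  seeds) but are not hard assertions, as they are properties of training
  dynamics rather than of the code.
* The synthetic generator captures gross statistics of plant imagery, not
  its full variability; conclusions about real datasets require real data.
* The NumPy engine targets clarity and exactness, not speed; it is not meant
  for large images or deep production models.
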