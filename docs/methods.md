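# Methods

This note documents the models and procedures implemented in
`paddytiller`, the parameters that matter, and the choices made where the
design was genuinely open.

## Image conditioning

**CLAHE.** The image is divided into an 8×8 tile grid; each tile's 256-bin
histogram is clipped at `clip_limit × (tile pixels / 256)` (default clip
limit 2.0) and the clipped excess is redistributed uniformly in a single
pass — no iterative re-clipping, which keeps the mapping deterministic.
Each tile's equalization map is `round(255 · cdf)`, and per-pixel output
bilinearly blends the four surrounding tile maps (tile centers as nodes;
beyond the outer centers the nearest map extends). Colour images are
transformed to BT.601 YCbCr, equalized on Y only, and transformed back:
equalizing channels independently would shift hue and corrupt the
greenness features downstream. Degenerate sizes (fewer pixels than tiles)
fall back to fewer tiles, ultimately global equalization.

**Median filter.** 3×3 window, channels independent, symmetric padding
(edge pixels duplicated into the virtual border: a,b,c → a,a,b,c; scipy's
`reflect` mode). The 3×3/symmetric combination removes the bulk of
salt-and-pepper noise while keeping 1–2 px leaf structures; the package
measures its restoration rate on a synthetic piecewise-constant image at
2 % impulse density (acceptance script, target ≥ 92 % of corrupted pixels
exactly restored; measured ≈ 99.9 %).

## Classical segmentation

ExG = 2G − R − B is computed in exact integer arithmetic (range
[−510, 510]) and mapped to bytes by the *fixed* affine
(v + 510)·255/1020 — not per-image min-max — so Otsu thresholds are
comparable across images. Otsu maximizes between-class variance over the
256-bin histogram; ties break toward the smallest threshold; the
implementation is vectorized cumulative sums and is tested against an
exhaustive 256-threshold scan.

Degenerate handling: a constant image, or a scene whose 1st–99th
percentile spread of rescaled ExG is below 32 byte levels, has no
meaningful bimodality — Otsu on such a histogram would simply split the
noise and mark roughly half the pixels foreground. These scenes fall back
to the sign rule ExG > 0, which leaves plant-free scenes (soil is
reddish-brown, G < R, so ExG is clearly negative) essentially empty and
all-green frames fully positive. The 32-level guard sits well below the
≈57-level spread a vegetated scene produces and well above the ≈17-level
spread of pure background noise; both figures come from the synthetic
scene model below.

## Swin-UNet

Architecture: 4×4 patch embedding (linear, LayerNorm) → encoder stages of
Swin blocks (LayerNorm → window attention → residual → LayerNorm → 2-layer
GELU MLP → residual), alternating unshifted (W-MSA) and shifted (SW-MSA,
shift = window/2) windows, with patch merging (2×2 concat → linear,
channels ×2) between stages → bottleneck → mirror-image decoder whose
upsampling is a sub-pixel expansion (linear 2C → 2×2×C, depth-to-space)
with skip fusion by concatenation + linear → final ×4 sub-pixel head.
Shifted windows use the standard region-label additive mask (−1e9 across
region boundaries). Relative-position bias is omitted — at desk scale it
adds parameters without measurable benefit on the synthetic scenes.

**Input-level skip.** The patch embedding compresses each 4×4×3 patch
(48 values) below its raw dimensionality (24 channels in the tiny
profile), which puts a hard ceiling on per-pixel boundary accuracy: with
a token-only head the network plateaued near mIoU 0.83 on scenes whose
pixels are linearly separable by colour (a per-pixel logistic fit reaches
≈1.0). The head therefore receives the raw patch concatenated to the
decoder token — fusing shallow per-pixel detail with the transformer's
global semantics — which removed the ceiling (mIoU 0.99 on the overfit
check). Inputs are standardized by fixed constants ((x/255 − 0.4)/0.25,
field scenes average ≈0.4 reflectance) so the raw-skip path is on the
same scale as the normalized tokens.

Profiles: default embed 96, depths (2,2,2), heads (3,6,12), window 8
(Swin-T-like); `tiny` embed 24, depths (2,2), heads (2,4), window 4 for
64×64 inputs — the profile used by the tests. All weights act on
channels, so any input size satisfying the divisibility constraints is
accepted at inference; `pad_to_valid` edge-pads and predictions are
cropped back.

**Loss and optimizer.** Per-pixel cross-entropy with class weights
(1, 3): rice occupies only ~7 % of early-tillering scenes and the plain
loss undertrains the minority class. Lion updates:
c = β1·m + (1−β1)·g, p ← p − lr·(sign(c) + wd·p), m ← β2·m + (1−β2)·g,
sign(0) = 0; defaults β1 = 0.9, β2 = 0.99, lr 1e-4, wd 0.01. The training
loop uses minibatches of 2 with a cosine learning-rate decay from 3e-3 to
a 1e-4 floor over the epoch budget — sign-based updates do not settle at
a fixed step size, and the decay is what closes the last few mIoU points.
Training is full-precision float32 and bit-deterministic under a fixed
seed (seeded init, seeded shuffling).

The autodiff engine (`paddytiller.nn`) is a ~15-operation reverse-mode
tape over numpy (broadcast arithmetic, batched matmul, reshape/transpose/
roll/slice, exp/log/erf, reductions, concatenation); every operation is
checked against central finite differences in float64.

**Metrics.** PA = (TP+TN)/total; mIoU averages per-class IoU over
background and rice, a class absent from both prediction and label
contributing IoU 1. Background is a class in its own right in the mean,
per the per-class-sum form of the definition.

## Plant separation

8-connectivity throughout (thin leaves connect diagonally). The noise
floor defaults to 50 px² ≈ 1.1 cm² at 0.15 cm/px. Distance transform is
the exact Euclidean transform; an all-foreground mask measures distances
to the image border.

**Cyclic-threshold adhesion splitting.** The published description of
this step is informal; the implementation here is a reconstruction and is
flagged as such. Sweep t from max(d) downward in steps of 0.05·max; at
each level count the connected components of {d ≥ t}. The first count ≥ 2
that persists for 3 consecutive steps is accepted; seeds are taken at the
*deepest* step of that plateau (largest cores, just before merging) and
must each have ≥ 9 px. Counting raw components while validating only the
final seeds matters: filtered counts can pass through a 2-core
configuration in a single step on smoothly overlapping plants, while a
raw-count plateau is stable. A 3×3-disc morphological opening then
refines the seeds (its components replace the threshold cores when
counts agree), and every pixel of the original region is assigned to the
nearest core centroid — so the outputs partition the input exactly, by
construction. Brightness-unequal cores are treated symmetrically.

Geometry: convex hull by monotone chain on pixel centers (shoelace area;
collinear → 0); minimum-area rectangle by rotating calipers
(shapely's `minimum_rotated_rectangle`), width ≥ height, angle of the
width side mod 90°, degenerate single-pixel/collinear cases floored for
feature use.

## Features

The 12 features and their conventions:

| feature | definition | unit |
|---|---|---|
| total_area | region pixel count | px² |
| perimeter | boundary-pixel count (8-neighbour rule) | px |
| rect_height, rect_width | min-area rectangle sides (w ≥ h), floored at 1 | px |
| area_rect_ratio | area / (w·h), capped at 1 | – |
| rect_aspect | w / h | – |
| fractal_dim | box-counting slope, ε = 2…M/4 on the bounding-box canvas padded to a power-of-two square | – |
| perim_area_ratio | perimeter / area | px⁻¹ |
| hull_area | convex-hull area of pixel centers | px² |
| area_hull_ratio | area / hull_area, capped at 1 | – |
| green_value | Σ G over green pixels ÷ tile pixel count | – |
| green_ratio | green pixel count ÷ tile pixel count | – |

"Green" pixels have G strictly dominant (G > R and G > B). Both colour
features are normalized by the *tile* pixel count (the lattice cell a
hill was sampled from), so they are diluted by tile area — this is the
convention under which the packaged greenness regression's scale is
coherent. Perimeter as a boundary-pixel count (not polygonal arc length)
likewise matches the packaged perimeter equation's scale. The
bounding-box canvas makes the fractal dimension exactly
translation-invariant at the feature level; patches under 8 px in either
direction are below the box-series floor and report the curve-limit 1.0.

Normalization maps each column to [1, 2] by x' = 1 + (x−min)/(max−min);
constant columns map to 1; the fitted scaler (per-column min/max,
serialized as JSON) is reused on held-out data with clipping into [1, 2].
Per-plot sample values average the four sampled hills.

## Regression

The 11 packaged linear equations ship as a JSON registry (id, feature
names, coefficients, intercept). Equations printed in the form
y = (x+a)/b are stored as slope 1/b and intercept a/b. One printed
four-feature equation contains an unbalanced parenthesis; it is read as
−0.0006·x3 + 0.0405·x4, the pattern of its neighbours, and one
multi-factor equation's "x2r" token is read as x2.

Metrics: RMSE, MAE, nRMSE = RMSE/NF·100 % with NF = mean observed value
(the normalizer is not otherwise pinned down; the observed mean is the
common choice and consistent with the packaged models' reported
magnitudes), and R² in two forms — standard 1 − SSres/SStot (default;
the only form meaningful on held-out data for nonlinear models) and the
regression-sum-of-squares form SSreg/SStot (identical for in-sample OLS).
Zero-variance truth flags R² as undefined.

ML regressors are scikit-learn's RandomForestRegressor and SVR and
xgboost's XGBRegressor behind a common `fit_ml` surface; all seeded and
single-threaded for determinism. PSO is canonical:
v ← ωv + c1·r1·(pbest−x) + c2·r2·(gbest−x), x clipped to bounds, with
ω = 0.729, c1 = c2 = 1.49445 (constriction-style values), swarm 30,
50 iterations by default — these numeric settings are this package's
choices. The random draw order is part of the contract (documented in
the docstring) so an independent reimplementation reproduces the
trajectory exactly under a shared seed. `fit_pso_ml` minimizes k-fold
cross-validated RMSE (5 folds by default) over per-algorithm boxes
(gradient boosting: trees 50–500, depth 2–10, learning rate 0.01–0.3,
subsample/colsample 0.5–1, L2 0–10; random forest: trees 50–500, depth
2–20, min leaf 1–10; SVR: C and γ on log scales, ε 0.01–1) and
warm-starts one particle at the library-default hyperparameters, making
"tuned ≤ default on the same folds" structural rather than statistical.

## Thematic mapping

Checkerboard cells of side `scale` px tile the image exactly (last
row/column truncated). Per-cell estimates sum the predictions of plants
whose centroids fall in the cell. Jenks natural breaks run Fisher's
O(k·n²) dynamic program over the sorted values with prefix-sum SSD
queries; breaks are the upper values of classes 1..k−1, and the
goodness-of-variance fit GVF = 1 − SSDwithin/SSDtotal is reported for
transparency. Colours interpolate linearly between (102, 255, 102) and
(0, 153, 0) over k classes; legends use the ≤b₁, b₁+1–b₂, …, ≥b₄ style
for integer counts. The published example breaks (83, 114, 143, 171) are
shipped as a worked legend only — breaks for new data are always
recomputed from that data.

## Synthetic scenes

The generator emulates one breeding plot: a jittered 3×9 hill lattice on
a 1.2 m × 0.9 m plot at 0.15 cm/px (800×600 px), per-hill tiller counts
uniform on 2–30 (the span field protocols record from early to late
tillering). Each hill renders radiating leaf strokes (length 8–30 px,
width 2–4 px) until its plant area reaches
`area_per_tiller · tillers · (1+ε)`, ε ~ N(0, 0.15) truncated at ±0.5;
when strokes saturate their reach the canopy closes by dilation, as a
dense crown does from above. `area_per_tiller` defaults to 220 px², the
scale implied by the packaged plant-area equation (slope ≈ 1/222).
σ = 0.15 puts the area↔tiller Pearson correlation near 0.95 at this
tiller range, emulating the strong linear relation reported for field
data; the generator's calibration test asserts r ≥ 0.9.

Background: reddish-brown soil (≈(150, 85, 60), so ExG ≈ −40) with a
low-frequency bilinear gradient applied equally to all channels (leaving
ExG untouched), elliptical blue water patches, small bright speculars,
per-pixel Gaussian colour noise (σ 6), and optional salt-and-pepper
impulses. Plants are green-dominant (≈(60, 150, 50)) with per-hill hue
jitter. Everything derives from one seeded generator; scenes are
byte-reproducible.

What the generator does *not* emulate — and hence what passing tests do
not show about field data: perspective and stitching artifacts, algae
mats hugging the plant base, growth-stage colour drift, yellowing or
nitrogen-stressed leaves, inter-plot occlusion, and realistic leaf
texture. Synthetic results demonstrate that the pipeline's machinery is
correct and well-calibrated, not that field-scale accuracies transfer.

## Problem sizes used in the checks

The test suite exercises the network at the tiny profile on five 64×64
two-hill scenes (overfit capacity check: training mIoU ≥ 0.95 within 200
epochs; reached ≈0.99 in ~30 s on one CPU) and the end-to-end recovery
on 8 full plots (216 hills) with a reduced PSO budget (swarm 12, 15
iterations, 3 folds; the library defaults remain swarm 30/50/5). These
sizes are the package's chosen desk-scale study conditions; enlarging
them changes runtimes, not conclusions.

## Known limitations

* The adhesion-splitting rule is a reconstruction of an informally
  described procedure; other plateau conventions are defensible.
* The numpy network trains at desk scale only; field-scale training
  (hundreds of 512² tiles) wants a GPU framework, and the packaged
  linear equations' coefficients apply to the imaging setup they were
  fitted on, not to arbitrary GSDs.
* Otsu's low-contrast guard (32 levels) is calibrated to this package's
  scene model; unusually dark or washed-out vegetated imagery could
  trip it and should be contrast-enhanced first.
* `evaluate`'s confusion counts treat rice as the positive class; the
  mIoU is insensitive to that labelling but PA-style derived quantities
  are not.
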