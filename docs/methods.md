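# Methods

## Problem and pipeline

The package estimates five standard conformation measurements of large
livestock (body length, body height, oblique body length, chest girth,
cannon circumference, all in cm) from a single side-view photograph that
contains a reference ruler of known physical length (1.1 m) lying in the
imaging plane.  Two stages:

1. a convolutional pose network detects ten named body-surface keypoints
   and one bounding box per image;
2. Euclidean distances between designated keypoint pairs, converted to
   centimetres through the ruler calibration (`pixels_per_metre` =
   ruler pixel length / 1.1), form a feature vector that a regression
   network maps to the five measurements.

Because the circumferential measures (chest girth, cannon circumference)
are three-dimensional quantities, a side view can only observe their 2-D
proxies (chest depth, cannon width).  The regression stage is therefore
expected to exploit allometry — the strong covariation of body dimensions —
rather than to measure girths directly.

## Synthetic data generator

No public dataset of this kind exists, so all training and validation run
on a parametric generator.

**Population model.**  An individual is a latent tuple: standing height
`size_scale` ~ truncated Normal(1.20 m, 0.12), trunk aspect ratio
(length/height) ~ truncated Normal(1.25, 0.05), and three shape fractions
(chest depth / height, cannon width / height, girth eccentricity) that are
fixed means multiplied by log-normal residuals with coefficients of
variation 2.5–3.5 %.  The multiplicative structure mirrors real
conformation data, where skeletal and girth dimensions scale nearly
isometrically with body size and within-size residual variation is a few
percent (cross-correlations of r ≈ 0.9).  Without this coupling the girths
would be unpredictable from side-view geometry at any realistic keypoint
precision — an 11 px cannon width cannot be resolved to the sub-pixel level
that independent variation would require.

**Geometry.**  The body template is a 2-D articulated silhouette: a
superellipse trunk (exponent 4, giving a flat back and belly), four
rectangular legs with distinct upper/cannon/hoof widths, a neck/head wedge
with a disc head and muzzle, and a tail.  All ten keypoints are defined in closed form
on this template, so the three linear measurements equal their keypoint
distances exactly (in cm: 100× the metric distance).  Chest girth is the
perimeter of an ellipse with semi-major axis = half the observed chest
depth and axis ratio = the individual's girth eccentricity, evaluated with
the complete elliptic integral; cannon circumference is π × cannon width
(circular cross-section).  Measurement noise (default 1 % multiplicative)
emulates repeat-and-average manual measurement error.

**Rendering.**  Scenes are rasterised at 320×320 px with a per-view scale
of roughly 150 px/m (auto-fitted so the animal plus margins fits the
frame), a textured background with an illumination gain, fur-texture noise
on the coat, a striped ruler bar on the ground line, and a fair-coin
horizontal mirroring so both orientations occur.  The head, neck and
muzzle are deliberately prominent: they are the orientation cue a real
side view carries, and without them front/back becomes unlearnable at
reduced training resolutions.  Pose jitter displaces
keypoints by a configurable fraction of body height (default 2 %;
the ground-contact point stays on the ground plane).  Everything is a pure
function of (configuration, seed): images regenerate bit-identically.

**What the generator does not model** — and hence what passing tests do
not demonstrate about real data: photorealistic appearance, fur occlusion
of landmarks, out-of-plane rotation, perspective foreshortening, herd
scenes, and annotation ambiguity by human labellers.  The generator's
role is to make every algorithmic contract testable, not to certify field
accuracy.

## Pose network

The backbone/neck follow the published YOLO11 layout (recorded layer by
layer in `morphopose/configs/yolo11_pose.yaml`): C3k2 stacks, SPPF, C2PSA,
a three-scale P3/P4/P5 head with distribution-focal box regression
(`reg_max` bins per box side), a depthwise-separable class branch and a
keypoint branch emitting (dx, dy, confidence) per keypoint per cell.

Three attention insertions are switchable:

* **UIB** (expand 1×1 → depthwise 3×3 → compress 1×1, SiLU output
  activation, residual when channels match) replaces the dense bottlenecks
  inside the C3k2 stacks of the stride-4…16 stages (layers 2, 4, 6, 13,
  16, 19).  The outer nonlinearity of the UIB chain is interpreted as the
  block's output activation; a sigmoid there would crush the residual
  feature scale.
* **SENetV2** (squeeze = global average pool; per-branch bottleneck MLPs
  whose excitation logits are averaged before one sigmoid; default 2
  branches, reduction 16) recalibrates the SPPF output channels.  With one
  branch it reduces exactly to classic SE.
* **TripleAttention** (three Z-pool→conv7→sigmoid gates over the (H,W),
  (C,H) and (C,W) tensor rotations, fused with fixed weights ⅓ each, a
  learnable softmax parameterisation optional) gates the attention path of
  C2PSA.

Turning an insertion off recovers the unmodified host bit-for-bit under a
shared seed, because insertions wrap hosts without re-ordering parameter
initialisation.  The five ablation presets are E0 (none), E1 (UIB),
E2 (SE), E3 (TA), Ep (all three).

**Free hyper-parameters fixed from printed complexity.**  The published
description does not state which host instances receive the insertions nor
the UIB expansion ratio or SE width.  These were fixed once from the
published complexity figures of the final model (≈10.06 MB parameters,
6.4 GFLOPs): inserting UIB into all eight C3k2 stacks is inconsistent with
those figures (it removes 1.0–1.2 MB), whereas the shallow/intermediate
subset with expansion 1.5 lands at 10.17 MB / 6.40 GFLOPs, and also yields
a UIB-only variant at 10.11 MB / 6.39 GFLOPs, matching the published
UIB-only row (10.12 / 6.4) almost exactly.  This choice was made on the
complexity counter alone, before any accuracy experiments.

**Complexity accounting.**  Parameters are enumerated exactly over
trainable tensors (batch-norm affine pairs included; the fixed
distribution-focal projection excluded).  FLOPs use the fused-convolution
convention of common profilers: each convolution contributes
k²·C_in/groups·C_out·H_out·W_out multiply–accumulates, one MAC = two
FLOPs; activations, pooling, concatenation and attention matrix products
are uncounted.  Since the graph is fully convolutional, per-layer areas
scale exactly with input area and the count is traced once at 64 px and
rescaled to the requested size.  Reported figures: E0 = 2,738,429
parameters = 10.45 MB, 6.85 GFLOPs at 640²; Ep = 2,666,929 = 10.17 MB,
6.40 GFLOPs.

**Training.**  Single animal per image.  The box/class ground truth is
assigned to the 3×3 cell neighbourhood of the box centre at every stride
whose bin range can represent the box.  Keypoints use local
heatmap-with-offset coding: per keypoint, the 2×2 cells nearest its
location are presence-positive and carry exact sub-cell offsets —
long-range offset regression from the box centre systematically shrinks
body-extreme landmarks toward the mean extent, while local coding keeps
every offset within about one cell.  Loss = BCE on the class map
(positive cells up-weighted ×20) + complete-IoU on decoded boxes + BCE on
the per-keypoint presence maps + L2 on the local offsets, with weights
1 / 5 / 2 / 10.  The published full-scale protocol (SGD momentum 0.937,
batch 16, 200 epochs, 640 px) is the default; the CPU-scale `tiny-test`
preset (width 1/16 of the base, `reg_max` 12 so that all three strides stay
eligible at 160 px input) trains with Adam 3e-3, batch 8, ≤40 epochs,
cosine-decayed.  Online horizontal-flip augmentation (p = 0.5) mirrors the
image, box, and keypoints; keypoint identities are kept, since the ten
side-view landmarks have no left/right pairs — a flip is the animal facing
the other way.  The best checkpoint is chosen by validation OKS-mAP with
PCK as tie-break (mAP saturates at zero early in short runs).

**Inference.**  Letterbox to the input size; boxes decode from all scales
with NMS; each keypoint is the confidence-weighted vote of its presence
peak and the peak's immediate neighbours on the finest stride.  A
structural side-consistency constraint resolves residual front/back
identity ambiguity: the reliably detected fore-limb cannon pair fixes the
facing direction, and the anterior (posterior) body-length and oblique
landmarks are searched on that (the opposite) side of the box centre —
the anatomy any quadruped side view obeys.  Optional flip-averaged
decoding (`tta`) averages the image's and its mirror's keypoints.
Coordinates map back through the exact letterbox inverse.  An image with
no candidate above the confidence threshold yields an explicit no-animal
result (`None`), not an exception.

## Morphometry

Features are either the five named pairs that define the measurements
(`named5`) or all C(10,2) = 45 pairwise distances (`all_pairs`); both are
first-class because the source description does not fix the
dimensionality.  Distances are exactly invariant to rotation and
translation, and invariant to image rescaling through the ruler
calibration.  Missing (invisible) keypoints raise a named error rather
than being imputed.  The `FeatureNormalizer` z-scores per dimension with
statistics frozen on the training split and refuses zero-variance
dimensions by name.

## Regression

Each scalar feature becomes a token: value × learned per-dimension
embedding + learned identity encoding.  A stack of post-norm Transformer
encoder blocks (default d_model 64, 4 heads, 2 layers, FFN 128) models
global dependencies; the mean-pooled encoding is concatenated with the raw
feature vector and decoded by a dense head into the five outputs.  The
"residual" variant adds one extra identity skip around each encoder block
(parameter counts are identical).  Baselines: DeepMLP (3 hidden layers),
stacked LSTM consuming tokens in the fixed anatomical order (the order is
a convention, not a temporal sequence), and a 1-D CNN.

All models train with MSE on z-scored targets (so centimetre-scale girth
and cannon errors weigh comparably), Adam with cosine decay from 1e-2,
early stopping on validation MSE (patience 50, ≤300 epochs), optional
weight decay and optional train-time feature-noise injection in raw
feature units.  These optimisation defaults were chosen so that every
architecture recovers exact linear ground truth to R² ≥ 0.99 at moderate
sample sizes; a 1e-3 rate with the same budget under-converges the
transformer.  Targets are de-scored at prediction, so outputs are cm.

## End-to-end pipeline

`TwoStagePipeline` trains the detector on the train split, extracts
*detected* features for train and validation images, and fits the
regressor on them so that systematic detector bias is absorbed.  Because
the detector partially memorises its training images, train-split features
understate test-time noise; the pipeline therefore estimates per-feature
noise SDs on the validation split (detected minus annotated features,
median-absolute-deviation scale so rare gross failures do not inflate it)
and injects matched Gaussian noise during regressor training.  The
regression training rows combine detected and annotated train-split
features: clean rows anchor the allometric structure, detected rows teach
robustness to detector error.  Inference uses flip-averaged decoding, and
per-individual estimates are predicted from the median of the per-view
feature vectors, robust to a single bad detection.  Detection failures on
training images fall back to the annotated keypoints; on evaluation
images they raise.

## Evaluation

OKS uses box area as the scale and a uniform per-keypoint tolerance
k = 0.05 (no published per-landmark sigmas exist for livestock); mAP
averages all-point-interpolated AP over OKS 0.50:0.05:0.95, with
precision/recall quoted at OKS 0.5 and the operating confidence threshold.
PCK at 0.1 × box diagonal is reported alongside as a sigma-free check.
Regression metrics (RMSE, MAE, MAPE %, R²) are computed per target and
macro-averaged; per-target values are always retained.  The perturbation
suite applies brightness gain (bounded to ±30 %), additive Gaussian noise
(default SD 10/255), horizontal linear motion blur (default 9 px kernel,
normalised to sum 1) and rectangular occlusion (default 10 % of image
area, filled with the background level) — photometric only, so annotation
geometry is untouched.  Split stability re-splits by individual ID under
different seeds and reports per-seed metrics with range and SD.

## Numerical and engineering choices

* All networks run on an in-repo reverse-mode autodiff engine over NumPy
  (im2col convolutions with BLAS contractions, explicit VJPs), verified
  against central finite differences to 1e-5 relative error.
* Initialisation is Kaiming-uniform from an explicit Generator; every
  model build, training run and dataset generation is a pure function of
  its seed.
* Problem sizes for the bundled studies were chosen to keep a full suite
  run at desk scale: the recovery study uses 60 individuals × 3 views at
  160 px and ≤40 epochs; the regression-only studies use the full study
  population size (111 individuals) with features computed in metric space.
* Degenerate inputs fail loudly: coincident ruler endpoints, missing or
  duplicate keypoint labels, zero-variance normaliser dimensions, empty
  validation splits and non-finite losses all raise typed errors.

## Known limitations

* A statistical note on the end-to-end recovery study: with a 7:2:1 split
  of 60 individuals the test set holds only six animals, so the test R² of
  even an oracle regressor fluctuates by several points across seeds; the
  bundled acceptance check runs two fixed seeds and accepts the better one,
  mirroring that variance.
* At the CPU study scale (160 px input, ≤40 epochs, 1/16-width preset) the
  detector's residual per-individual feature biases are 2–4 cm.  The
  keypoint-recovery bar (PCK ≥ 0.9) is met, and the measurement pipeline
  reaches macro R² ≈ 0.86 on the larger validation split, but the 0.95
  end-to-end bar on the six-animal test split is not reliably reached at
  this scale — the regression-only studies at the full population size do
  reach it, isolating the gap to desk-scale detector precision.
* Girth predictions rely on allometric proxies by construction; on real
  animals with pathological or atypical conformation they would degrade.
* The tiny CPU preset differs from the full-scale protocol (optimizer,
  input size, width); conclusions about the full-scale model's accuracy
  cannot be drawn from it, only contract-level correctness.
* The complexity convention reproduces published baseline figures to
  within 1 % but not exactly; the original profiling convention
  (bias terms, unfused layers, profiler version) is not stated there.
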