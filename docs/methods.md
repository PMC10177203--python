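# Methods

## The problem and the estimator

`histocad` classifies H&E-stained histology images as benign or malignant
using a *frozen* convolutional network as a feature extractor and a
classical classifier on top. No network weight is ever updated: features
are read out at several intermediate stages ("tap points"), each feature
map is reduced by global average pooling (GAP — the spatial mean, one
value per channel), and the pooled vectors are concatenated. A standard
scaler, an optional Nystroem kernel map, and an SVM or gradient-boosting
classifier are then fitted per training fold.

The quantity the package estimates is generalization accuracy under a
**patient-grouped nested 5-fold cross-validation**. The grouping unit is
the *case* (one histological slide / one patient): all images of a case
fall on one side of every split, outer and inner. This matters because
images from one slide share staining, illumination and tissue appearance;
an image-level split lets a classifier recognize the slide rather than
the pathology, inflating accuracy. The inner 5-fold loop (also grouped,
for consistency with the outer leakage rule) drives a random search over
classifier hyperparameters; the winning draw is refit on the full outer
training set and scored on the untouched outer test images. The reported
figure is the mean ± sd of the five outer-fold image-level accuracies
(sample sd, ddof 1 — the choice of denominator is ours), plus PPV and NPV
from pooled confusion counts with malignant as the positive class.

Accuracy is image-level by default (each test image is one prediction);
a case-level majority aggregation is available
(`evaluate.aggregate_case_level`) but not the default.

## Augmentation

Two training strategies:

* **base** — shorter edge resized to `resize_edge` (default 512 px,
  aspect preserved, bilinear), uniform random square crop at the
  backbone's input size, rotation drawn from {0, 90, 180, 270}°, vertical
  flip with probability 0.5. "Resize to 512" is interpreted as
  shorter-edge resize because bench-microscope captures are non-square
  (e.g. 1024×768) and isotropic rescaling preserves magnification.
* **advanced** — random-resized crop (area fraction Uniform[0.08, 1.0],
  aspect ratio log-uniform over [3/4, 4/3], treated as an interval rather
  than a two-point set, matching the usual random-resized-crop
  construction; a two-point variant is a one-line config change), then
  the same rotation/flip, then brightness, contrast and saturation each
  scaled by independent Uniform(0.8, 1.2) factors. Operation order is
  crop → resize → rotate → flip → jitter; since the rotations are exact
  multiples of 90° they commute with the resize up to resampling, so the
  order is a convention, fixed here once. Saturation jitter uses the
  standard blend-with-grayscale construction (PIL `ImageEnhance.Color`),
  which is linear in pixel values and therefore exactly testable;
  contrast jitter interpolates about the mean luminance.

Integer crop side lengths round *up* from the sampled target area, so the
realized pixel-area fraction never falls below the sampled one — this
keeps every realized fraction inside the declared [0.08, 1.0] band, which
the contract tests assert draw by draw.

At test time there is no randomness: shorter-edge resize, then either the
centre crop or the ten crops (centre + four corners + the horizontal
flips of those five, in that fixed order), then ImageNet normalization
(mean (0.485, 0.456, 0.406), sd (0.229, 0.224, 0.225), overridable).
Ten-crop predictions combine by majority vote; a 5–5 split goes to the
side with the larger absolute summed decision score (equivalently the
sign of the total), and an exact zero total goes to malignant, favouring
sensitivity. Ties are logged when they occur.

## Backbones and tap points

Tap points per architecture (registry-versioned in
`backbones.TAP_REGISTRY`):

| backbone | input | taps | channels | F |
|---|---|---|---|---|
| vgg16 | 224 | each conv block, pre-pool | 64,128,256,512,512 | 1472 |
| inception_v3 | 299 | first 2 conv blocks + first 2 inception blocks | 64,192,256,288 | 800 |
| efficientnet_b4 | 380 | last map before each channel increase | 24,32,56,112,160,272,448 | 1104 |
| stub | 96 | after each conv stage | configurable (8,16,32) | 56 |

The Inception-v3 and EfficientNet-B4 rows resolve a verbal tap rule
against the published architecture definitions; the registry flags them
as interpretation. Pretrained ImageNet weights are not bundled, and
requesting them raises with an instruction to use the stub or supply a
weights source. The `stub` backbone — three seeded, He-initialized random
3×3 convolution + ReLU + max-pool stages with a NumPy forward pass — is a
first-class citizen: random frozen convolutions are a legitimate (weak)
feature map, and they exercise every downstream stage deterministically
with zero downloads. VGG16 also has a NumPy forward pass with seeded
random weights, used to confirm the tap structure (F = 1472) by an actual
forward pass; its feature dimension does not depend on the weight values.

Extraction is frozen and pure: the same image always yields a
bit-identical vector, batching never changes results, and the
concatenation order is the registry's tap order.

## Classifiers

* Linear SVM: exact solver (`SVC(kernel="linear")`).
* Poly-3 / RBF SVM: Nystroem landmark map (landmarks are a seeded
  subsample of training rows) followed by a linear SVM in the
  approximated feature space. With as many landmarks as training rows the
  map reproduces the exact kernel Gram matrix to numerical precision,
  which the fidelity tests assert at 1e-6. The polynomial kernel is
  (γ⟨x, x′⟩ + 1)³. A landmark count above n is clipped to n with a
  warning.
* Stochastic gradient boosting: stagewise tree ensemble
  (`GradientBoostingClassifier`) with per-iteration row subsampling and a
  constant learning rate.

Search spaces (this package's choices, echoed in every report): C
log-uniform [1e-4, 1e2]; γ log-uniform [1e-5, 1e-1]; landmarks
{256, 512, 1024} (clipped at n_train); SGB learning rate log-uniform
[0.01, 0.3], trees {100, 300, 1000}, depth {1, 2, 3}, subsample
{0.5, 0.75, 1.0}. Default search budget: 20 draws, scored by mean
inner-fold image-level accuracy on centre-crop features; ties break to
the earliest draw. No class weighting by default (a `balanced` option
exists behind a config flag).

## The synthetic generator

The generator emulates the *statistical* structure of a slide-level
dataset, not tissue morphology: images nested in cases, one label per
case, a class effect carried by nucleus texture, and a case-level
appearance confound.

Each image is an "eosin" background (230, 180, 200) plus N ~
Poisson(λ_label) "hematoxylin" ellipses (90, 60, 140) at uniform
positions with Normal axis radii truncated at 1 px; nuclei may overlap
(collision handling would add realism but no statistical structure).
Gaussian pixel noise (sd 3 on the 8-bit scale, clipped) prevents
degenerate constant features. Each case carries one RGB tint ~
N(0, stain_shift_sd) added to its background — the stain-variation
confound that makes grouped splitting consequential.

Reference conditions, fixed once: 20 cases per class × 8 images at
96×96 px (small enough that the full nested pipeline runs in seconds per
experiment; the generator scales to 1024×768). Class effect λ_benign = 20
vs λ_malignant = 120 nuclei with radii 4±1 vs 5±1 px — a strong,
deliberately easy effect for the recovery check. Null conditions use
λ = 60 and equal radii (any common value works; 60 keeps nucleus coverage
comparable to the mid-range of the effect conditions). Stain shift sd 8
for the recovery/null conditions (visible but not dominant); sd 25 for
the leakage demonstration ("strong" — tints then dominate the
within-class feature variance, the regime the grouped/ungrouped contrast
is about). The ungrouped control uses the RBF-SVM family because
case memorization is a nearest-neighbour-like task: a kernel method
recalls the case clusters it has seen, which is exactly the failure mode
grouping prevents, while the grouped run with the same features and
family stays at chance.

What passing these tests does **not** show: robustness to real H&E
variability (scanner differences, stain protocols, tissue folds,
morphological heterogeneity), to class imbalance at realistic rates, or
to the much higher feature dimensionality of pretrained backbones. The
synthetic effect is a density/colour effect; real malignancy cues are
structural.

## Determinism and seeds

One master seed fans out through `numpy.random.SeedSequence` spawning to
every random stage: fold dealing, per-image/per-replicate augmentation
draws, hyperparameter sampling, Nystroem landmark choice, SGB
subsampling, and the generator's per-case/per-image streams. Reports are
written with sorted keys and no timestamps, so a repeated run with the
same seed is byte-identical — asserted in the tests. Augmentation
streams are indexed by image position, not fold, so grouped and
ungrouped runs with one master seed share identical features.

## Numerical choices and degenerate inputs

Bilinear interpolation everywhere; crop coordinates are top-left-origin,
half-open. Zero-variance feature dimensions scale to 0 (no division
error). Fold dealing shuffles per label and deals round-robin, so fold
sizes within a label differ by at most one (44 cases → outer folds of
9,9,9,9,8). Single-class training labels, undersized images, dimension
mismatches, unknown names/keys are all hard errors, not warnings, except
the landmark-count clip, which is a logged warning because it is a
well-defined reduction rather than a contract violation.

## Known limitations

* No bundled forward pass for Inception-v3 / EfficientNet-B4; their tap
  registry entries provide dimensions only.
* No stain normalization, patch tiling, or whole-slide formats.
* No probability calibration; decision scores are margins, not
  probabilities.
* The BreakHis reader parses the published folder convention but the
  data itself is never bundled or downloaded.
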