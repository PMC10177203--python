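# histocad

Computer-aided benign/malignant classification of H&E-stained histology
images, built for the common setting where a whole-slide scanner and a
GPU budget are not available: a *frozen* convolutional network provides
features, classical classifiers do the learning, and a patient-grouped
nested cross-validation provides an honest estimate of generalization.
The intended users are groups evaluating such pipelines on slide-level
image collections (e.g. veterinary or human tumor cohorts photographed
at the microscope), where the number of patients is small and the danger
of leaking patient appearance across the train/test boundary is large.

## Method

For an image x, a frozen CNN f is evaluated and its feature maps are
read out at tap points t₁ … t_m (e.g. the five pre-pool block outputs of
VGG16). Global average pooling reduces each map over its spatial
dimensions, and the pooled vectors are concatenated:

    φ(x) = [ GAP(f_{t₁}(x)) ; … ; GAP(f_{t_m}(x)) ] ∈ ℝ^F

Training features are drawn through one of two augmentation strategies
(*base*: resize-512 + random crop + 90°-rotations + vertical flip;
*advanced*: random-resized crop + rotations/flips + ±20% colour jitter),
standard-scaled with training-fold statistics, optionally passed through
a Nystroem kernel map (for polynomial-3 and RBF SVMs), and fitted with a
soft-margin SVM or stochastic gradient boosting. Generalization accuracy
is estimated by nested 5-fold cross-validation **grouped by case** — all
images of one slide/patient stay on one side of every split — with
random-search hyperparameter tuning in the inner folds. Test images are
classified from the centre crop or by majority vote over ten crops
(centre + corners + horizontal flips). Reports carry mean ± sd accuracy
over the outer folds and PPV/NPV with malignant as the positive class.

Because pretrained weights and real histology cannot ship with a source
package, `histocad` includes a seeded synthetic histology generator
(case-structured images with a Poisson nucleus-density class effect and
per-case stain tints) and a seeded random "stub" backbone, so the entire
pipeline — including its leakage behaviour — is testable offline.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```sh
histocad synth --config examples/synthetic_run.yaml --out data
histocad run   --config examples/synthetic_run.yaml --manifest data/manifest.csv --out results
```

which prints (after per-fold progress logs):

```
wrote 80 images in 20 cases to data
stub + linear_svm (base 1x, center_crop): accuracy 1.000 ± 0.000, PPV 1.000, NPV 1.000
stub + linear_svm (base 1x, ten_crop): accuracy 1.000 ± 0.000, PPV 1.000, NPV 1.000
```

The example dataset has a deliberately strong class effect (20 vs 120
nuclei per image on average), so a linear SVM on stub features separates
the classes perfectly in every outer fold: mean accuracy 1.000 with
zero sd across the five folds, and perfect positive and negative
predictive values. Setting both rates equal in the config (a null
dataset) drops accuracy to chance, and raising `stain_shift_sd` while
keeping rates equal demonstrates the case-memorization artifact that
grouped splitting exists to prevent — an image-level split scores high
on pure confounds while the grouped split stays at 0.5.

Real datasets enter either as a directory tree (`<label>_<caseID>/`
folders of JPEG/PNG, or the BreakHis folder convention) or as a flat CSV
manifest with columns `image_id, path, case_id, label, magnification,
width_px, height_px`.

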