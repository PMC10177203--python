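# End-to-end example: generate a synthetic case-structured dataset and
# evaluate stub-backbone features with a linear SVM under grouped nested CV.
schema_version: 1
master_seed: 7

dataset:
  layout: synthetic
  synthetic:
    n_cases_per_class: 10
    images_per_case: 4
    image_size: [96, 96]
    nucleus_rate: {benign: 20.0, malignant: 120.0}
    stain_shift_sd: 8.0
    seed: 7

backbone:
  name: stub
  input_size: 96
  stub_widths: [8, 16, 32]
  seed: 0

augmentation:
  strategy: base
  target_size: 96
  resize_edge: 96
  repeats: 1

classifier:
  family: linear_svm

evaluation:
  k: 5
  k_inner: 5
  n_search_iter: 10
  test_strategies: [center_crop, ten_crop]
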