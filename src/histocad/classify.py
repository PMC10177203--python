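"""Fold-scoped classifiers over extracted features.

Four families are supported, all binary (benign vs malignant, with
malignant as the positive class everywhere):

* ``linear_svm`` — soft-margin linear SVM (exact solver).
* ``poly3_svm`` / ``rbf_svm`` — kernel SVMs where the kernel is
  approximated by the Nystroem method (a low-rank map built from a random
  subsample of training rows, the *landmarks*), followed by a linear SVM
  in the approximated feature space.
* ``sgb`` — stochastic gradient boosting: stagewise additive decision-tree
  ensemble with per-iteration row subsampling.

Every model is fold-scoped: the standard scaler and the Nystroem landmarks
are fitted on training rows only and frozen into the
:class:`TrainedModel`, so held-out rows can never influence the fit.

Hyperparameter search spaces are this package's own (C and the kernel
width γ log-uniform, discrete sets for landmark count and the boosting
knobs); they are recorded in every report.
"""

from __future__ import annotations

import pickle
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.kernel_approximation import Nystroem
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

FAMILIES = ("linear_svm", "poly3_svm", "rbf_svm", "sgb")
LABEL_ORDER = ("benign", "malignant")  # malignant = positive class

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassifierSpec:
    family: str = "linear_svm"
    seed: int = 0
    #: discrete choices / log-uniform bounds defining the random-search space
    hyper_space: dict[str, Any] = field(default_factory=dict)
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")

    def space(self) -> dict[str, Any]:
        """The effective search space: defaults overlaid with overrides."""
        if self.family == "sgb":
            base: dict[str, Any] = {
                "learning_rate": ("log_uniform", 0.01, 0.3),
                "n_trees": ("choice", (100, 300, 1000)),
                "tree_depth": ("choice", (1, 2, 3)),
                "subsample_fraction": ("choice", (0.5, 0.75, 1.0)),
            }
        else:
            base = {"C": ("log_uniform", 1e-4, 1e2)}
            if self.family in ("poly3_svm", "rbf_svm"):
                base["gamma"] = ("log_uniform", 1e-5, 1e-1)
                base["nystroem_components"] = ("choice", (256, 512, 1024))
        base.update(self.hyper_space)
        return base


def sample_hypers(spec: ClassifierSpec, rng: np.random.Generator) -> dict[str, Any]:
    """One random draw from the spec's search space."""
    draw: dict[str, Any] = {}
    for name, dist in spec.space().items():
        kind = dist[0]
        if kind == "log_uniform":
            lo, hi = dist[1], dist[2]
            draw[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "choice":
            options = dist[1]
            draw[name] = options[int(rng.integers(len(options)))]
        elif kind == "fixed":
            draw[name] = dist[1]
        else:
            raise ValueError(f"unknown distribution kind {kind!r} for {name!r}")
    return draw


def fit_scaler(features: np.ndarray) -> StandardScaler:
    """Per-dimension standardization fitted on training rows only.

    Population (ddof 0) statistics; zero-variance dimensions map to 0.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need a 2-D feature matrix with at least 2 rows")
    return StandardScaler().fit(features)


def apply_scaler(scaler: StandardScaler, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.shape[1] != scaler.mean_.shape[0]:
        raise ValueError(
            f"feature dimension {features.shape[1]} does not match "
            f"scaler dimension {scaler.mean_.shape[0]}"
        )
    return scaler.transform(features)


_KERNELS = {"rbf": dict(kernel="rbf"), "poly3": dict(kernel="polynomial", degree=3, coef0=1.0)}


def fit_nystroem(
    features: np.ndarray,
    kernel: str,
    gamma: float,
    n_components: int,
    seed: int,
) -> Nystroem:
    """Fit the landmark map; landmarks are a subsample of the given rows."""
    if kernel not in _KERNELS:
        raise ValueError(f"kernel must be one of {sorted(_KERNELS)}, got {kernel!r}")
    n = features.shape[0]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > n:
        warnings.warn(
            f"nystroem_components={n_components} exceeds n_train={n}; clipping to {n}",
            stacklevel=2,
        )
        n_components = n
    mapper = Nystroem(
        **_KERNELS[kernel], gamma=gamma, n_components=n_components, random_state=seed
    )
    return mapper.fit(features)


def nystroem_map(
    features: np.ndarray,
    kernel: str,
    gamma: float,
    n_components: int,
    seed: int,
) -> np.ndarray:
    """Transformed training rows: inner products approximate kernel values."""
    return fit_nystroem(features, kernel, gamma, n_components, seed).transform(features)


@dataclass
class TrainedModel:
    scaler: StandardScaler
    nystroem: Nystroem | None
    classifier: Any
    spec: ClassifierSpec
    hypers: dict[str, Any]
    label_order: tuple[str, str] = LABEL_ORDER


def train_classifier(
    spec: ClassifierSpec,
    hypers: dict[str, Any],
    X: np.ndarray,
    y: np.ndarray,
) -> TrainedModel:
    """Scale, optionally kernel-approximate, and fit one classifier.

    ``y`` holds string labels; both classes must be present.  Fitting is a
    deterministic function of (spec.seed, hypers, X, y).
    """
    y = np.asarray(y)
    present = set(np.unique(y))
    if present != set(LABEL_ORDER):
        raise ValueError(
            f"training labels must contain both of {LABEL_ORDER}, got {sorted(present)}"
        )
    scaler = fit_scaler(X)
    Xs = apply_scaler(scaler, X)

    mapper: Nystroem | None = None
    if spec.family in ("poly3_svm", "rbf_svm"):
        kernel = "rbf" if spec.family == "rbf_svm" else "poly3"
        mapper = fit_nystroem(
            Xs, kernel, hypers["gamma"], int(hypers["nystroem_components"]), spec.seed
        )
        Xs = mapper.transform(Xs)

    if spec.family == "linear_svm":
        clf = SVC(kernel="linear", C=hypers["C"], class_weight=spec.class_weight)
    elif spec.family in ("poly3_svm", "rbf_svm"):
        clf = LinearSVC(
            C=hypers["C"],
            class_weight=spec.class_weight,
            random_state=spec.seed,
            max_iter=20000,
        )
    else:  # sgb
        clf = GradientBoostingClassifier(
            learning_rate=hypers["learning_rate"],
            n_estimators=int(hypers["n_trees"]),
            max_depth=int(hypers["tree_depth"]),
            subsample=float(hypers["subsample_fraction"]),
            random_state=spec.seed,
        )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        clf.fit(Xs, y)
    assert list(clf.classes_) == list(LABEL_ORDER)
    return TrainedModel(scaler=scaler, nystroem=mapper, classifier=clf, spec=spec, hypers=hypers)


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Real-valued scores; positive means malignant."""
    Xs = apply_scaler(model.scaler, X)
    if model.nystroem is not None:
        Xs = model.nystroem.transform(Xs)
    scores = np.asarray(model.classifier.decision_function(Xs), dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite decision scores")
    return scores


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(labels, scores); label is malignant iff score > 0."""
    scores = decision_scores(model, X)
    labels = np.where(scores > 0, model.label_order[1], model.label_order[0])
    return labels, scores


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Binary container + JSON manifest of spec/hypers for provenance."""
    path = Path(path)
    path.with_suffix(".pkl").write_bytes(pickle.dumps(model))
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "family": model.spec.family,
        "seed": model.spec.seed,
        "hypers": {k: (v if isinstance(v, (int, str)) else float(v))
                   for k, v in model.hypers.items()},
        "label_order": list(model.label_order),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def load_model(path: str | Path) -> TrainedModel:
    return pickle.loads(Path(path).with_suffix(".pkl").read_bytes())
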