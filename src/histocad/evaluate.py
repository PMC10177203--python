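"""Patient-grouped nested cross-validation and crop-vote evaluation.

The estimator of generalization error is a nested k-fold cross-validation
(k = 5 outer and inner by default) grouped at the *case* level: every image
of a histological slide/patient lands on exactly one side of every split,
outer and inner, so no appearance trait of a patient can leak from
training into testing.  Inner folds — also grouped — drive a random search
over the classifier's hyperparameter space; the winner is refit on the
full outer-training set and scored on the untouched outer-test images.
The final figure is the mean (± sample sd) of the outer-fold image-level
accuracies, with pooled confusion counts giving PPV and NPV (malignant =
positive class).

Test images are classified deterministically from either the single
centre crop or the ten crops (centre + corners + their horizontal flips);
with ten crops the label is the majority of the per-crop labels, even
5–5 splits resolved by the larger absolute summed decision score and an
exact zero sum resolved to malignant (favouring sensitivity).

An intentionally ungrouped mode (``group_by="image"``) is provided purely
as a control: on data with per-case appearance shifts it inflates
accuracy by memorizing cases, which is the failure mode grouping exists
to prevent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from PIL import Image

from .augment import AugmentationConfig, augment, normalize, test_time_crops, CROP_IDS
from .backbones import (
    TAP_REGISTRY_VERSION,
    BackboneSpec,
    build_backbone,
)
from .classify import (
    ClassifierSpec,
    LABEL_ORDER,
    decision_scores,
    sample_hypers,
    train_classifier,
)
from .manifest import DatasetManifest

logger = logging.getLogger(__name__)

TEST_STRATEGIES = ("center_crop", "ten_crop")


class EvaluationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# fold planning


@dataclass(frozen=True)
class FoldPlan:
    """Case-to-fold assignments for the outer and (nested) inner loops.

    ``outer[f]`` holds the unit ids tested in outer fold ``f``;
    ``inner[f][j]`` holds the unit ids validated in inner fold ``j`` of
    outer fold ``f`` (a partition of the outer-training units).  A *unit*
    is a case id under grouped splitting, an image id under the ungrouped
    control.
    """

    outer: tuple[tuple[str, ...], ...]
    inner: tuple[tuple[tuple[str, ...], ...], ...]
    unit_labels: dict[str, str]
    seed: int
    group_by: str = "case"

    @property
    def k(self) -> int:
        return len(self.outer)


def _deal_balanced(
    units: list[str], labels: dict[str, str], k: int, rng: np.random.Generator
) -> list[list[str]]:
    """Shuffle per label, deal round-robin: balances label counts per fold."""
    folds: list[list[str]] = [[] for _ in range(k)]
    for label in LABEL_ORDER:
        members = [u for u in units if labels[u] == label]
        order = rng.permutation(len(members))
        for i, idx in enumerate(order):
            folds[i % k].append(members[idx])
    return [sorted(f) for f in folds]


def make_fold_plan(
    manifest: DatasetManifest,
    k: int = 5,
    k_inner: int = 5,
    seed: int = 0,
    group_by: str = "case",
) -> FoldPlan:
    """Grouped, label-balanced nested fold assignments.

    Deterministic given ``seed``.  Cases (or images, for the ungrouped
    control) are shuffled per label and dealt round-robin, so fold sizes
    differ by at most one within each label.
    """
    if group_by == "case":
        unit_labels = manifest.case_labels
    elif group_by == "image":
        unit_labels = {r.image_id: r.label for r in manifest.records}
    else:
        raise ValueError(f"group_by must be 'case' or 'image', got {group_by!r}")
    units = sorted(unit_labels)
    if len(units) < k:
        raise EvaluationError(
            f"cannot make {k} folds from {len(units)} {group_by} units"
        )
    seqs = np.random.SeedSequence(seed).spawn(1 + k)
    outer = _deal_balanced(units, unit_labels, k, np.random.default_rng(seqs[0]))
    inner: list[tuple[tuple[str, ...], ...]] = []
    for f in range(k):
        train_units = [u for u in units if u not in set(outer[f])]
        rng = np.random.default_rng(seqs[1 + f])
        inner.append(tuple(tuple(fold) for fold in
                           _deal_balanced(train_units, unit_labels, k_inner, rng)))
    return FoldPlan(
        outer=tuple(tuple(f) for f in outer),
        inner=tuple(inner),
        unit_labels=dict(unit_labels),
        seed=seed,
        group_by=group_by,
    )


def verify_no_leakage(plan: FoldPlan) -> int:
    """Exhaustively count train/test unit overlaps over all splits (want 0)."""
    violations = 0
    all_units = set(plan.unit_labels)
    covered: set[str] = set()
    for f, test_units in enumerate(plan.outer):
        test_set = set(test_units)
        violations += len(test_set & covered)  # outer folds must not overlap
        covered |= test_set
        train_set = all_units - test_set  # train side of this outer split
        violations += len(test_set & train_set)
        inner_covered: set[str] = set()
        for val_units in plan.inner[f]:
            val_set = set(val_units)
            violations += len(val_set & test_set)       # inner val leaks outer test
            violations += len(val_set - train_set)      # val outside outer train
            violations += len(val_set & inner_covered)  # inner folds overlap
            inner_covered |= val_set
        violations += len(train_set - inner_covered)    # inner folds not exhaustive
    violations += len(all_units - covered)  # outer folds must be exhaustive
    return violations


# --------------------------------------------------------------------------
# feature tables


@dataclass
class FeatureTable:
    """A feature matrix with row provenance (image, case, label, crop)."""

    X: np.ndarray
    meta: pd.DataFrame  # columns: image_id, case_id, label, replicate, crop_id

    def rows_for_units(self, units: set[str], group_by: str) -> np.ndarray:
        col = "case_id" if group_by == "case" else "image_id"
        return self.meta[col].isin(units).to_numpy()


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one evaluation run depends on, seeded by ``master_seed``."""

    backbone: BackboneSpec = BackboneSpec()
    classifier: ClassifierSpec = ClassifierSpec()
    augmentation: AugmentationConfig = AugmentationConfig(target_size=96, resize_edge=96)
    test_strategies: tuple[str, ...] = ("center_crop", "ten_crop")
    n_search_iter: int = 20
    k: int = 5
    k_inner: int = 5
    group_by: str = "case"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.augmentation.target_size != self.backbone.resolved_input_size:
            raise ValueError(
                f"augmentation.target_size ({self.augmentation.target_size}) must "
                f"equal backbone input size ({self.backbone.resolved_input_size})"
            )
        bad = [s for s in self.test_strategies if s not in TEST_STRATEGIES]
        if bad:
            raise ValueError(f"unknown test strategies {bad}; known: {TEST_STRATEGIES}")
        if self.n_search_iter < 1:
            raise ValueError("n_search_iter must be >= 1")


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_images(manifest: DatasetManifest) -> dict[str, np.ndarray]:
    images: dict[str, np.ndarray] = {}
    for rec in manifest.records:
        with Image.open(manifest.abspath(rec)) as im:
            images[rec.image_id] = np.asarray(im.convert("RGB"))
    return images


def extract_feature_tables(
    config: ExperimentConfig,
    manifest: DatasetManifest,
    images: dict[str, np.ndarray] | None = None,
) -> dict[str, FeatureTable]:
    """Extract all training-replicate and test-crop features up front.

    Features are generated and stored before any classifier training; the
    augmentation draws depend only on (master_seed, image index,
    replicate), never on the fold plan, so grouped and ungrouped runs with
    the same master seed see identical features.
    """
    if images is None:
        images = load_images(manifest)
    extractor = build_backbone(config.backbone)
    aug_root = np.random.SeedSequence((config.master_seed, 1))
    want_ten = "ten_crop" in config.test_strategies

    train_rows, train_meta = [], []
    test_rows, test_meta = [], []
    img_seqs = aug_root.spawn(len(manifest.records))
    for rec, seq in zip(manifest.records, img_seqs):
        img = images[rec.image_id]
        for rep, rep_seq in enumerate(seq.spawn(config.augmentation.repeats)):
            aug = augment(img, config.augmentation, np.random.default_rng(rep_seq))
            train_rows.append(extractor.extract(normalize(aug)))
            train_meta.append((rec.image_id, rec.case_id, rec.label, rep, "train"))
        crops = test_time_crops(
            img, config.augmentation, "ten_crop" if want_ten else "center_crop"
        )
        ids = CROP_IDS if want_ten else ("center",)
        for crop_id, crop in zip(ids, crops):
            test_rows.append(extractor.extract(normalize(crop)))
            test_meta.append((rec.image_id, rec.case_id, rec.label, 0, crop_id))

    cols = ["image_id", "case_id", "label", "replicate", "crop_id"]
    return {
        "train": FeatureTable(np.stack(train_rows), pd.DataFrame(train_meta, columns=cols)),
        "test": FeatureTable(np.stack(test_rows), pd.DataFrame(test_meta, columns=cols)),
    }


# --------------------------------------------------------------------------
# tuning and prediction


def tune(
    spec: ClassifierSpec,
    train_table: FeatureTable,
    val_table: FeatureTable,
    inner_folds: tuple[tuple[str, ...], ...],
    n_iter: int,
    seed: int,
    group_by: str = "case",
) -> tuple[dict[str, Any], list[dict[str, Any]]]:
    """Random search scored by mean inner-fold image-level accuracy.

    Each draw is evaluated by training on the augmented features of the
    inner-training images and predicting the centre-crop features of the
    inner-validation images.  Ties break toward the earliest draw.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    center = val_table.meta["crop_id"].eq("center").to_numpy()
    best: dict[str, Any] | None = None
    best_score = -np.inf
    history: list[dict[str, Any]] = []
    for i in range(n_iter):
        hypers = sample_hypers(spec, rng)
        accs = []
        for val_units in inner_folds:
            val_set = set(val_units)
            tr_mask = ~train_table.rows_for_units(val_set, group_by)
            model = train_classifier(
                spec, hypers, train_table.X[tr_mask],
                train_table.meta.loc[tr_mask, "label"].to_numpy(),
            )
            va_mask = center & val_table.rows_for_units(val_set, group_by)
            scores = decision_scores(model, val_table.X[va_mask])
            pred = np.where(scores > 0, LABEL_ORDER[1], LABEL_ORDER[0])
            truth = val_table.meta.loc[va_mask, "label"].to_numpy()
            accs.append(float((pred == truth).mean()))
        score = float(np.mean(accs))
        history.append({"draw": i, "hypers": _to_jsonable(hypers), "inner_accuracy": score})
        logger.debug("tune draw=%d inner_acc=%.4f hypers=%s", i, score, hypers)
        if score > best_score:
            best, best_score = hypers, score
    assert best is not None
    return best, history


def majority_vote(scores: np.ndarray) -> str:
    """Label from per-crop decision scores (positive = malignant).

    Majority of per-crop labels; an even split falls to the side with the
    larger absolute summed score (equivalently the sign of the total),
    and an exact zero total goes to malignant.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    votes_malignant = int((scores > 0).sum())
    if 2 * votes_malignant > n:
        return LABEL_ORDER[1]
    if 2 * votes_malignant < n:
        return LABEL_ORDER[0]
    logger.info("crop-vote tie (%d/%d); tie-break by summed score %.4g",
                votes_malignant, n, scores.sum())
    return LABEL_ORDER[1] if scores.sum() >= 0 else LABEL_ORDER[0]


def predict_image(model, crop_features: np.ndarray, test_strategy: str) -> str:
    """Classify one image from its test-crop feature rows."""
    if test_strategy == "center_crop":
        crop_features = crop_features[:1]
    scores = decision_scores(model, crop_features)
    return majority_vote(scores)


# --------------------------------------------------------------------------
# the experiment runner


@dataclass
class StrategyResult:
    fold_accuracies: list[float]
    mean: float
    sd: float
    confusion: dict[str, int]  # tp/fp/tn/fn, malignant positive
    ppv: float
    npv: float


@dataclass
class EvaluationReport:
    config: dict[str, Any]
    config_hash: str
    seeds: dict[str, int]
    tap_registry_version: int
    strategies: dict[str, StrategyResult]
    chosen_hypers: list[dict[str, Any]]
    search_history: list[list[dict[str, Any]]]
    predictions: list[dict[str, Any]]  # per image x strategy
    failure: dict[str, Any] | None = None

    def to_dict(self) -> dict[str, Any]:
        return _to_jsonable(self)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        )
        summarize(self).to_csv(out_dir / "summary.csv", index=False, lineterminator="\n")


def _confusion(preds: list[tuple[str, str]]) -> dict[str, int]:
    pos = LABEL_ORDER[1]
    tp = sum(1 for t, p in preds if t == pos and p == pos)
    fp = sum(1 for t, p in preds if t != pos and p == pos)
    tn = sum(1 for t, p in preds if t != pos and p != pos)
    fn = sum(1 for t, p in preds if t == pos and p != pos)
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def run_experiment(
    config: ExperimentConfig,
    manifest: DatasetManifest,
    features: dict[str, FeatureTable] | None = None,
    out_dir: str | Path | None = None,
) -> EvaluationReport:
    """Full nested-CV evaluation of one (backbone, classifier, augmentation).

    Per outer fold: random-search tuning on grouped inner folds, refit on
    the whole outer-training set, per-image crop-vote prediction on the
    outer-test images.  Returns (and optionally writes) the report; any
    stage failure is recorded in the report with the fold and stage named,
    then re-raised.
    """
    plan = make_fold_plan(
        manifest, config.k, config.k_inner, seed=_sub_seed(config.master_seed, 0),
        group_by=config.group_by,
    )
    if features is None:
        features = extract_feature_tables(config, manifest)
    train_t, test_t = features["train"], features["test"]

    per_strategy_preds: dict[str, list[list[tuple[str, str]]]] = {
        s: [] for s in config.test_strategies
    }
    predictions: list[dict[str, Any]] = []
    chosen: list[dict[str, Any]] = []
    histories: list[list[dict[str, Any]]] = []
    failure: dict[str, Any] | None = None
    stage = "setup"
    try:
        for f, test_units in enumerate(plan.outer):
            stage = f"fold {f}: tuning"
            test_set = set(test_units)
            best, hist = tune(
                config.classifier, _subset(train_t, test_set, config.group_by, invert=True),
                _subset(test_t, test_set, config.group_by, invert=True),
                plan.inner[f], config.n_search_iter,
                seed=_sub_seed(config.master_seed, 10 + f), group_by=config.group_by,
            )
            chosen.append(_to_jsonable(best))
            histories.append(hist)

            stage = f"fold {f}: refit"
            tr_mask = ~train_t.rows_for_units(test_set, config.group_by)
            model = train_classifier(
                config.classifier, best, train_t.X[tr_mask],
                train_t.meta.loc[tr_mask, "label"].to_numpy(),
            )

            stage = f"fold {f}: prediction"
            te_meta = test_t.meta[test_t.rows_for_units(test_set, config.group_by)]
            fold_preds: dict[str, list[tuple[str, str]]] = {
                s: [] for s in config.test_strategies
            }
            for image_id, grp in te_meta.groupby("image_id", sort=True):
                order = {cid: r for r, cid in zip(grp.index, grp["crop_id"])}
                row_idx = [order[cid] for cid in CROP_IDS if cid in order]
                rows = test_t.X[row_idx]
                truth = grp["label"].iloc[0]
                for strat in config.test_strategies:
                    pred = predict_image(model, rows, strat)
                    fold_preds[strat].append((truth, pred))
                    predictions.append(
                        {"fold": f, "image_id": image_id, "strategy": strat,
                         "truth": truth, "prediction": pred}
                    )
            for strat in config.test_strategies:
                per_strategy_preds[strat].append(fold_preds[strat])
            logger.info(
                "fold=%d done acc=%s", f,
                {s: round(float(np.mean([t == p for t, p in fold_preds[s]])), 4)
                 for s in config.test_strategies},
            )
    except Exception as exc:  # noqa: BLE001 - flush partial report, then re-raise
        failure = {"stage": stage, "error": str(exc)}
        report = _assemble(config, plan, per_strategy_preds, chosen, histories,
                           predictions, failure)
        if out_dir is not None:
            report.write(out_dir)
        raise EvaluationError(f"experiment failed at {stage}: {exc}") from exc

    report = _assemble(config, plan, per_strategy_preds, chosen, histories,
                       predictions, None)
    if out_dir is not None:
        report.write(out_dir)
    return report


def _sub_seed(master_seed: int, stream: int) -> int:
    return int(np.random.SeedSequence((master_seed, stream)).generate_state(1)[0] % (2**31))


def _subset(table: FeatureTable, units: set[str], group_by: str, invert: bool) -> FeatureTable:
    mask = table.rows_for_units(units, group_by)
    if invert:
        mask = ~mask
    return FeatureTable(table.X[mask], table.meta[mask].reset_index(drop=True))


def _assemble(config, plan, per_strategy_preds, chosen, histories, predictions, failure):
    strategies: dict[str, StrategyResult] = {}
    for strat, folds in per_strategy_preds.items():
        if not folds:
            continue
        accs = [float(np.mean([t == p for t, p in fp])) for fp in folds]
        pooled = [tp for fp in folds for tp in fp]
        conf = _confusion(pooled)
        ppv = conf["tp"] / (conf["tp"] + conf["fp"]) if conf["tp"] + conf["fp"] else float("nan")
        npv = conf["tn"] / (conf["tn"] + conf["fn"]) if conf["tn"] + conf["fn"] else float("nan")
        strategies[strat] = StrategyResult(
            fold_accuracies=accs,
            mean=float(np.mean(accs)),
            sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            confusion=conf,
            ppv=float(ppv),
            npv=float(npv),
        )
    return EvaluationReport(
        config=_to_jsonable(config),
        config_hash=config_hash(config),
        seeds={"master_seed": config.master_seed, "fold_plan": _sub_seed(config.master_seed, 0)},
        tap_registry_version=TAP_REGISTRY_VERSION,
        strategies=strategies,
        chosen_hypers=chosen,
        search_history=histories,
        predictions=predictions,
        failure=failure,
    )


def aggregate_case_level(report: EvaluationReport, manifest: DatasetManifest,
                         strategy: str) -> float:
    """Optional case-level accuracy: majority of image predictions per case."""
    by_case: dict[str, list[str]] = {}
    truth: dict[str, str] = manifest.case_labels
    image_case = {r.image_id: r.case_id for r in manifest.records}
    for p in report.predictions:
        if p["strategy"] != strategy:
            continue
        by_case.setdefault(image_case[p["image_id"]], []).append(p["prediction"])
    correct = 0
    for case, preds in by_case.items():
        n_mal = sum(1 for p in preds if p == LABEL_ORDER[1])
        pred = LABEL_ORDER[1] if 2 * n_mal >= len(preds) else LABEL_ORDER[0]
        correct += pred == truth[case]
    return correct / len(by_case)


def summarize(report: EvaluationReport) -> pd.DataFrame:
    """One row per test strategy, shaped like the published results tables."""
    cfg = report.config
    rows = []
    for strat, res in report.strategies.items():
        rows.append(
            {
                "feature_extractor": cfg["backbone"]["name"],
                "classifier": cfg["classifier"]["family"],
                "augmentation": f"{cfg['augmentation']['strategy']} "
                                f"{cfg['augmentation']['repeats']}x",
                "test_strategy": strat,
                "accuracy_mean": round(res.mean, 4),
                "accuracy_sd": round(res.sd, 4),
                "ppv": round(res.ppv, 4),
                "npv": round(res.npv, 4),
            }
        )
    return pd.DataFrame(rows)


def format_summary(report: EvaluationReport) -> str:
    frame = summarize(report)
    lines = [
        f"{r.feature_extractor} + {r.classifier} ({r.augmentation}, {r.test_strategy}): "
        f"accuracy {r.accuracy_mean:.3f} ± {r.accuracy_sd:.3f}, "
        f"PPV {r.ppv:.3f}, NPV {r.npv:.3f}"
        for r in frame.itertuples(index=False)
    ]
    return "\n".join(lines)
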