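import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from histocad.augment import AugmentationConfig
from histocad.backbones import BackboneSpec
from histocad.classify import ClassifierSpec
from histocad.evaluate import (
    EvaluationError,
    EvaluationReport,
    ExperimentConfig,
    FeatureTable,
    StrategyResult,
    aggregate_case_level,
    extract_feature_tables,
    majority_vote,
    make_fold_plan,
    run_experiment,
    summarize,
    tune,
    verify_no_leakage,
)
from histocad.manifest import DatasetManifest, ImageRecord


def _case_manifest(n_benign, n_malignant, images_per_case=1):
    records = []
    for label, n in (("benign", n_benign), ("malignant", n_malignant)):
        for c in range(n):
            cid = f"{label[0]}{c:02d}"
            for j in range(images_per_case):
                records.append(
                    ImageRecord(f"{cid}_{j}", f"{cid}_{j}.png", cid, label, 400, 8, 8)
                )
    return DatasetManifest(records=tuple(records), root=".", layout="flat-csv")


class TestFoldPlan:
    def test_44_cases_give_fold_sizes_9_9_9_9_8(self):
        m = _case_manifest(20, 24)
        plan = make_fold_plan(m, k=5, k_inner=5, seed=0)
        sizes = sorted(len(f) for f in plan.outer)
        assert sizes == [8, 9, 9, 9, 9]
        # label balance: each fold has 4 benign and 4-5 malignant
        for fold in plan.outer:
            n_b = sum(1 for u in fold if plan.unit_labels[u] == "benign")
            assert n_b == 4

    def test_no_case_overlap_anywhere(self):
        plan = make_fold_plan(_case_manifest(20, 24), seed=3)
        assert verify_no_leakage(plan) == 0

    def test_seed_determinism_and_sensitivity(self):
        m = _case_manifest(10, 10)
        assert make_fold_plan(m, seed=5) == make_fold_plan(m, seed=5)
        assert make_fold_plan(m, seed=5).outer != make_fold_plan(m, seed=6).outer

    def test_image_level_units_for_ungrouped_control(self):
        m = _case_manifest(4, 4, images_per_case=3)
        plan = make_fold_plan(m, k=4, k_inner=3, seed=0, group_by="image")
        assert len(plan.unit_labels) == 24
        assert verify_no_leakage(plan) == 0

    def test_fewer_cases_than_folds_is_fatal(self):
        with pytest.raises(EvaluationError, match="folds"):
            make_fold_plan(_case_manifest(2, 1), k=5)


class TestMajorityVote:
    def test_unanimous(self):
        assert majority_vote(np.full(10, 0.3)) == "malignant"
        assert majority_vote(np.full(10, -0.3)) == "benign"

    def test_seven_three(self):
        scores = np.array([1.0] * 7 + [-5.0] * 3)
        assert majority_vote(scores) == "malignant"

    def test_tie_goes_to_larger_absolute_score_sum(self):
        # 5 malignant at +0.1 vs 5 benign at -2: benign side dominates
        assert majority_vote(np.array([0.1] * 5 + [-2.0] * 5)) == "benign"
        assert majority_vote(np.array([2.0] * 5 + [-0.1] * 5)) == "malignant"

    def test_exact_zero_sum_tie_is_malignant(self):
        assert majority_vote(np.array([1.0] * 5 + [-1.0] * 5)) == "malignant"

    def test_vote_matches_brute_force_recount(self, rng):
        for _ in range(300):
            scores = rng.normal(size=10)
            n_mal = sum(1 for s in scores if s > 0)
            if n_mal > 5:
                expected = "malignant"
            elif n_mal < 5:
                expected = "benign"
            else:
                pos = sum(s for s in scores if s > 0)
                neg = -sum(s for s in scores if s <= 0)
                expected = "malignant" if pos >= neg else "benign"
            assert majority_vote(scores) == expected

    def test_single_score_is_its_sign(self):
        assert majority_vote(np.array([0.2])) == "malignant"
        assert majority_vote(np.array([-0.2])) == "benign"
        assert majority_vote(np.array([0.0])) == "benign"


def _toy_tables(rng, n_cases=8, per_case=4, effect=3.0):
    """Feature tables where class separation is along dimension 0."""
    rows, meta = [], []
    for c in range(n_cases):
        label = "benign" if c % 2 == 0 else "malignant"
        mu = -effect / 2 if label == "benign" else effect / 2
        for j in range(per_case):
            x = rng.normal(size=4)
            x[0] += mu
            iid = f"c{c}_{j}"
            rows.append(x)
            meta.append((iid, f"c{c}", label, 0, "train"))
    X = np.array(rows)
    df = pd.DataFrame(meta, columns=["image_id", "case_id", "label", "replicate", "crop_id"])
    train = FeatureTable(X, df)
    val = FeatureTable(X.copy(), df.assign(crop_id="center"))
    return train, val


class TestTune:
    def test_collapsed_space_returns_single_point(self, rng):
        train, val = _toy_tables(rng)
        spec = ClassifierSpec(family="linear_svm", hyper_space={"C": ("fixed", 0.5)})
        folds = (("c0", "c1"), ("c2", "c3"), ("c4", "c5"), ("c6", "c7"))
        best, history = tune(spec, train, val, folds, n_iter=5, seed=0)
        assert best == {"C": 0.5}
        assert len(history) == 5

    def test_better_candidate_wins(self, rng):
        """Direct evaluation oracle: of two C values, the higher-scoring one
        is chosen. A vanishingly small C underfits the separable toy."""
        train, val = _toy_tables(rng, effect=4.0)
        folds = (("c0", "c1"), ("c2", "c3"), ("c4", "c5"), ("c6", "c7"))
        scores = {}
        for c_val in (1e-9, 1.0):
            spec = ClassifierSpec(family="linear_svm",
                                  hyper_space={"C": ("fixed", c_val)})
            _, hist = tune(spec, train, val, folds, n_iter=1, seed=0)
            scores[c_val] = hist[0]["inner_accuracy"]
        assert scores[1.0] > scores[1e-9]
        spec = ClassifierSpec(family="linear_svm",
                              hyper_space={"C": ("choice", (1e-9, 1.0))})
        best, _ = tune(spec, train, val, folds, n_iter=12, seed=0)
        assert best["C"] == 1.0

    def test_same_seed_same_draws_and_choice(self, rng):
        train, val = _toy_tables(rng)
        spec = ClassifierSpec(family="linear_svm")
        folds = (("c0", "c1"), ("c2", "c3"), ("c4", "c5"), ("c6", "c7"))
        b1, h1 = tune(spec, train, val, folds, n_iter=4, seed=7)
        b2, h2 = tune(spec, train, val, folds, n_iter=4, seed=7)
        assert b1 == b2 and h1 == h2


def _report_with(accs, confusion):
    tp, fp, tn, fn = confusion
    res = StrategyResult(
        fold_accuracies=list(accs),
        mean=float(np.mean(accs)),
        sd=float(np.std(accs, ddof=1)),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        ppv=tp / (tp + fp),
        npv=tn / (tn + fn),
    )
    return EvaluationReport(
        config={"backbone": {"name": "stub"}, "classifier": {"family": "linear_svm"},
                "augmentation": {"strategy": "base", "repeats": 1}},
        config_hash="x", seeds={}, tap_registry_version=1,
        strategies={"center_crop": res}, chosen_hypers=[], search_history=[],
        predictions=[],
    )


class TestReporting:
    def test_mean_and_sample_sd_hand_arithmetic(self):
        report = _report_with([0.8, 0.9, 0.85, 0.8, 0.9], (9, 1, 8, 2))
        frame = summarize(report)
        assert len(frame) == 1
        row = frame.iloc[0]
        assert row["accuracy_mean"] == 0.85
        assert row["accuracy_sd"] == 0.05
        assert row["ppv"] == 0.9
        assert row["npv"] == 0.8

    def test_report_means_recompute_from_fold_values(self):
        report = _report_with([0.6, 0.7, 0.8], (5, 2, 6, 1))
        res = report.strategies["center_crop"]
        assert res.mean == pytest.approx(np.mean(res.fold_accuracies))
        assert res.sd == pytest.approx(np.std(res.fold_accuracies, ddof=1))


@pytest.fixture(scope="module")
def tiny_run(small_dataset, tmp_path_factory):
    _, manifest = small_dataset
    cfg = ExperimentConfig(
        backbone=BackboneSpec(name="stub", input_size=96),
        classifier=ClassifierSpec(family="linear_svm", seed=0),
        augmentation=AugmentationConfig(strategy="base", target_size=96,
                                        resize_edge=96),
        test_strategies=("center_crop", "ten_crop"),
        n_search_iter=3, k=3, k_inner=3, master_seed=21,
    )
    out = tmp_path_factory.mktemp("tinyrun")
    report = run_experiment(cfg, manifest, out_dir=out)
    return cfg, manifest, report, out


class TestRunExperiment:
    def test_report_structure_and_accuracy(self, tiny_run):
        cfg, manifest, report, out = tiny_run
        assert set(report.strategies) == {"center_crop", "ten_crop"}
        assert len(report.strategies["center_crop"].fold_accuracies) == 3
        # strongly separable conditions: the pipeline should do well
        assert report.strategies["center_crop"].mean >= 0.9
        assert report.failure is None
        assert len(report.chosen_hypers) == 3
        n_images = len(manifest)
        assert len(report.predictions) == n_images * 2

    def test_report_files_written(self, tiny_run):
        _, _, report, out = tiny_run
        data = json.loads((out / "report.json").read_text())
        assert data["config_hash"] == report.config_hash
        assert (out / "summary.csv").exists()

    def test_rerun_same_seed_is_byte_identical(self, tiny_run, tmp_path):
        cfg, manifest, _, out = tiny_run
        run_experiment(cfg, manifest, out_dir=tmp_path)
        assert (tmp_path / "report.json").read_bytes() == (out / "report.json").read_bytes()
        assert (tmp_path / "summary.csv").read_bytes() == (out / "summary.csv").read_bytes()

    def test_case_level_aggregation(self, tiny_run):
        _, manifest, report, _ = tiny_run
        acc = aggregate_case_level(report, manifest, "center_crop")
        assert 0.0 <= acc <= 1.0
        assert acc >= report.strategies["center_crop"].mean - 0.2

    def test_failure_is_flushed_and_named(self, small_dataset, tmp_path):
        _, manifest = small_dataset
        cfg = ExperimentConfig(
            backbone=BackboneSpec(name="stub", input_size=96),
            classifier=ClassifierSpec(
                family="linear_svm", hyper_space={"C": ("bogus_kind", 1)}
            ),
            augmentation=AugmentationConfig(strategy="base", target_size=96,
                                            resize_edge=96),
            test_strategies=("center_crop",), n_search_iter=2, k=3, k_inner=3,
            master_seed=0,
        )
        with pytest.raises(EvaluationError, match="fold 0: tuning"):
            run_experiment(cfg, manifest, out_dir=tmp_path)
        data = json.loads((tmp_path / "report.json").read_text())
        assert data["failure"]["stage"] == "fold 0: tuning"


class TestConfigValidation:
    def test_target_size_must_match_backbone_input(self):
        with pytest.raises(ValueError, match="target_size"):
            ExperimentConfig(
                backbone=BackboneSpec(name="stub", input_size=96),
                augmentation=AugmentationConfig(target_size=64, resize_edge=96),
            )

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategies"):
            ExperimentConfig(
                backbone=BackboneSpec(name="stub", input_size=96),
                augmentation=AugmentationConfig(target_size=96, resize_edge=96),
                test_strategies=("five_crop",),
            )


def test_feature_tables_are_fold_independent(small_dataset):
    """Same master seed, different grouping: identical features."""
    _, manifest = small_dataset
    mk = lambda group_by: ExperimentConfig(
        backbone=BackboneSpec(name="stub", input_size=96),
        augmentation=AugmentationConfig(strategy="base", target_size=96, resize_edge=96),
        test_strategies=("center_crop",),
        group_by=group_by, master_seed=4, k=3, k_inner=3,
    )
    a = extract_feature_tables(mk("case"), manifest)
    b = extract_feature_tables(mk("image"), manifest)
    assert np.array_equal(a["train"].X, b["train"].X)
    assert np.array_equal(a["test"].X, b["test"].X)
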