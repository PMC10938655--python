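import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    confusion_matrix as sk_confusion_matrix,
    precision_recall_fscore_support,
)

import flowstarve as fs
from flowstarve.classifiers import (
    LABEL_TO_INT,
    ModelConfig,
    _table_xy,
    build_model,
    fit,
    predict_labels,
)
from flowstarve.io import SEVERITY_CLASSES


def separable_table(n_per_class=100, seed=0):
    """Three cleanly separated synthetic Paw shapes, one per class."""
    rng = np.random.default_rng(seed)
    base = np.linspace(10.0, 20.0, 80)  # passive-like rising ramp
    dip = np.sin(np.linspace(0, np.pi, 80))
    rows, labels = [], []
    for k, cls in enumerate(SEVERITY_CLASSES):
        amp = [0.5, 7.0, 15.0][k]
        for _ in range(n_per_class):
            rows.append(base - amp * dip + rng.normal(0, 0.4, 80))
            labels.append(cls)
    ids = [f"b{i}" for i in range(len(rows))]
    return fs.make_breath_table(
        ids, ["p"] * len(rows), np.array(rows), label=labels
    )


class TestModelConstruction:
    def test_recurrent_parameter_count_closed_form(self):
        model = build_model(ModelConfig(architecture="recurrent", seed=0))
        h = 128
        expected = 4 * h * (1 + h + 1) + 4 * h * (h + h + 1) + (h * 3 + 3)
        assert model.n_parameters() == expected

    def test_probabilities_normalized(self, rng):
        for arch in ("recurrent", "conv1d"):
            model = build_model(ModelConfig(architecture=arch, seed=1))
            p = fs.predict_proba(model, rng.normal(15, 3, (7, 80)))
            assert p.shape == (7, 3)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inconsistent_conv_config_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            ModelConfig(
                architecture="conv1d", conv_channels=(16, 32),
                conv_kernel_sizes=(5,),
            )


class TestTraining:
    def test_separable_fixture_learned(self):
        table = separable_table(n_per_class=100)
        x, y = _table_xy(table)
        for arch in ("conv1d", "recurrent"):
            cfg = ModelConfig(architecture=arch, epochs=10, seed=3)
            model = build_model(cfg)
            fit(model, x, y, cfg)
            acc = 100.0 * np.mean(predict_labels(model, x) == y)
            assert acc > 95.0, arch

    def test_single_class_degenerate_optimum(self):
        table = separable_table(n_per_class=40)
        table = table[table.label == "moderate"].reset_index(drop=True)
        cfg = ModelConfig(architecture="conv1d", epochs=5, seed=0,
                          early_stopping=False)
        model = build_model(cfg)
        x, y = _table_xy(table)
        fit(model, x, y, cfg)
        assert (predict_labels(model, x) == LABEL_TO_INT["moderate"]).all()

    def test_training_is_deterministic(self):
        table = separable_table(n_per_class=30)
        x, y = _table_xy(table)
        losses = []
        for _ in range(2):
            cfg = ModelConfig(architecture="conv1d", epochs=4, seed=11)
            model = build_model(cfg)
            _, log = fit(model, x, y, cfg)
            losses.append(log[-1]["train_loss"])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_unlabeled_rows_rejected(self):
        table = separable_table(n_per_class=5)
        table.loc[3, "label"] = None
        cfg = ModelConfig(architecture="conv1d", epochs=1)
        with pytest.raises(ValueError, match="unlabeled"):
            fs.train_model(build_model(cfg), table, cfg)


class TestPredictBreath:
    def test_tie_breaks_toward_severe(self):
        from flowstarve.classifiers import _argmax_severe

        assert _argmax_severe(np.array([[1 / 3, 1 / 3, 1 / 3]]))[0] == 2
        assert _argmax_severe(np.array([[0.4, 0.4, 0.2]]))[0] == 1
        assert _argmax_severe(np.array([[0.1, 0.2, 0.7]]))[0] == 2

    def test_non_finite_input_rejected(self):
        model = build_model(ModelConfig(architecture="conv1d", seed=0))
        x = np.full(80, 10.0)
        x[5] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fs.predict_breath(model, x)

    def test_held_out_passive_breath_classified_normal(self):
        table = separable_table(n_per_class=80, seed=1)
        cfg = ModelConfig(architecture="conv1d", epochs=10, seed=2)
        model = build_model(cfg)
        x, y = _table_xy(table)
        fit(model, x, y, cfg)
        fresh = np.linspace(10.0, 20.0, 80) - 0.5 * np.sin(np.linspace(0, np.pi, 80))
        label, probs = fs.predict_breath(model, fresh)
        assert label == "normal_mild"
        assert probs.argmax() == 0


class TestCapBreathsPerPatient:
    def test_oversized_stratum_capped(self, rng):
        x = rng.normal(10, 1, (400, 80))
        table = fs.make_breath_table(
            [f"b{i}" for i in range(400)], ["p1"] * 400, x, label=["severe"] * 400
        )
        capped = fs.cap_breaths_per_patient(table, cap=350, seed=4)
        assert len(capped) == 350

    def test_small_strata_untouched_and_deterministic(self, rng):
        x = rng.normal(10, 1, (30, 80))
        labels = ["normal_mild"] * 10 + ["moderate"] * 10 + ["severe"] * 10
        table = fs.make_breath_table(
            [f"b{i}" for i in range(30)], ["p1"] * 30, x, label=labels
        )
        out1 = fs.cap_breaths_per_patient(table, cap=350, seed=1)
        out2 = fs.cap_breaths_per_patient(table, cap=350, seed=1)
        pd.testing.assert_frame_equal(out1, table)
        pd.testing.assert_frame_equal(out1, out2)


class TestConfusionMatrixAndMetrics:
    def test_perfect_prediction_is_diagonal(self):
        y = ["normal_mild", "moderate", "severe"] * 4
        cm = fs.confusion_matrix(y, y)
        assert np.trace(cm) == 12 and cm.sum() == 12

    def test_matches_sklearn_tally(self, rng):
        t = rng.integers(0, 3, 500)
        p = rng.integers(0, 3, 500)
        np.testing.assert_array_equal(
            fs.confusion_matrix(t, p), sk_confusion_matrix(t, p, labels=[0, 1, 2])
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            fs.confusion_matrix(["mystery"], ["severe"])

    def test_metrics_match_sklearn_oracle(self, rng):
        t = rng.integers(0, 3, 400)
        p = rng.integers(0, 3, 400)
        cm = fs.confusion_matrix(t, p)
        m = fs.classification_metrics(cm)
        prec, rec, f1, _ = precision_recall_fscore_support(
            t, p, labels=[0, 1, 2], average="weighted", zero_division=0
        )
        assert m["accuracy"] == pytest.approx(100.0 * np.mean(t == p), abs=1e-12)
        assert m["precision"] == pytest.approx(100.0 * prec, abs=1e-9)
        assert m["recall"] == pytest.approx(100.0 * rec, abs=1e-9)
        assert m["f1"] == pytest.approx(100.0 * f1, abs=1e-9)

    def test_identity_matrix_metrics(self):
        m = fs.classification_metrics(np.diag([10, 20, 30]))
        assert m["accuracy"] == 100.0 and m["f1"] == 100.0


class TestRepeatedHoldout:
    def test_validation_size_arithmetic(self):
        table = separable_table(n_per_class=10)
        cfg = ModelConfig(architecture="conv1d", epochs=1, early_stopping=False)
        report = fs.repeated_holdout_evaluate(table, cfg, n_repetitions=2, seed=0)
        for rep in report.per_repetition:
            assert rep["confusion_matrix"].sum() == 6  # 20% of 30, stratified

    def test_median_matches_order_statistic_oracle(self):
        table = separable_table(n_per_class=15)
        cfg = ModelConfig(architecture="conv1d", epochs=2, early_stopping=False)
        report = fs.repeated_holdout_evaluate(table, cfg, n_repetitions=5, seed=1)
        accs = sorted(r["accuracy"] for r in report.per_repetition)
        assert report.median_metrics["accuracy"] == accs[2]  # middle of 5

    def test_missing_class_rejected(self):
        table = separable_table(n_per_class=10)
        table = table[table.label != "moderate"].reset_index(drop=True)
        cfg = ModelConfig(architecture="conv1d", epochs=1)
        with pytest.raises(ValueError, match="absent"):
            fs.repeated_holdout_evaluate(table, cfg, n_repetitions=1)


class TestLearningCurve:
    def test_full_size_consistent_and_errors(self):
        table = separable_table(n_per_class=12)
        cfg = ModelConfig(architecture="conv1d", epochs=2, early_stopping=False)
        points = fs.learning_curve(table, cfg, [len(table)], n_repetitions=2, seed=3)
        report = fs.repeated_holdout_evaluate(table, cfg, n_repetitions=2, seed=3)
        assert points[0] == (36, report.median_metrics["accuracy"])
        with pytest.raises(ValueError, match="exceeds"):
            fs.learning_curve(table, cfg, [1000], n_repetitions=1)
        with pytest.raises(ValueError, match="too small"):
            fs.learning_curve(table, cfg, [3], n_repetitions=1)
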