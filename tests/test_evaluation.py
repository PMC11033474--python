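import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, cohen_kappa_score, recall_score

from ramanid import (BaseModelSpec, ConfusionMatrix, compute_metrics,
                     confusion_report, repeated_cv, split_train_test)

from conftest import make_set, tiny_config
from ramanid.synthetic import generate_ramanome
from ramanid.preprocess import preprocess_set


def grid_set(n_per_class, n_classes=9, seed=0):
    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    species = np.repeat([f"sp{i}" for i in range(n_classes)], n_per_class)
    return make_set(rng.normal(size=(n, 4)), axis=[600, 700, 800, 900],
                    species=list(species))


class TestSplit:
    def test_seventy_thirty_arithmetic(self):
        s = grid_set(100)
        train, test = split_train_test(s, 0.7, seed=0)
        assert train.n_cells == 630 and test.n_cells == 270
        counts = pd.Series(train.species).value_counts()
        assert (counts == 70).all()

    def test_floor_rule_on_small_class(self):
        s = grid_set(10, n_classes=2)
        train, test = split_train_test(s, 0.7, seed=0)
        assert train.n_cells == 14 and test.n_cells == 6

    def test_disjoint_exhaustive_and_seed_deterministic(self):
        s = grid_set(20, n_classes=3)
        tr1, te1 = split_train_test(s, 0.7, seed=5)
        tr2, te2 = split_train_test(s, 0.7, seed=5)
        assert tr1.labels["cell_id"].tolist() == tr2.labels["cell_id"].tolist()
        ids = set(tr1.labels["cell_id"]) | set(te1.labels["cell_id"])
        assert len(ids) == s.n_cells
        assert not set(tr1.labels["cell_id"]) & set(te1.labels["cell_id"])

    def test_rejects_bad_fraction_and_tiny_class(self):
        s = grid_set(10, n_classes=2)
        with pytest.raises(ValueError):
            split_train_test(s, 1.0)
        one = make_set([[1, 2], [3, 4]], axis=[600, 700], species=["A", "B"])
        with pytest.raises(ValueError, match="fewer than 2"):
            split_train_test(one, 0.7)


class TestComputeMetrics:
    def test_perfect_diagonal_matrix(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]), np.array(["a", "b", "c"]))
        m = compute_metrics(cm)
        assert m.accuracy == 100.0
        assert m.mean_sensitivity == 100.0
        assert m.mean_specificity == 100.0
        assert m.kappa == 1.0

    def test_binary_hand_computation(self):
        cm = ConfusionMatrix(np.array([[45, 5], [10, 40]]),
                             np.array(["a", "b"]))
        m = compute_metrics(cm)
        assert m.accuracy == pytest.approx(85.0)
        # p0 = 0.85; pe = (50*55 + 50*45) / 100^2 = 0.5
        assert m.kappa == pytest.approx((0.85 - 0.5) / 0.5, abs=1e-12)

    def test_independent_predictions_have_near_zero_kappa(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 100_000)
        y_pred = rng.integers(0, 4, 100_000)
        cm = ConfusionMatrix.from_labels(y_true, y_pred, classes=np.arange(4))
        assert abs(compute_metrics(cm).kappa) < 0.02

    def test_oracle_equivalence_on_random_matrices(self):
        # per-sample recomputation with scikit-learn as the independent oracle
        rng = np.random.default_rng(1)
        for _ in range(100):
            C = int(rng.integers(2, 6))
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, C, n)
            y_pred = rng.integers(0, C, n)
            classes = np.arange(C)
            m = compute_metrics(ConfusionMatrix.from_labels(y_true, y_pred,
                                                            classes))
            assert m.accuracy == pytest.approx(
                100 * accuracy_score(y_true, y_pred), abs=1e-9)
            present = np.unique(y_true)
            assert m.mean_sensitivity == pytest.approx(
                100 * recall_score(y_true, y_pred, labels=present,
                                   average="macro", zero_division=0), abs=1e-9)
            assert m.kappa == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-9)
            # brute-force one-vs-rest specificity
            specs = []
            for c in classes:
                tn = np.sum((y_true != c) & (y_pred != c))
                fp = np.sum((y_true != c) & (y_pred == c))
                if tn + fp:
                    specs.append(tn / (tn + fp))
            assert m.mean_specificity == pytest.approx(
                100 * np.mean(specs), abs=1e-9)

    def test_kappa_bounds_and_degenerate_definition(self):
        worst = ConfusionMatrix(np.array([[0, 10], [10, 0]]),
                                np.array(["a", "b"]))
        assert compute_metrics(worst).kappa == pytest.approx(-1.0)
        single = ConfusionMatrix(np.array([[5, 0], [0, 0]]),
                                 np.array(["a", "b"]))
        assert compute_metrics(single).kappa == 1.0
        wrong = ConfusionMatrix(np.array([[0, 0], [5, 0]]),
                                np.array(["a", "b"]))
        assert compute_metrics(wrong).kappa == 0.0

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), dtype=int), np.array(["a", "b"]))
        with pytest.raises(ValueError):
            compute_metrics(cm)


class TestConfusionReport:
    def test_row_rates_match_narrative_counts(self):
        # 84/2/1 correct/misclassified counts reproduce 96.55/2.30/1.15 %
        cm = ConfusionMatrix(np.array([[84, 2, 1], [0, 5, 0], [0, 0, 5]]),
                             np.array(["r", "p", "q"]))
        rep = confusion_report(cm)
        assert rep.loc["r", "TPR%"] == pytest.approx(96.55, abs=0.005)
        assert rep.loc["r", "FNR%"] == pytest.approx(3.45, abs=0.005)
        assert 100 * 2 / 87 == pytest.approx(2.30, abs=0.005)
        assert 100 * 1 / 87 == pytest.approx(1.15, abs=0.005)

    def test_identity_matrix_perfect_margins(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int), np.array(["a", "b", "c"]))
        rep = confusion_report(cm)
        assert (rep.loc[["a", "b", "c"], "TPR%"] == 100.0).all()
        assert (rep.loc["PPV%", ["a", "b", "c"]] == 100.0).all()
        assert (rep.loc["FDR%", ["a", "b", "c"]] == 0.0).all()

    def test_never_predicted_class_has_undefined_ppv(self):
        cm = ConfusionMatrix(np.array([[2, 0], [3, 0]]), np.array(["a", "b"]))
        rep = confusion_report(cm)
        assert np.isnan(rep.loc["PPV%", "b"])
        assert np.isnan(rep.loc["FDR%", "b"])


@pytest.fixture(scope="module")
def easy_set():
    return preprocess_set(generate_ramanome(
        tiny_config(cells=8, seed=2, noise_sd=0.005,
                    amplitude_jitter_cv=0.02)))


class TestRepeatedCV:

    def test_record_count_is_repeats_times_folds_per_model(self, easy_set):
        specs = [BaseModelSpec(name="KNN", seed=0),
                 BaseModelSpec(name="LDA", seed=0)]
        report = repeated_cv(easy_set, specs, repeats=2, folds=2, seed=0, k=1)
        counts = report.records.groupby("model").size()
        assert (counts == 4).all()
        assert set(counts.index) == {"KNN", "LDA", "EMC"}

    def test_near_perfect_classifier_scores_perfectly(self, easy_set):
        specs = [BaseModelSpec(name="KNN", seed=0)]
        report = repeated_cv(easy_set, specs, repeats=1, folds=2, seed=0, k=1)
        knn = report.records[report.records.model == "KNN"]
        assert (knn.accuracy == 100.0).all()
        assert (knn.kappa == 1.0).all()

    def test_pooled_confusion_covers_every_cell_each_repeat(self, easy_set):
        specs = [BaseModelSpec(name="KNN", seed=0)]
        report = repeated_cv(easy_set, specs, repeats=2, folds=2, seed=0, k=1)
        assert report.confusion.total == 2 * easy_set.n_cells

    def test_class_smaller_than_fold_count_rejected(self, easy_set):
        with pytest.raises(ValueError, match="cells"):
            repeated_cv(easy_set, [BaseModelSpec(name="KNN")], repeats=1,
                        folds=easy_set.n_cells, seed=0)

    def test_report_files_written(self, easy_set, tmp_path):
        specs = [BaseModelSpec(name="KNN", seed=0)]
        report = repeated_cv(easy_set, specs, repeats=1, folds=2, seed=0, k=1)
        report.write(tmp_path)
        assert (tmp_path / "records.csv").exists()
        assert (tmp_path / "summary.csv").exists()
        assert (tmp_path / "confusion.csv").exists()
        summary = pd.read_csv(tmp_path / "summary.csv")
        assert {"median", "q1", "q3"} <= set(summary.columns)
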