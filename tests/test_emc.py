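import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ramanid import (BaseModelSpec, TrainedModel, TrainedModelSuite,
                     build_base_model, build_emc, compute_weights,
                     ensemble_predict, ensemble_predict_proba, select_top_k)
from ramanid.emc import EnsembleModel

# Published single-model accuracies of the five ensemble members
# (CNN, LSTM, SVM, RF, KNN) used as a hand-arithmetic oracle.
MEMBER_ACCURACIES = [93.64, 92.07, 84.32, 82.45, 80.76]


class _FixedProba:
    """Stub classifier emitting a constant probability matrix."""

    def __init__(self, P, classes):
        self._P = np.asarray(P, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return np.tile(self._P, (len(X), 1))[: len(X)]


def stub_model(name, P, classes=("A", "B")):
    classes = np.asarray(classes)
    return TrainedModel(spec=BaseModelSpec(name=name), classes=classes,
                        impl=_FixedProba(P, classes))


class TestComputeWeights:
    def test_published_accuracies_normalize_to_unit_sum(self):
        w = compute_weights(MEMBER_ACCURACIES)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[0] == pytest.approx(93.64 / 433.24, abs=1e-12)
        assert round(float(w[0]), 5) == 0.21614

    def test_equal_accuracies_give_equal_weights(self):
        assert np.allclose(compute_weights([80, 80]), [0.5, 0.5])

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(1.0, 100.0), min_size=1, max_size=8),
           st.floats(0.1, 10.0))
    def test_scale_invariance_and_order(self, acc, c):
        w = compute_weights(acc)
        assert np.allclose(w, compute_weights([c * a for a in acc]), atol=1e-9)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        # weights ordered like the accuracies (ties allowed)
        for i, j in itertools.combinations(range(len(acc)), 2):
            assert (acc[i] - acc[j]) * (w[i] - w[j]) >= 0

    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            compute_weights([])
        with pytest.raises(ValueError):
            compute_weights([50.0, 0.0])


class TestSelection:
    def make_suite(self, accs):
        # one stub per base learner, in canonical registry order
        names = ("LDA", "PLS-DA", "XGBoost", "KNN", "RF", "SVM", "LSTM", "CNN")
        models = [stub_model(n, [[0.5, 0.5]]) for n in names]
        return TrainedModelSuite(models=models, val_accuracy=list(accs))

    def test_published_accuracies_select_the_five_members(self):
        suite = self.make_suite([70.41, 73.11, 76.59, 80.76, 82.45, 84.32,
                                 92.07, 93.64])
        ens = select_top_k(suite, k=5)
        assert set(ens.member_names) == {"CNN", "LSTM", "SVM", "RF", "KNN"}

    def test_k_one_selects_single_best(self):
        suite = self.make_suite([10, 20, 30, 40, 50, 60, 70, 99])
        ens = select_top_k(suite, k=1)
        assert ens.member_names == ["CNN"]

    def test_rank_tie_breaks_by_canonical_name_order(self):
        # KNN and RF tied at the k-th rank: KNN is earlier in registry order
        suite = self.make_suite([99, 98, 97, 80, 80, 96, 10, 10])
        ens = select_top_k(suite, k=5)
        assert "KNN" in ens.member_names and "RF" not in ens.member_names

    def test_weights_renormalized_over_selected_members(self):
        suite = self.make_suite([70.41, 73.11, 76.59, 80.76, 82.45, 84.32,
                                 92.07, 93.64])
        ens = build_emc(suite, k=5)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)
        by_name = dict(zip(ens.member_names, ens.weights))
        assert by_name["CNN"] == pytest.approx(93.64 / 433.24, abs=1e-12)

    def test_k_out_of_range(self):
        suite = self.make_suite(range(1, 9))
        with pytest.raises(ValueError):
            select_top_k(suite, k=0)
        with pytest.raises(ValueError):
            select_top_k(suite, k=9)


class TestFusion:
    def test_two_member_hand_arithmetic(self):
        e = EnsembleModel(
            members=[stub_model("KNN", [[1.0, 0.0]]),
                     stub_model("RF", [[0.0, 1.0]])],
            weights=[0.6, 0.4], classes=np.array(["A", "B"]))
        P = ensemble_predict_proba(e, np.zeros((1, 3)))
        assert np.allclose(P, [[0.6, 0.4]])
        assert list(ensemble_predict(e, np.zeros((1, 3)))) == ["A"]

    def test_unanimous_members_unchanged_by_any_weights(self):
        P0 = [[0.2, 0.3, 0.5]]
        e = EnsembleModel(
            members=[stub_model(n, P0, classes=("A", "B", "C"))
                     for n in ("KNN", "RF", "SVM")],
            weights=[0.5, 0.3, 0.2], classes=np.array(["A", "B", "C"]))
        assert np.allclose(ensemble_predict_proba(e, np.zeros((2, 4))), P0)

    def test_three_member_fusion_matches_brute_force(self):
        rng = np.random.default_rng(0)
        mats, members = [], []
        for name in ("KNN", "RF", "SVM"):
            P = rng.dirichlet(np.ones(3), size=1)
            mats.append(P)
            members.append(stub_model(name, P, classes=("A", "B", "C")))
        w = np.array([0.2, 0.5, 0.3])
        e = EnsembleModel(members=members, weights=w,
                          classes=np.array(["A", "B", "C"]))
        expected = sum(wi * Pi for wi, Pi in zip(w, mats))
        assert np.allclose(ensemble_predict_proba(e, np.zeros((1, 2))), expected)

    def test_tied_fused_probabilities_break_to_first_class(self):
        e = EnsembleModel(members=[stub_model("KNN", [[0.5, 0.5]])],
                          weights=[1.0], classes=np.array(["A", "B"]))
        assert list(ensemble_predict(e, np.zeros((1, 2)))) == ["A"]

    def test_member_class_mismatch_rejected(self):
        with pytest.raises(ValueError, match="class"):
            EnsembleModel(
                members=[stub_model("KNN", [[1, 0]], classes=("A", "B")),
                         stub_model("RF", [[1, 0]], classes=("A", "C"))],
                weights=[0.5, 0.5], classes=np.array(["A", "B"]))


class TestOnRealModels:
    def test_k1_ensemble_equals_its_member(self, tiny_ramanome):
        X, y = tiny_ramanome.intensities, tiny_ramanome.species
        model = build_base_model(BaseModelSpec(name="KNN", seed=0)).fit(X, y)
        suite = TrainedModelSuite(models=[model], val_accuracy=[90.0])
        ens = build_emc(suite, k=1)
        assert np.array_equal(ens.predict(X), model.predict(X))
        assert np.allclose(ens.predict_proba(X), model.predict_proba(X))

    def test_fused_rows_stochastic_and_save_load_round_trip(
            self, tiny_ramanome, tmp_path):
        X, y = tiny_ramanome.intensities, tiny_ramanome.species
        specs = [BaseModelSpec(name=n, seed=0) for n in ("KNN", "RF", "LDA")]
        models = [build_base_model(sp).fit(X, y) for sp in specs]
        suite = TrainedModelSuite(models=models, val_accuracy=[90.0, 85.0, 70.0])
        ens = build_emc(suite, k=2)
        P = ens.predict_proba(X)
        assert np.all(P >= 0) and np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
        ens.save(tmp_path / "ens")
        back = EnsembleModel.load(tmp_path / "ens")
        assert np.allclose(back.predict_proba(X), P)
        assert back.member_names == ens.member_names
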