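"""The bank of eight base spectrum classifiers behind one probabilistic contract.

Six classical learners — linear discriminant analysis (LDA), linear support
vector machine (SVM, Platt-calibrated probabilities), random forest (RF),
extreme gradient boosting (XGBoost), k-nearest neighbours (KNN, neighbour
vote fractions as probabilities) and partial least squares discriminant
analysis (PLS-DA) — plus two small deep learners over the wavenumber axis
(a 1-D CNN and an LSTM, NumPy implementations from :mod:`ramanid.nn`).

Every fitted model honours the same contract: ``predict_proba(X)`` returns
an (n, C) row-stochastic matrix over a shared, sorted class order, and
``predict(X)`` is its argmax.  That uniformity is what lets the ensemble
meta-classifier fuse them by weighted probability summation.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .io import SpectrumSet
from .nn import CNN1D, LSTMNet

__all__ = [
    "MODEL_NAMES",
    "BaseModelSpec",
    "TrainedModel",
    "TrainedModelSuite",
    "build_base_model",
    "fit_plsda",
    "train_and_validate_suite",
    "default_specs",
]

#: Canonical model-name order; also the documented tie-break order wherever
#: two models compare equal (earlier name wins).
MODEL_NAMES = ("LDA", "PLS-DA", "XGBoost", "KNN", "RF", "SVM", "LSTM", "CNN")


@dataclass(frozen=True)
class BaseModelSpec:
    """Name + hyperparameters + seed of one base learner."""

    name: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")


def default_specs(seed: int = 0, include_deep: bool = True) -> list[BaseModelSpec]:
    """One spec per base learner with default hyperparameters."""
    names = MODEL_NAMES if include_deep else MODEL_NAMES[:6]
    return [BaseModelSpec(name=n, seed=seed) for n in names]


class PLSDAModel:
    """Partial least squares discriminant analysis.

    One-hot encodes the class labels, fits a PLS2 regression of the
    indicator matrix on the spectra, and turns predicted responses into
    class probabilities with a softmax; the predicted class is the argmax
    (equivalently, the largest predicted indicator response).
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PLSDAModel":
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("PLS-DA needs at least 2 classes")
        ncomp = min(self.n_components, X.shape[0] - 1, X.shape[1])
        if ncomp < 1:
            raise ValueError("n_components out of range for this data")
        Y = (np.asarray(y)[:, None] == self.classes_[None, :]).astype(float)
        self._pls = PLSRegression(n_components=ncomp, scale=False)
        self._pls.fit(X, Y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        R = self._pls.predict(np.asarray(X, dtype=float))
        R = R - R.max(axis=1, keepdims=True)
        E = np.exp(R)
        return E / E.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class _EncodedNet:
    """Adapter giving the NumPy nets a string-label sklearn-like surface."""

    def __init__(self, net):
        self._net = net

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        codes = np.searchsorted(self.classes_, y)
        self._net.fit(X, codes, n_classes=self.classes_.size)
        return self

    def predict_proba(self, X):
        return self._net.predict_proba(X)

    def predict(self, X):
        return self.classes_[self._net.predict(X).astype(int)]


class _EncodedXGB:
    """XGBoost with string labels mapped to integer codes."""

    def __init__(self, **kw):
        self._xgb = XGBClassifier(**kw)

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self._xgb.fit(X, np.searchsorted(self.classes_, y))
        return self

    def predict_proba(self, X):
        return self._xgb.predict_proba(X)

    def predict(self, X):
        return self.classes_[self._xgb.predict(X).astype(int)]


def _factory(name: str, hp: dict, seed: int):
    if name == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    if name == "SVM":
        hp = {"kernel": "linear", "C": 1.0, **hp}
        # Platt-style sigmoid calibration turns SVM margins into probabilities
        return CalibratedClassifierCV(SVC(random_state=seed, **hp),
                                      method="sigmoid", cv=5, ensemble=False)
    if name == "RF":
        hp = {"n_estimators": 100, **hp}
        return RandomForestClassifier(random_state=seed, **hp)
    if name == "KNN":
        hp = {"n_neighbors": 5, **hp}
        return KNeighborsClassifier(**hp)
    if name == "XGBoost":
        hp = {"n_estimators": 60, "max_depth": 4, "tree_method": "hist",
              "n_jobs": 1, **hp}
        return _EncodedXGB(random_state=seed, **hp)
    if name == "PLS-DA":
        return PLSDAModel(**hp)
    if name == "CNN":
        return _EncodedNet(CNN1D(seed=seed, **hp))
    if name == "LSTM":
        return _EncodedNet(LSTMNet(seed=seed, **hp))
    raise ValueError(f"unknown model {name!r}")


@dataclass(eq=False)
class TrainedModel:
    """A fitted base learner with its class order and probability output."""

    spec: BaseModelSpec
    classes: np.ndarray
    impl: object

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        P = np.asarray(self.impl.predict_proba(X), dtype=float)
        impl_classes = np.asarray(self.impl.classes_)
        if not np.array_equal(impl_classes, self.classes):
            # remap columns onto the canonical (sorted) class order
            order = np.searchsorted(self.classes, impl_classes)
            Q = np.zeros((P.shape[0], self.classes.size))
            Q[:, order] = P
            P = Q
        return P

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax takes the first maximum: ties break to the earlier class
        return self.classes[self.predict_proba(X).argmax(axis=1)]


class UntrainedModel:
    """Factory handle returned by build_base_model; fit() yields a TrainedModel."""

    def __init__(self, spec: BaseModelSpec):
        self.spec = spec

    def fit(self, X: np.ndarray, y: np.ndarray) -> TrainedModel:
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        impl = _factory(self.spec.name, dict(self.spec.hyperparams), self.spec.seed)
        impl.fit(np.asarray(X, dtype=float), y)
        return TrainedModel(spec=self.spec, classes=np.unique(y), impl=impl)


def build_base_model(spec: BaseModelSpec) -> UntrainedModel:
    """Instantiate an untrained base learner from its spec."""
    _factory(spec.name, dict(spec.hyperparams), spec.seed)  # validate eagerly
    return UntrainedModel(spec)


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int = 10) -> TrainedModel:
    """Fit the PLS-DA learner directly (convenience around the bank)."""
    spec = BaseModelSpec(name="PLS-DA", hyperparams={"n_components": n_components})
    return UntrainedModel(spec).fit(X, y)


@dataclass(eq=False)
class TrainedModelSuite:
    """Fitted base learners plus their held-out validation accuracies (%)."""

    models: list[TrainedModel]
    val_accuracy: list[float]

    def __post_init__(self) -> None:
        if len(self.models) != len(self.val_accuracy):
            raise ValueError("one accuracy per model required")
        if any(not 0 <= a <= 100 for a in self.val_accuracy):
            raise ValueError("accuracies must be percentages in [0, 100]")

    @property
    def names(self) -> list[str]:
        return [m.spec.name for m in self.models]

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"models": [], "val_accuracy": self.val_accuracy}
        for i, m in enumerate(self.models):
            state = directory / f"model_{i}_{m.spec.name}.pkl"
            with open(state, "wb") as fh:
                pickle.dump(m, fh)
            meta["models"].append({
                "name": m.spec.name, "hyperparams": m.spec.hyperparams,
                "seed": m.spec.seed, "classes": [str(c) for c in m.classes],
                "state_file": state.name})
        (directory / "suite.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModelSuite":
        directory = Path(directory)
        meta = json.loads((directory / "suite.json").read_text())
        models = []
        for entry in meta["models"]:
            with open(directory / entry["state_file"], "rb") as fh:
                models.append(pickle.load(fh))
        return cls(models=models, val_accuracy=meta["val_accuracy"])


def train_and_validate_suite(train: SpectrumSet,
                             specs: list[BaseModelSpec] | None = None,
                             val_fraction: float = 0.2,
                             seed: int = 0,
                             accuracy_data: tuple[np.ndarray, np.ndarray] | None = None,
                             ) -> TrainedModelSuite:
    """Fit every base learner and measure its validation accuracy.

    The training set is split (stratified by species) into a fit part and an
    internal validation part; each model is fitted on the fit part and its
    ``val_accuracy`` is the percentage correct on the validation part.
    Those accuracies later become the ensemble weights, so by default they
    come from data the ensemble's test set never sees.

    ``accuracy_data=(X, y)`` overrides the internal split: models are fitted
    on the full training set and accuracies measured on the given data
    instead.  Passing the test set here reproduces protocols that weight by
    test-set accuracy, at the price of leaking test labels into the ensemble.
    """
    specs = specs if specs is not None else default_specs(seed=seed)
    X = train.intensities
    y = train.species
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 species")
    if accuracy_data is None:
        if not 0 < val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        X_fit, X_val, y_fit, y_val = train_test_split(
            X, y, test_size=val_fraction, stratify=y, random_state=seed)
    else:
        X_fit, y_fit = X, y
        X_val, y_val = accuracy_data
    models, accs = [], []
    for spec in specs:
        model = build_base_model(spec).fit(X_fit, y_fit)
        accs.append(100.0 * float(np.mean(model.predict(X_val) == y_val)))
        models.append(model)
    return TrainedModelSuite(models=models, val_accuracy=accs)
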