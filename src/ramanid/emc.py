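"""Accuracy-weighted ensemble meta-classifier (EMC).

The combiner works in four steps:

1. measure each base classifier's accuracy on held-out data;
2. keep the top-K models by accuracy (default K = 5);
3. weight each kept model by its normalized accuracy,
   ``w_n = acc_n / sum(acc_1 ... acc_K)``;
4. fuse per-class probabilities by weighted summation,
   ``P(class j) = sum_n w_n * P_n(class j)``, and predict the argmax class.

Because the weights are a convex combination and each member emits a
row-stochastic probability matrix, the fused matrix is row-stochastic by
construction — no renormalization step is needed.  Weights are computed
over the selected members only (renormalized after selection).
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifiers import MODEL_NAMES, TrainedModel, TrainedModelSuite

__all__ = [
    "EnsembleModel",
    "compute_weights",
    "select_top_k",
    "build_emc",
    "ensemble_predict_proba",
    "ensemble_predict",
]


def compute_weights(accuracies) -> np.ndarray:
    """Normalize accuracies into weights: w_i = acc_i / sum(acc).

    Order-preserving and scale-invariant; requires strictly positive input.
    """
    acc = np.asarray(list(accuracies), dtype=float)
    if acc.size == 0:
        raise ValueError("cannot compute weights from an empty accuracy list")
    if np.any(acc <= 0):
        raise ValueError("accuracies must be strictly positive")
    return acc / acc.sum()


@dataclass(eq=False)
class EnsembleModel:
    """Selected member models with their normalized accuracy weights."""

    members: list[TrainedModel]
    weights: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != self.weights.size:
            raise ValueError("one weight per member required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        for m in self.members:
            if not np.array_equal(np.asarray(m.classes), self.classes):
                raise ValueError(
                    f"member {m.spec.name} has a different class set")

    @property
    def member_names(self) -> list[str]:
        return [m.spec.name for m in self.members]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return ensemble_predict_proba(self, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return ensemble_predict(self, X)

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"members": [], "weights": self.weights.tolist(),
                "classes": [str(c) for c in self.classes]}
        for i, m in enumerate(self.members):
            state = directory / f"member_{i}_{m.spec.name}.pkl"
            with open(state, "wb") as fh:
                pickle.dump(m, fh)
            meta["members"].append({"name": m.spec.name, "state_file": state.name})
        (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        meta = json.loads((directory / "ensemble.json").read_text())
        members = []
        for entry in meta["members"]:
            with open(directory / entry["state_file"], "rb") as fh:
                members.append(pickle.load(fh))
        return cls(members=members, weights=np.asarray(meta["weights"]),
                   classes=np.asarray(meta["classes"]))


def _top_k_indices(suite: TrainedModelSuite, k: int) -> list[int]:
    if not 1 <= k <= len(suite.models):
        raise ValueError(f"k={k} out of range for {len(suite.models)} models")
    order = sorted(range(len(suite.models)),
                   key=lambda i: (-suite.val_accuracy[i],
                                  MODEL_NAMES.index(suite.models[i].spec.name)))
    return sorted(order[:k])  # keep original suite order among the selected


def select_top_k(suite: TrainedModelSuite, k: int = 5) -> EnsembleModel:
    """Keep the k most accurate base models, unweighted (uniform weights).

    Ties at rank k break by the canonical model-name order (earlier wins),
    so selection is deterministic.
    """
    chosen = _top_k_indices(suite, k)
    members = [suite.models[i] for i in chosen]
    return EnsembleModel(members=members, weights=np.full(k, 1.0 / k),
                         classes=members[0].classes)


def build_emc(suite: TrainedModelSuite, k: int = 5) -> EnsembleModel:
    """Top-k selection followed by accuracy weighting over the selected members."""
    chosen = _top_k_indices(suite, k)
    members = [suite.models[i] for i in chosen]
    acc = [suite.val_accuracy[i] for i in chosen]
    return EnsembleModel(members=members, weights=compute_weights(acc),
                         classes=members[0].classes)


def ensemble_predict_proba(e: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Weighted sum of member probability matrices: P = sum_n w_n P_n(X)."""
    fused = None
    for w, m in zip(e.weights, e.members):
        P = m.predict_proba(X)
        fused = w * P if fused is None else fused + w * P
    return fused


def ensemble_predict(e: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Argmax class of the fused probabilities (ties break to earlier class)."""
    return e.classes[ensemble_predict_proba(e, X).argmax(axis=1)]
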