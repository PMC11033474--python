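"""Splits, repeated cross-validation, multiclass metrics and confusion reports.

The evaluation protocol: a stratified 70/30 train/test split for single
reports, and repeated stratified k-fold cross-validation (default 10 × 10,
i.e. 100 resamples) for distributions.  Four metrics summarize a confusion
matrix:

* accuracy — percentage of correctly classified cells;
* mean sensitivity — macro average over classes of the one-vs-rest recall
  TP/(TP+FN);
* mean specificity — macro average of the one-vs-rest true-negative rate
  TN/(TN+FP);
* Cohen's kappa — chance-corrected agreement (p0 − pe)/(1 − pe), with
  p0 the observed accuracy and pe the agreement expected from the row and
  column margins alone.

The confusion report adds the margins used in per-class error analysis:
row-wise true-positive and false-negative rates (TPR/FNR) and column-wise
positive-predictive values and false-discovery rates (PPV/FDR).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifiers import BaseModelSpec, default_specs, train_and_validate_suite
from .emc import build_emc
from .io import SpectrumSet

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "Metrics",
    "split_train_test",
    "compute_metrics",
    "confusion_report",
    "repeated_cv",
]

EMC_NAME = "EMC"


@dataclass(eq=False)
class ConfusionMatrix:
    """C × C count matrix; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.classes = np.asarray(self.classes)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != self.classes.size:
            raise ValueError("one class label per row required")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = np.unique(np.concatenate([y_true, y_pred]))
        classes = np.asarray(classes)
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((classes.size, classes.size), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, classes=classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if not np.array_equal(self.classes, other.classes):
            raise ValueError("cannot add confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, self.classes)


@dataclass(frozen=True)
class Metrics:
    """The four summary metrics of one confusion matrix."""

    accuracy: float          # %
    mean_sensitivity: float  # %
    mean_specificity: float  # %
    kappa: float             # [-1, 1]


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, macro sensitivity, macro specificity and Cohen's kappa.

    Macro averages run over classes where the rate is defined (a class with
    no true cells has no sensitivity; one predicted or true everywhere has
    no specificity).  When the chance agreement pe equals 1 — all mass in a
    single row-column cell — kappa is defined as 1 for a perfect matrix and
    0 otherwise.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    p0 = diag.sum() / total
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(rows > 0, diag / rows, np.nan)
        tn = total - rows - cols + diag
        fp = cols - diag
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    pe = float(np.sum(rows * cols)) / total ** 2
    if pe == 1.0:
        kappa = 1.0 if p0 == 1.0 else 0.0
    else:
        kappa = (p0 - pe) / (1.0 - pe)
    return Metrics(accuracy=100.0 * p0,
                   mean_sensitivity=100.0 * float(np.nanmean(sens)),
                   mean_specificity=100.0 * float(np.nanmean(spec)),
                   kappa=float(kappa))


def confusion_report(cm: ConfusionMatrix) -> pd.DataFrame:
    """Counts with TPR/FNR row margins and PPV/FDR column margins (%).

    Margins of empty rows/columns are NaN (undefined), never 0: a class that
    was never predicted has no positive predictive value.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(rows > 0, 100.0 * diag / rows, np.nan)
        ppv = np.where(cols > 0, 100.0 * diag / cols, np.nan)
    classes = [str(c) for c in cm.classes]
    df = pd.DataFrame(cm.counts, index=classes, columns=classes, dtype=float)
    df["TPR%"] = tpr
    df["FNR%"] = 100.0 - tpr
    ppv_row = pd.Series(ppv, index=classes)
    fdr_row = 100.0 - ppv_row
    df.loc["PPV%"] = ppv_row
    df.loc["FDR%"] = fdr_row
    return df


def split_train_test(s: SpectrumSet, train_fraction: float = 0.7,
                     seed: int = 0) -> tuple[SpectrumSet, SpectrumSet]:
    """Stratified split: per species, floor(train_fraction·n) cells to train.

    Disjoint and exhaustive; the per-class shuffle is seeded, so the same
    seed always yields the identical partition.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for sp, grp in s.labels.groupby("species", sort=True):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 cells")
        idx = rng.permutation(idx)
        # epsilon guards the floor against float error (0.7*180 = 125.999...)
        n_train = int(np.floor(train_fraction * idx.size + 1e-9))
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return s.select(np.sort(train_idx)), s.select(np.sort(test_idx))


@dataclass(eq=False)
class EvalReport:
    """Per-resample metric records plus a pooled ensemble confusion matrix.

    ``records`` columns: repeat, fold, model, accuracy, mean_sensitivity,
    mean_specificity, kappa.  ``confusion`` pools the ensemble's held-out
    predictions over every fold and repeat.
    """

    records: pd.DataFrame
    confusion: ConfusionMatrix
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Median and quartiles of each metric per model (box-plot statistics)."""
        metrics = ["accuracy", "mean_sensitivity", "mean_specificity", "kappa"]
        rows = []
        for model, grp in self.records.groupby("model", sort=False):
            for met in metrics:
                q1, med, q3 = np.percentile(grp[met], [25, 50, 75])
                rows.append({"model": model, "metric": met,
                             "median": med, "q1": q1, "q3": q3,
                             "mean": grp[met].mean()})
        return pd.DataFrame(rows)

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(directory / "records.csv", index=False)
        self.summary().to_csv(directory / "summary.csv", index=False)
        confusion_report(self.confusion).to_csv(directory / "confusion.csv")
        return directory


def _metric_row(y_true, y_pred, classes, **ids) -> dict:
    cm = ConfusionMatrix.from_labels(y_true, y_pred, classes)
    m = compute_metrics(cm)
    return {**ids, "accuracy": m.accuracy, "mean_sensitivity": m.mean_sensitivity,
            "mean_specificity": m.mean_specificity, "kappa": m.kappa}


def repeated_cv(s: SpectrumSet, specs: list[BaseModelSpec] | None = None,
                repeats: int = 10, folds: int = 10, seed: int = 0,
                k: int = 5, val_fraction: float = 0.2) -> EvalReport:
    """Repeated stratified k-fold cross-validation of the bank and the ensemble.

    For each repeat (reseeded deterministically) the cells are partitioned
    into stratified folds; on each fold's training part the whole suite is
    fitted and the ensemble is built from scratch (selection and weighting
    use only training-fold data, so held-out labels never leak), then every
    base model and the ensemble are scored on the held-out fold.  With the
    default 10 repeats × 10 folds each model accrues 100 resample records.
    """
    specs = specs if specs is not None else default_specs(seed=seed)
    y = s.species
    classes, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} cells; needs >= {folds}")
    records: list[dict] = []
    pooled = ConfusionMatrix(np.zeros((classes.size, classes.size), dtype=int),
                             classes)
    for rep in range(repeats):
        rep_seed = int((seed * 1_000_003 + rep) % (2 ** 31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(skf.split(s.intensities, y)):
            train = s.select(tr)
            suite = train_and_validate_suite(
                train, specs, val_fraction=val_fraction, seed=rep_seed + fold)
            ens = build_emc(suite, k=min(k, len(suite.models)))
            X_te, y_te = s.intensities[te], y[te]
            for model in suite.models:
                records.append(_metric_row(
                    y_te, model.predict(X_te), classes,
                    repeat=rep, fold=fold, model=model.spec.name))
            y_hat = ens.predict(X_te)
            records.append(_metric_row(y_te, y_hat, classes,
                                       repeat=rep, fold=fold, model=EMC_NAME))
            pooled = pooled + ConfusionMatrix.from_labels(y_te, y_hat, classes)
    report = EvalReport(records=pd.DataFrame(records), confusion=pooled,
                        meta={"repeats": repeats, "folds": folds, "seed": seed,
                              "k": k, "models": [sp.name for sp in specs]})
    return report
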