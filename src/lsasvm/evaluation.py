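"""Cross-validation, metrics, and the six-classifier benchmark harness.

The harness compares the plain SVMs with their advised variants —
c-SVM, v-SVM, c-SA-SVM, v-SA-SVM, c-LSA-SVM, v-LSA-SVM — on *identical*
stratified folds, so accuracy differences are paired comparisons and never
an artifact of the split.  Fold sizing follows the data: 3 folds for large
datasets (n > 1000), 5 otherwise.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .base_svm import LabeledDataset, train_svm, predict
from .kernels import KernelSpec
from .lsa_svm import fit_lsa_svm, lsa_predict
from .sa_svm import fit_sa_svm, advised_predict

__all__ = ["CVResult", "ClassifierConfig", "CLASSIFIER_IDS", "auto_folds",
           "kfold_split", "accuracy", "sensitivity_specificity",
           "multilabel_accuracy", "benchmark", "results_table"]

CLASSIFIER_IDS = ("c-svm", "v-svm", "c-sa-svm", "v-sa-svm",
                  "c-lsa-svm", "v-lsa-svm")

LARGE_DATA_THRESHOLD = 1000


def auto_folds(n: int) -> int:
    """Fold-count sizing rule: 3-fold for large data, 5-fold otherwise."""
    return 3 if n > LARGE_DATA_THRESHOLD else 5


def kfold_split(ds: LabeledDataset, k: int, seed: int) -> list[np.ndarray]:
    """Stratified, disjoint, exhaustive test folds (deterministic per seed)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    _, counts = np.unique(ds.y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class must have >= k={k} members; smallest has {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(ds.X, ds.y)]


def accuracy(y_true, y_pred) -> float:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    return float(np.mean(y_true == y_pred))


def sensitivity_specificity(y_true, y_pred, positive_label=None) -> tuple[float, float]:
    """TP/(TP+FN) and TN/(TN+FP) for the declared positive label;
    with no positive label, the macro-average of one-vs-rest values."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")

    def _one(pos):
        tp = np.sum((y_true == pos) & (y_pred == pos))
        fn = np.sum((y_true == pos) & (y_pred != pos))
        tn = np.sum((y_true != pos) & (y_pred != pos))
        fp = np.sum((y_true != pos) & (y_pred == pos))
        sens = tp / (tp + fn) if tp + fn > 0 else 1.0
        spec = tn / (tn + fp) if tn + fp > 0 else 1.0
        return sens, spec

    if positive_label is not None:
        return tuple(map(float, _one(positive_label)))
    pairs = [_one(c) for c in sorted(set(y_true.tolist()), key=str)]
    return (float(np.mean([p[0] for p in pairs])),
            float(np.mean([p[1] for p in pairs])))


def multilabel_accuracy(true_sets, pred_sets) -> float:
    """Mean Jaccard overlap |y ∧ ŷ| / |y ∨ ŷ| over samples; two empty
    sets count as a perfect match."""
    if len(true_sets) != len(pred_sets):
        raise ValueError(f"length mismatch: {len(true_sets)} vs {len(pred_sets)}")
    scores = []
    for t, p in zip(true_sets, pred_sets):
        t, p = set(t), set(p)
        union = t | p
        scores.append(1.0 if not union else len(t & p) / len(union))
    return float(np.mean(scores)) if scores else 1.0


@dataclass(frozen=True)
class ClassifierConfig:
    """One row of the benchmark: which classifier, with which parameters."""

    id: str
    C: float = 1.0
    nu: float = 0.1
    gamma: float = 1.0
    kernel_kind: str = "rbf"
    normalize: bool = False       # z-score features, fitted on training folds
    label_scheme: str | None = None

    def __post_init__(self) -> None:
        if self.id not in CLASSIFIER_IDS:
            raise ValueError(
                f"unknown classifier id {self.id!r}; valid ids: {CLASSIFIER_IDS}")

    @property
    def variant(self) -> str:
        return "nu" if self.id.startswith("v-") else "c"

    @property
    def C_or_nu(self) -> float:
        return self.nu if self.variant == "nu" else self.C

    @property
    def layer(self) -> str:
        if "lsa" in self.id:
            return "lsa"
        return "sa" if "sa" in self.id else "svm"


@dataclass
class CVResult:
    classifier_id: str
    fold_accuracies: list
    mean_accuracy: float
    sensitivity: float
    specificity: float
    train_time_ms: float
    params: dict = field(default_factory=dict)


def _fit_predict(cfg: ClassifierConfig, train: LabeledDataset, Xtest
                 ) -> tuple[np.ndarray, float]:
    kernel = KernelSpec(kind=cfg.kernel_kind,
                        gamma=None if cfg.kernel_kind == "linear" else cfg.gamma)
    t0 = time.perf_counter()
    base = train_svm(train, cfg.variant, kernel, cfg.C_or_nu)
    if cfg.layer == "sa":
        model = fit_sa_svm(base, train)
    elif cfg.layer == "lsa":
        model = fit_lsa_svm(base, train, scheme=cfg.label_scheme)
    train_ms = (time.perf_counter() - t0) * 1000.0
    if cfg.layer == "svm":
        return predict(base, Xtest), train_ms
    if cfg.layer == "sa":
        return advised_predict(model, Xtest), train_ms
    return lsa_predict(model, Xtest), train_ms


def benchmark(ds: LabeledDataset, classifiers, k: int, seed: int,
              positive_label=None) -> list[CVResult]:
    """Run every configured classifier over the same stratified folds."""
    configs = [c if isinstance(c, ClassifierConfig) else ClassifierConfig(id=c)
               for c in classifiers]
    folds = kfold_split(ds, k, seed)
    all_idx = np.arange(ds.n)
    results = []
    for cfg in configs:
        fold_accs, times = [], []
        y_true_all, y_pred_all = [], []
        for test_idx in folds:
            tr_idx = np.setdiff1d(all_idx, test_idx)
            tr = ds.subset(tr_idx)
            Xte = ds.X[test_idx]
            if cfg.normalize:
                scaler = StandardScaler().fit(tr.X)
                tr = LabeledDataset(scaler.transform(tr.X), tr.y,
                                    classes=list(tr.classes))
                Xte = scaler.transform(Xte)
            pred, train_ms = _fit_predict(cfg, tr, Xte)
            fold_accs.append(accuracy(ds.y[test_idx], pred))
            times.append(train_ms)
            y_true_all.append(ds.y[test_idx])
            y_pred_all.append(pred)
        y_true = np.concatenate(y_true_all)
        y_pred = np.concatenate(y_pred_all)
        sens, spec = sensitivity_specificity(y_true, y_pred, positive_label)
        results.append(CVResult(
            classifier_id=cfg.id,
            fold_accuracies=fold_accs,
            mean_accuracy=float(np.mean(fold_accs)),
            sensitivity=sens, specificity=spec,
            train_time_ms=float(np.mean(times)),
            params={"variant": cfg.variant, "C_or_nu": cfg.C_or_nu,
                    "gamma": cfg.gamma, "kernel": cfg.kernel_kind,
                    "normalize": cfg.normalize, "folds": k, "seed": seed},
        ))
    return results


def results_table(results: list[CVResult]) -> pd.DataFrame:
    """Benchmark report, one row per classifier, in the order given."""
    return pd.DataFrame([{
        "classifier": r.classifier_id,
        "accuracy_pct": 100.0 * r.mean_accuracy,
        "sensitivity": r.sensitivity,
        "specificity": r.specificity,
        "train_time_ms": r.train_time_ms,
    } for r in results])
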