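"""Standard c-SVM and nu-SVM training, decision values, and grid search.

The quadratic program itself is delegated to scikit-learn's libsvm wrappers
(SVC / NuSVC); what this module owns is the model record — support vectors,
signed dual coefficients alpha_i * y_i, and bias per pairwise machine — and
the contract that decision values recomputed from that record,

    h(x) = sum_i alpha_i y_i k(x, x_i) + b,

agree with the solver's own output to 1e-6.  Multiclass problems are
reduced one-vs-one: one binary machine per unordered class pair, majority
vote, ties broken toward the earliest class in class order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, NuSVC

from .kernels import KernelSpec, kernel_matrix

__all__ = ["LabeledDataset", "PairwiseMachine", "SVMModel", "ParamGrid",
           "GridSearchResult", "train_svm", "decision_value",
           "pairwise_decision_values", "predict", "decision_proxy",
           "grid_search", "default_param_grid"]

RECONSTRUCTION_TOL = 1e-6


@dataclass
class LabeledDataset:
    """Feature matrix X (n x d) with one hashable class label per row.

    ``classes`` is the ordered set of distinct labels (sorted by default);
    every class-order tie-break in the package refers to this ordering.
    ``metadata`` is free-form (the synthetic generators record ground truth
    there).
    """

    X: np.ndarray
    y: np.ndarray
    classes: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        n, d = self.X.shape
        if n < 1 or d < 1:
            raise ValueError(f"need n >= 1 and d >= 1, got X of shape {self.X.shape}")
        if len(self.y) != n:
            raise ValueError(f"length of y ({len(self.y)}) != number of rows ({n})")
        if not self.classes:
            self.classes = sorted(set(self.y.tolist()))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], classes=list(self.classes))


@dataclass
class PairwiseMachine:
    """One binary machine for the class pair (neg_class, pos_class).

    Internally the pair is coded neg -> -1, pos -> +1, so a positive
    decision value votes for ``pos_class``.  dual_coefs holds alpha_i * y_i
    for the retained support vectors (all alpha_i > 0).
    """

    neg_class: Hashable
    pos_class: Hashable
    support_vectors: np.ndarray
    dual_coefs: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coefs = np.asarray(self.dual_coefs, dtype=float).ravel()
        if self.support_vectors.ndim != 2 or self.support_vectors.shape[0] == 0:
            raise ValueError("a trained machine must retain at least one support vector")
        if len(self.dual_coefs) != self.support_vectors.shape[0]:
            raise ValueError("dual_coefs and support_vectors disagree in length")


@dataclass
class SVMModel:
    """A trained (possibly one-vs-one multiclass) SVM."""

    variant: str                      # "c" or "nu"
    kernel: KernelSpec
    C_or_nu: float
    classes: list
    machines: list                    # list[PairwiseMachine], pairs in class order
    multiclass_scheme: str = "binary"

    @property
    def d(self) -> int:
        return self.machines[0].support_vectors.shape[1]


@dataclass(frozen=True)
class ParamGrid:
    """Hyperparameter grid; the default C and gamma grids are the 20 powers
    of two from 2^-9 through 2^10."""

    C_values: tuple = ()
    gamma_values: tuple = ()
    nu_values: tuple = ()


def default_param_grid() -> ParamGrid:
    pows = tuple(2.0 ** p for p in range(-9, 11))   # 2^-9 ... 2^10, 20 values
    nus = tuple(round(0.05 * i, 2) for i in range(1, 11))  # 0.05 ... 0.5
    return ParamGrid(C_values=pows, gamma_values=pows, nu_values=nus)


def _check_x(model: SVMModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.d:
        raise ValueError(f"dimension mismatch: model expects d={model.d}, got d={X.shape[1]}")
    return X


def train_svm(train: LabeledDataset, variant: str, kernel: KernelSpec,
              C_or_nu: float) -> SVMModel:
    """Fit an SVM of the given variant; one machine per class pair.

    Raises on single-class data, on invalid C/nu, and on a nu that is
    infeasible for the class balance of some pair (libsvm's feasibility
    bound is nu <= 2*min(n+, n-)/(n+ + n-)).
    """
    if variant not in ("c", "nu"):
        raise ValueError(f"variant must be 'c' or 'nu', got {variant!r}")
    if len(train.classes) < 2:
        raise ValueError(
            f"training requires >= 2 classes, got classes={train.classes!r}")
    if variant == "c" and C_or_nu <= 0:
        raise ValueError(f"C must be > 0, got {C_or_nu}")
    if variant == "nu" and not (0 < C_or_nu <= 1):
        raise ValueError(f"nu must lie in (0, 1], got {C_or_nu}")

    skl_kw = kernel.sklearn_params
    machines: list[PairwiseMachine] = []
    for a, b in itertools.combinations(train.classes, 2):
        mask = (train.y == a) | (train.y == b)
        Xp = train.X[mask]
        yp = np.where(train.y[mask] == a, -1, 1)
        if variant == "c":
            clf = SVC(C=C_or_nu, **skl_kw)
        else:
            clf = NuSVC(nu=C_or_nu, **skl_kw)
        try:
            clf.fit(Xp, yp)
        except ValueError as exc:
            if variant == "nu" and "nu" in str(exc).lower():
                raise ValueError(
                    f"nu={C_or_nu} is infeasible for the class balance of pair "
                    f"({a!r}, {b!r}): {exc}") from exc
            raise
        machines.append(PairwiseMachine(
            neg_class=a, pos_class=b,
            support_vectors=clf.support_vectors_,
            dual_coefs=clf.dual_coef_[0],
            bias=float(clf.intercept_[0]),
        ))
        # contract: the stored record reproduces the solver's decision values
        own = _machine_decision(machines[-1], kernel, Xp)
        ref = clf.decision_function(Xp)
        if np.max(np.abs(own - ref)) > RECONSTRUCTION_TOL:
            raise RuntimeError(
                "stored model record fails to reproduce solver decision values "
                f"(max |delta| = {np.max(np.abs(own - ref)):.3g})")

    scheme = "binary" if len(train.classes) == 2 else "one_vs_one"
    return SVMModel(variant=variant, kernel=kernel, C_or_nu=C_or_nu,
                    classes=list(train.classes), machines=machines,
                    multiclass_scheme=scheme)


def _machine_decision(m: PairwiseMachine, kernel: KernelSpec, X: np.ndarray) -> np.ndarray:
    K = kernel_matrix(kernel, X, m.support_vectors)
    return K @ m.dual_coefs + m.bias


def pairwise_decision_values(model: SVMModel, X) -> np.ndarray:
    """(n_samples, n_pairs) matrix of h(x) values, pairs in class order."""
    X = _check_x(model, X)
    return np.column_stack([
        _machine_decision(m, model.kernel, X) for m in model.machines])


def decision_value(model: SVMModel, x):
    """h(x) for one point: a scalar for binary models, a per-pair vector
    for one-vs-one models."""
    H = pairwise_decision_values(model, np.asarray(x, dtype=float).reshape(1, -1))
    return float(H[0, 0]) if model.multiclass_scheme == "binary" else H[0]


def _votes(model: SVMModel, H: np.ndarray) -> np.ndarray:
    """Majority vote over pairwise machines; ties to the earliest class."""
    n = H.shape[0]
    counts = np.zeros((n, len(model.classes)), dtype=int)
    idx = {c: i for i, c in enumerate(model.classes)}
    for j, m in enumerate(model.machines):
        pos = H[:, j] > 0
        counts[pos, idx[m.pos_class]] += 1
        counts[~pos, idx[m.neg_class]] += 1
    # argmax takes the first maximum, i.e. the earliest class in class order
    return np.argmax(counts, axis=1)


def predict(model: SVMModel, X) -> np.ndarray:
    """Predicted labels; binary = sign of h mapped onto the class pair,
    one-vs-one = majority vote."""
    X = _check_x(model, X)
    H = pairwise_decision_values(model, X)
    winners = _votes(model, H)
    return np.asarray([model.classes[w] for w in winners])


def decision_proxy(model: SVMModel, X) -> tuple[np.ndarray, np.ndarray]:
    """(predicted labels, per-point confidence proxy).

    Binary: the proxy is |h(x)| itself.  One-vs-one: the vote winner's
    smallest pairwise |h| over the machines it took part in — the weakest
    link of the winning class, reducing exactly to |h| for 2 classes.
    """
    X = _check_x(model, X)
    H = pairwise_decision_values(model, X)
    winners = _votes(model, H)
    labels = np.asarray([model.classes[w] for w in winners])
    proxy = np.empty(X.shape[0])
    involved = {c: [j for j, m in enumerate(model.machines)
                    if c in (m.neg_class, m.pos_class)] for c in model.classes}
    for i, w in enumerate(winners):
        cols = involved[model.classes[w]]
        proxy[i] = np.min(np.abs(H[i, cols]))
    return labels, proxy


@dataclass
class GridSearchResult:
    best_C_or_nu: float
    best_gamma: float
    table: pd.DataFrame        # columns: C_or_nu, gamma, mean_accuracy
    n_evaluated: int


def grid_search(train: LabeledDataset, variant: str, grid: ParamGrid | None,
                folds: int, seed: int) -> GridSearchResult:
    """Exhaustive (C|nu, gamma) search by stratified k-fold accuracy.

    Ties break toward the smaller C (or nu), then the smaller gamma —
    iteration order is sorted, and only strict improvements replace the
    incumbent.
    """
    if grid is None:
        grid = default_param_grid()
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    _, counts = np.unique(train.y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"fold count {folds} exceeds the smallest class count {counts.min()}")
    cvals = sorted(grid.C_values if variant == "c" else grid.nu_values)
    gvals = sorted(grid.gamma_values)
    if not cvals or not gvals:
        raise ValueError("parameter grid is empty for this variant")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(train.X, train.y))
    rows = []
    best = (-math.inf, None, None)
    for c in cvals:
        for g in gvals:
            kern = KernelSpec(kind="rbf", gamma=g)
            accs = []
            for tr_idx, te_idx in splits:
                try:
                    model = train_svm(train.subset(tr_idx), variant, kern, c)
                except ValueError:
                    accs = [0.0]
                    break
                pred = predict(model, train.X[te_idx])
                accs.append(float(np.mean(pred == train.y[te_idx])))
            mean_acc = float(np.mean(accs))
            rows.append((c, g, mean_acc))
            if mean_acc > best[0]:
                best = (mean_acc, c, g)
    table = pd.DataFrame(rows, columns=["C_or_nu", "gamma", "mean_accuracy"])
    return GridSearchResult(best_C_or_nu=best[1], best_gamma=best[2],
                            table=table, n_evaluated=len(rows))
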