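"""The self-advised SVM (SA-SVM) layer.

A trained SVM discards what its own training errors could tell it.  The
self-advising layer recovers that information without retraining:

1. collect the misclassified training set MD = {i : y_i != predict(x_i)};
2. give each MD point a neighborhood length NL(x_i) — the kernel-induced
   distance to the nearest *correctly classified* training point of a
   *different* label, i.e. the radius within which the MD point's label is
   the most local evidence available;
3. at test time score each point x_k with an advised weight
   AW(x_k) in [0, 1] — the mean of (1 - d/NL) over the MD points whose
   neighborhood contains x_k (0 if none, or if MD is empty);
4. compare AW against the batch-scaled |decision value|: when the SVM is
   confident (scaled |h| > AW) its label stands; otherwise the point is
   relabeled with the true label of the nearest qualifying MD point.

The layer is non-iterative: it never retrains the underlying machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .base_svm import LabeledDataset, SVMModel, decision_proxy, predict
from .kernels import KernelSpec, induced_distance_matrix

__all__ = ["MisclassifiedSet", "AdvisedModel", "find_misclassified",
           "neighborhood_lengths", "advised_weight", "scale_decision_values",
           "advised_predict", "fit_sa_svm"]


@dataclass
class MisclassifiedSet:
    """Training rows the base SVM got wrong, with their neighborhood lengths.

    ``nl`` is NaN for points not yet assigned a length and for flagged
    points — those with no correctly-classified, differently-labeled
    neighbor to measure against; flagged points are excluded from advising.
    """

    indices: np.ndarray          # training-row indices, ascending
    points: np.ndarray           # (m, d)
    labels: np.ndarray           # (m,) true labels
    nl: np.ndarray               # (m,) float, NaN = flagged/unset

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels)
        self.nl = np.asarray(self.nl, dtype=float)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def is_empty(self) -> bool:
        return len(self.indices) == 0

    @property
    def active(self) -> np.ndarray:
        """Mask of MD points usable for advising (finite positive NL)."""
        return np.isfinite(self.nl) & (self.nl > 0)


@dataclass
class AdvisedModel:
    """A base SVM plus its misclassified set and the advising space."""

    base: SVMModel
    md: MisclassifiedSet
    space: str = "feature"                    # "feature" (SA) or "label" (LSA)
    label_encoding: Optional[object] = None   # LabelEncoding, label space only
    label_kernel: Optional[KernelSpec] = None
    normalization: str = "mean"               # AW aggregation rule tag


def find_misclassified(base: SVMModel, train: LabeledDataset) -> MisclassifiedSet:
    """MD = { i : y_i != predict(base, x_i) }; may be empty."""
    pred = predict(base, train.X)
    wrong = np.flatnonzero(pred != train.y)
    return MisclassifiedSet(indices=wrong, points=train.X[wrong],
                            labels=train.y[wrong],
                            nl=np.full(len(wrong), np.nan))


def neighborhood_lengths(md: MisclassifiedSet, train: LabeledDataset,
                         kernel: KernelSpec) -> MisclassifiedSet:
    """Assign NL(x_i) = min kernel-induced distance to a non-MD training
    point of a different label; points with no such neighbor stay NaN."""
    nl = np.full(len(md), np.nan)
    in_md = np.zeros(train.n, dtype=bool)
    in_md[md.indices] = True
    for r, (xi, yi) in enumerate(zip(md.points, md.labels)):
        cand = ~in_md & (train.y != yi)
        if not cand.any():
            continue
        d = induced_distance_matrix(kernel, xi, train.X[cand])
        nl[r] = float(d.min())
    return MisclassifiedSet(indices=md.indices, points=md.points,
                            labels=md.labels, nl=nl)


def fit_sa_svm(base: SVMModel, train: LabeledDataset) -> AdvisedModel:
    """Convenience: extract MD, compute feature-space NLs, assemble the model."""
    md = neighborhood_lengths(find_misclassified(base, train), train, base.kernel)
    return AdvisedModel(base=base, md=md, space="feature")


def _advised_weights(adv: AdvisedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(AW per row of X, distance matrix to active MD points)."""
    act = adv.md.active
    n = X.shape[0]
    if adv.md.is_empty or not act.any():
        return np.zeros(n), np.zeros((n, 0))
    D = induced_distance_matrix(adv.base.kernel, X, adv.md.points[act])
    nl = adv.md.nl[act]
    inside = D <= nl[None, :]
    contrib = np.where(inside, 1.0 - D / nl[None, :], 0.0)
    counts = inside.sum(axis=1)
    aw = np.zeros(n)
    nz = counts > 0
    aw[nz] = contrib[nz].sum(axis=1) / counts[nz]
    return np.clip(aw, 0.0, 1.0), D


def advised_weight(adv: AdvisedModel, xk) -> float:
    """AW(x_k) in [0, 1]: mean of (1 - d/NL) over MD neighborhoods
    containing x_k; 0 when MD is empty or no neighborhood qualifies."""
    if adv.space != "feature":
        raise ValueError("advised_weight applies to feature-space advising; "
                         "use label_advised_weight for label space")
    xk = np.asarray(xk, dtype=float).reshape(1, -1)
    return float(_advised_weights(adv, xk)[0][0])


def scale_decision_values(values) -> np.ndarray:
    """Map a batch of decision values onto [0, 1]: absolute value divided
    by the batch maximum absolute value; an all-zero batch stays zero."""
    v = np.abs(np.asarray(values, dtype=float))
    if v.size == 0:
        return v
    m = v.max()
    return v / m if m > 0 else v


def advised_predict(adv: AdvisedModel, Xtest) -> np.ndarray:
    """Apply the advised decision rule to a test batch.

    Per point: AW < scaled |h|  ->  base SVM label; otherwise the true
    label of the nearest qualifying MD point (kernel-induced distance,
    ties to the smallest MD index).  With no qualifying MD point, or an
    empty MD, the base label stands.
    """
    if adv.space != "feature":
        raise ValueError("advised_predict is the feature-space rule; "
                         "use lsa_predict for label-space advising")
    Xtest = np.asarray(Xtest, dtype=float)
    if Xtest.ndim == 1:
        Xtest = Xtest.reshape(1, -1)
    base_labels, proxy = decision_proxy(adv.base, Xtest)
    if adv.md.is_empty or not adv.md.active.any():
        return base_labels
    scaled = scale_decision_values(proxy)
    aw, D = _advised_weights(adv, Xtest)
    act_labels = adv.md.labels[adv.md.active]
    nl = adv.md.nl[adv.md.active]
    out = base_labels.copy()
    for i in range(Xtest.shape[0]):
        if aw[i] < scaled[i]:
            continue                      # strict '<' routes ties to relabeling
        inside = np.flatnonzero(D[i] <= nl)
        if inside.size == 0:
            continue
        nearest = inside[np.argmin(D[i, inside])]   # argmin -> smallest MD index on ties
        out[i] = act_labels[nearest]
    return out
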