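"""The label self-advised SVM (LSA-SVM): advising in label space.

Where SA-SVM measures how close a test point lies to the misclassified
training points in *feature* space, LSA-SVM measures closeness between
*labels*: neighborhood lengths and advised weights are computed on a
numeric encoding of the class labels (signed +/-1 for two classes, one-hot
otherwise).  Because label vectors are short — length 1 or L, versus d
feature dimensions — the advising pass touches far fewer numbers per
comparison, which is the method's motivation for large data.

The test point's own label is of course unknown at prediction time; the
layer uses the base SVM's predicted label as its stand-in (the advising
step runs strictly after the base prediction exists).  When the advice
wins, the replacement label is taken from the qualifying misclassified
point nearest in feature space, since for few classes the label metric is
too coarse to rank candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_svm import LabeledDataset, SVMModel, decision_proxy
from .kernels import KernelSpec, induced_distance_matrix
from .sa_svm import (AdvisedModel, MisclassifiedSet, find_misclassified,
                     scale_decision_values)

__all__ = ["LabelEncoding", "encode_labels", "label_neighborhood_lengths",
           "label_advised_weight", "lsa_predict", "fit_lsa_svm"]

_SCHEMES = ("signed_binary", "one_hot", "integer_code")


@dataclass
class LabelEncoding:
    """Injective, deterministic map from class labels to numeric vectors.

    Classes are sorted, so the encoding depends only on the class set:
    signed_binary sends the two classes to -1 and +1; one_hot to the unit
    basis of R^L; integer_code to 0, 1, ..., L-1.
    """

    scheme: str
    classes: list

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown encoding scheme {self.scheme!r}")
        if self.scheme == "signed_binary" and len(self.classes) != 2:
            raise ValueError(
                f"signed_binary requires exactly 2 classes, got {len(self.classes)}")

    @property
    def dim(self) -> int:
        return len(self.classes) if self.scheme == "one_hot" else 1

    def encode(self, labels) -> np.ndarray:
        labels = np.asarray(labels)
        idx = {c: i for i, c in enumerate(self.classes)}
        try:
            rows = np.array([idx[l] for l in labels.tolist()])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in encoding classes "
                             f"{self.classes!r}") from exc
        if self.scheme == "signed_binary":
            return np.where(rows == 0, -1.0, 1.0).reshape(-1, 1)
        if self.scheme == "one_hot":
            return np.eye(len(self.classes))[rows]
        return rows.astype(float).reshape(-1, 1)

    def decode(self, vectors: np.ndarray) -> np.ndarray:
        table = self.encode(np.asarray(self.classes, dtype=object))
        vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        out = []
        for v in vectors:
            hits = np.flatnonzero(np.all(np.isclose(table, v), axis=1))
            if hits.size == 0:
                raise ValueError(f"vector {v!r} decodes to no known class")
            out.append(self.classes[hits[0]])
        return np.asarray(out)

    def to_dict(self) -> dict:
        return {"scheme": self.scheme, "classes": list(self.classes)}

    @classmethod
    def from_dict(cls, d: dict) -> "LabelEncoding":
        return cls(scheme=d["scheme"], classes=list(d["classes"]))


def encode_labels(labels, scheme: str) -> tuple[np.ndarray, LabelEncoding]:
    """Fit an encoding on the distinct labels (sorted) and encode them."""
    classes = sorted(set(np.asarray(labels).tolist()))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 distinct labels, got {classes!r}")
    enc = LabelEncoding(scheme=scheme, classes=classes)
    return enc.encode(labels), enc


def default_encoding_scheme(n_classes: int) -> str:
    return "signed_binary" if n_classes == 2 else "one_hot"


def _label_distance(enc: LabelEncoding, U: np.ndarray, V: np.ndarray,
                    label_kernel: KernelSpec | None) -> np.ndarray:
    """Pairwise distances between encoded labels: plain Euclidean, or the
    kernel-induced form when a label kernel (label-space RBF) is given."""
    U = np.atleast_2d(U)
    V = np.atleast_2d(V)
    if label_kernel is None:
        diff = U[:, None, :] - V[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))
    return induced_distance_matrix(label_kernel, U, V)


def label_neighborhood_lengths(md: MisclassifiedSet, train: LabeledDataset,
                               enc: LabelEncoding,
                               label_kernel: KernelSpec | None = None
                               ) -> MisclassifiedSet:
    """NL(y_i) = min label-distance from the MD point's true label to the
    label of any correctly classified training point of a different class.

    Distances depend only on the label pair, so they are computed once per
    distinct pair.  MD points with no qualifying neighbor stay flagged NaN.
    """
    in_md = np.zeros(train.n, dtype=bool)
    in_md[md.indices] = True
    present = set(train.y[~in_md].tolist())   # labels of non-MD training data
    table = enc.encode(np.asarray(enc.classes, dtype=object))
    D = _label_distance(enc, table, table, label_kernel)
    cls_idx = {c: i for i, c in enumerate(enc.classes)}
    nl = np.full(len(md), np.nan)
    for r, yi in enumerate(md.labels):
        others = [cls_idx[c] for c in present if c != yi]
        if others:
            nl[r] = float(D[cls_idx[yi], others].min())
    return MisclassifiedSet(indices=md.indices, points=md.points,
                            labels=md.labels, nl=nl)


def fit_lsa_svm(base: SVMModel, train: LabeledDataset,
                scheme: str | None = None,
                label_kernel: KernelSpec | None = None) -> AdvisedModel:
    """Extract MD, fit the label encoding, compute label-space NLs."""
    md = find_misclassified(base, train)
    scheme = scheme or default_encoding_scheme(len(train.classes))
    _, enc = encode_labels(train.y, scheme)
    md = label_neighborhood_lengths(md, train, enc, label_kernel)
    return AdvisedModel(base=base, md=md, space="label",
                        label_encoding=enc, label_kernel=label_kernel)


def _law_batch(adv: AdvisedModel, yk_vecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(LAW per row of yk_vecs, label-distance matrix to active MD points)."""
    enc: LabelEncoding = adv.label_encoding
    act = adv.md.active
    n = yk_vecs.shape[0]
    if adv.md.is_empty or not act.any():
        return np.zeros(n), np.zeros((n, 0))
    md_vecs = enc.encode(adv.md.labels[act])
    D = _label_distance(enc, yk_vecs, md_vecs, adv.label_kernel)
    nl = adv.md.nl[act]
    inside = D <= nl[None, :]
    contrib = np.where(inside, 1.0 - D / nl[None, :], 0.0)
    counts = inside.sum(axis=1)
    law = np.zeros(n)
    nz = counts > 0
    law[nz] = contrib[nz].sum(axis=1) / counts[nz]
    return np.clip(law, 0.0, 1.0), D


def label_advised_weight(adv: AdvisedModel, yk_hat, xk=None) -> float:
    """LAW in [0, 1] for one encoded (predicted) label: the mean of
    (1 - d/NL) over MD points whose label neighborhood contains yk_hat;
    0 when MD is empty or nothing qualifies."""
    if adv.space != "label":
        raise ValueError("label_advised_weight requires a label-space model")
    yk_hat = np.asarray(yk_hat, dtype=float).reshape(1, -1)
    return float(_law_batch(adv, yk_hat)[0][0])


def lsa_predict(adv: AdvisedModel, Xtest) -> np.ndarray:
    """Label-space advised decision rule over a test batch.

    Per point: encode the base prediction, compute LAW; if LAW < scaled
    |h| the base label stands, otherwise the point takes the true label of
    the label-qualifying MD point nearest in feature space (ties to the
    smallest MD index).  Empty MD reduces to the base predictor.
    """
    if adv.space != "label":
        raise ValueError("lsa_predict requires a label-space advised model")
    Xtest = np.asarray(Xtest, dtype=float)
    if Xtest.ndim == 1:
        Xtest = Xtest.reshape(1, -1)
    base_labels, proxy = decision_proxy(adv.base, Xtest)
    if adv.md.is_empty or not adv.md.active.any():
        return base_labels
    scaled = scale_decision_values(proxy)
    yk_vecs = adv.label_encoding.encode(base_labels)
    law, D = _law_batch(adv, yk_vecs)
    act = adv.md.active
    nl = adv.md.nl[act]
    act_labels = adv.md.labels[act]
    Dfeat = induced_distance_matrix(adv.base.kernel, Xtest, adv.md.points[act])
    out = base_labels.copy()
    for i in range(Xtest.shape[0]):
        if law[i] < scaled[i]:
            continue
        inside = np.flatnonzero(D[i] <= nl)
        if inside.size == 0:
            continue
        nearest = inside[np.argmin(Dfeat[i, inside])]
        out[i] = act_labels[nearest]
    return out
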