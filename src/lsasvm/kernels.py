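"""Kernel evaluation and the kernel-induced metric.

Self-advising classifiers measure how far a test point sits from the
misclassified training points *in the feature space induced by the kernel*,
not in raw input space.  For a positive-definite kernel k the induced
distance between u and v is

    d(u, v) = sqrt( k(u,u) + k(v,v) - 2 k(u,v) )

which for the RBF kernel k(u,v) = exp(-gamma * ||u-v||^2) is a bounded,
strictly increasing transform of the Euclidean distance (range [0, sqrt(2))),
and for the linear kernel coincides with the Euclidean distance exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics.pairwise import pairwise_kernels

__all__ = ["KernelSpec", "kernel_eval", "kernel_matrix", "induced_distance",
           "induced_distance_matrix"]

_KINDS = ("rbf", "linear", "polynomial", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family with its hyperparameters.

    gamma is the RBF width (also used by polynomial/sigmoid in the
    ``(gamma * <u,v> + coef0)`` form); it is never defaulted silently for
    RBF — the caller states it and it travels with the model record.
    """

    kind: str = "rbf"
    gamma: float | None = None
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind != "linear":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError(f"kernel {self.kind!r} requires gamma > 0, got {self.gamma}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError(f"polynomial degree must be a positive integer, got {self.degree}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        return cls(**d)

    @property
    def sklearn_params(self) -> dict:
        """Keyword arguments for sklearn's SVC/pairwise_kernels."""
        name = "poly" if self.kind == "polynomial" else self.kind
        params: dict = {"kernel": name}
        if self.kind != "linear":
            params["gamma"] = self.gamma
        if self.kind == "polynomial":
            params["degree"] = self.degree
        if self.kind in ("polynomial", "sigmoid"):
            params["coef0"] = self.coef0
        return params


def _as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a.reshape(1, -1)
    return a


def kernel_matrix(spec: KernelSpec, A, B) -> np.ndarray:
    """Gram matrix K[i, j] = k(A_i, B_j).

    Empty inputs produce an empty matrix of consistent shape.
    """
    A, B = _as_2d(A), _as_2d(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: A has d={A.shape[1]}, B has d={B.shape[1]}")
    if A.shape[0] == 0 or B.shape[0] == 0:
        return np.zeros((A.shape[0], B.shape[0]))
    params = spec.sklearn_params
    metric = params.pop("kernel")
    return pairwise_kernels(A, B, metric=metric, **params)


def kernel_eval(spec: KernelSpec, u, v) -> float:
    """k(u, v) for a single pair of vectors."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape[0] != v.shape[0]:
        raise ValueError(f"dimension mismatch: u has d={u.shape[0]}, v has d={v.shape[0]}")
    return float(kernel_matrix(spec, u, v)[0, 0])


def induced_distance_matrix(spec: KernelSpec, A, B) -> np.ndarray:
    """Pairwise kernel-induced distances between rows of A and rows of B.

    The radicand k(u,u) + k(v,v) - 2 k(u,v) is clamped at zero before the
    square root to absorb floating-point negatives.
    """
    A, B = _as_2d(A), _as_2d(B)
    if A.shape[0] == 0 or B.shape[0] == 0:
        return np.zeros((A.shape[0], B.shape[0]))
    kaa = np.array([kernel_matrix(spec, a, a)[0, 0] for a in A])
    kbb = np.array([kernel_matrix(spec, b, b)[0, 0] for b in B])
    kab = kernel_matrix(spec, A, B)
    rad = kaa[:, None] + kbb[None, :] - 2.0 * kab
    return np.sqrt(np.clip(rad, 0.0, None))


def induced_distance(spec: KernelSpec, u, v) -> float:
    """Kernel-induced distance between two vectors (always >= 0)."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape[0] != v.shape[0]:
        raise ValueError(f"dimension mismatch: u has d={u.shape[0]}, v has d={v.shape[0]}")
    return float(induced_distance_matrix(spec, u, v)[0, 0])
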