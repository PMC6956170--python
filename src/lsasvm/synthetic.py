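"""Synthetic data generators: every pipeline stage is testable offline.

Three generators:

* ``make_blobs`` — Gaussian-cluster classification fixtures with an exact,
  recorded fraction of flipped labels (stand-in for small tabular
  benchmark datasets).
* ``make_planted_fixture`` — a two-class fixture engineered so the advising
  layer provably corrects the base SVM: a few training labels are flipped
  near the class boundary (they land in the misclassified set), and test
  points are planted inside those points' neighborhoods with low base-SVM
  confidence.  The generator *verifies* its own guarantees by running the
  base SVM and the advised rule, retrying with a fresh sub-seed if a draw
  fails — so downstream tests never silently exercise the wrong branch.
* ``make_semg`` — protocol-faithful synthetic surface EMG: 4 channels at
  2000 Hz, trials of 3 s activity and 5 s rest per movement class,
  class-specific per-channel activation envelopes modulating white noise,
  plus 50 Hz line interference and baseline noise.  It is an amplitude
  model (envelope-modulated Gaussian noise), not a physiological
  motor-unit simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base_svm import LabeledDataset, train_svm, predict
from .emg import SignalRecording, REST
from .kernels import KernelSpec
from .sa_svm import fit_sa_svm, advised_predict

__all__ = ["BlobSpec", "SemgSpec", "make_blobs", "make_planted_fixture",
           "make_semg"]


@dataclass(frozen=True)
class BlobSpec:
    n_per_class: int = 50
    n_classes: int = 2
    dim: int = 2
    centers: tuple | None = None      # n_classes x dim; default: spread on a line
    spread: float = 1.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError(f"spread must be > 0, got {self.spread}")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError(f"label_noise must lie in [0, 0.5), got {self.label_noise}")


def _default_centers(n_classes: int, dim: int, separation: float = 6.0) -> np.ndarray:
    centers = np.zeros((n_classes, dim))
    centers[:, 0] = separation * np.arange(n_classes)
    return centers


def make_blobs(spec: BlobSpec) -> LabeledDataset:
    """Gaussian clusters with an exact count of uniformly flipped labels.

    round(label_noise * n) rows get a label drawn from the other classes;
    the pre-flip ground truth and the flipped row indices are kept in
    ``metadata``.
    """
    rng = np.random.default_rng(spec.seed)
    centers = (np.asarray(spec.centers, dtype=float) if spec.centers is not None
               else _default_centers(spec.n_classes, spec.dim))
    n = spec.n_per_class * spec.n_classes
    X = np.empty((n, spec.dim))
    y = np.empty(n, dtype=int)
    for c in range(spec.n_classes):
        sl = slice(c * spec.n_per_class, (c + 1) * spec.n_per_class)
        X[sl] = centers[c] + spec.spread * rng.standard_normal((spec.n_per_class, spec.dim))
        y[sl] = c
    order = rng.permutation(n)
    X, y = X[order], y[order]
    truth = y.copy()
    n_flip = int(round(spec.label_noise * n))
    flipped = rng.choice(n, size=n_flip, replace=False) if n_flip else np.array([], dtype=int)
    for i in flipped:
        others = [c for c in range(spec.n_classes) if c != y[i]]
        y[i] = rng.choice(others)
    ds = LabeledDataset(X, y, classes=list(range(spec.n_classes)))
    ds.metadata.update(true_labels=truth, flipped_indices=np.sort(flipped),
                       spec=spec)
    return ds


PLANTED_C = 1.0
PLANTED_GAMMA = 0.2


def make_planted_fixture(seed: int) -> tuple[LabeledDataset, LabeledDataset, np.ndarray]:
    """(train, test, expected_flips): a fixture the advised rule must fix.

    Construction (verified at generation time, retrying up to 10 sub-seeds):

    * two clusters at x = -2 and x = +2 (d = 2, spread 0.45), 40 train
      points each;
    * 3 train points are placed on the wrong side of the boundary
      (x ~ -0.9) carrying the +1 cluster's label — the base SVM
      (rbf, gamma=0.2, C=1: deliberately smooth, so it cannot carve
      islands around them) predicts -1 there, and they enter MD;
    * 3 test points are planted essentially on top of those MD points with
      true label +1: the base SVM mispredicts them with small |h| relative
      to the batch (the rest of the test set sits deep in the clusters),
      while their advised weight is near 1 — the advised rule flips them
      to the MD points' (correct) label.
    """
    kernel = KernelSpec(kind="rbf", gamma=PLANTED_GAMMA)
    for attempt in range(10):
        rng = np.random.default_rng([seed, attempt])
        n_per, spread = 40, 0.45
        Xtr = np.vstack([
            np.array([-2.0, 0.0]) + spread * rng.standard_normal((n_per, 2)),
            np.array([+2.0, 0.0]) + spread * rng.standard_normal((n_per, 2)),
        ])
        ytr = np.array([-1] * n_per + [1] * n_per)
        planted = np.array([[-0.9, -0.6], [-0.95, 0.0], [-0.9, 0.6]])
        planted += 0.05 * rng.standard_normal(planted.shape)
        Xtr = np.vstack([Xtr, planted])
        ytr = np.concatenate([ytr, [1, 1, 1]])
        planted_idx = np.arange(2 * n_per, 2 * n_per + 3)
        train = LabeledDataset(Xtr, ytr, classes=[-1, 1])

        n_te = 20
        Xte = np.vstack([
            np.array([-2.0, 0.0]) + spread * rng.standard_normal((n_te, 2)),
            np.array([+2.0, 0.0]) + spread * rng.standard_normal((n_te, 2)),
            planted + 0.02 * rng.standard_normal(planted.shape),
        ])
        yte = np.concatenate([[-1] * n_te, [1] * n_te, [1, 1, 1]])
        test = LabeledDataset(Xte, yte, classes=[-1, 1])
        expected = np.arange(2 * n_te, 2 * n_te + 3)

        base = train_svm(train, "c", kernel, PLANTED_C)
        md_idx = set(np.flatnonzero(predict(base, Xtr) != ytr).tolist())
        if not set(planted_idx.tolist()) <= md_idx:
            continue
        adv = fit_sa_svm(base, train)
        base_pred = predict(base, Xte)
        adv_pred = advised_predict(adv, Xte)
        if not np.all(base_pred[expected] == -1):
            continue                     # base must mispredict the planted tests
        if not np.all(adv_pred[expected] == 1):
            continue                     # advising must correct every one
        base_acc = np.mean(base_pred == yte)
        adv_acc = np.mean(adv_pred == yte)
        if adv_acc <= base_acc:
            continue
        train.metadata.update(planted_train_indices=planted_idx, seed=seed,
                              C=PLANTED_C, gamma=PLANTED_GAMMA)
        test.metadata.update(expected_flips=expected)
        return train, test, expected
    raise RuntimeError(
        "planted fixture failed self-verification after 10 retries — "
        "this signals a regression in the base SVM or the advising layer")


@dataclass(frozen=True)
class SemgSpec:
    """Synthetic sEMG protocol: per movement class, one trial of 3 s
    activity followed by 5 s rest, repeated ``reps`` times."""

    n_channels: int = 4
    n_classes: int = 4
    rate: float = 2000.0
    trial_active_s: float = 3.0
    trial_rest_s: float = 5.0
    reps: int = 2
    activation: tuple | None = None    # (n_classes, n_channels) envelope gains
    line_hz: float = 50.0
    line_amp: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_active_s <= 0 or self.trial_rest_s <= 0:
            raise ValueError("trial durations must be > 0")
        if self.activation is not None:
            a = np.asarray(self.activation, dtype=float)
            if a.shape != (self.n_classes, self.n_channels):
                raise ValueError(
                    f"activation must be ({self.n_classes}, {self.n_channels}), "
                    f"got {a.shape}")
            if (a < 0).any():
                raise ValueError("activation gains must be >= 0")


def _default_activation(n_classes: int, n_channels: int) -> np.ndarray:
    """Distinct per-class channel patterns: each class drives a different
    dominant channel hard (gain 2) and its neighbors weakly."""
    a = np.full((n_classes, n_channels), 0.2)
    for c in range(n_classes):
        a[c, c % n_channels] = 2.0
        a[c, (c + 1) % n_channels] = 0.8
    return a


def _smooth_burst(n_active: int, rate: float, rng) -> np.ndarray:
    """Rectangular activation burst with ~100 ms raised-cosine ramps."""
    env = np.ones(n_active)
    ramp = min(int(0.1 * rate), n_active // 4)
    if ramp > 0:
        r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] *= r
        env[-ramp:] *= r[::-1]
    return env


def make_semg(spec: SemgSpec) -> SignalRecording:
    """Generate the full trial schedule as one continuous recording.

    Schedule: for rep in reps, for class in classes: 3 s activity
    annotated with the class, then 5 s rest annotated with the rest
    marker.  Per channel: gain[class, ch] * envelope * N(0,1) during
    activity, plus a 50 Hz sinusoid and baseline noise throughout.
    """
    rng = np.random.default_rng(spec.seed)
    act = (np.asarray(spec.activation, dtype=float) if spec.activation is not None
           else _default_activation(spec.n_classes, spec.n_channels))
    n_active = int(round(spec.trial_active_s * spec.rate))
    n_rest = int(round(spec.trial_rest_s * spec.rate))
    n_trial = n_active + n_rest
    n_total = spec.reps * spec.n_classes * n_trial

    data = spec.noise_sd * rng.standard_normal((spec.n_channels, n_total))
    ann = np.full(n_total, REST, dtype=object)
    pos = 0
    for _ in range(spec.reps):
        for c in range(spec.n_classes):
            env = _smooth_burst(n_active, spec.rate, rng)
            carrier = rng.standard_normal((spec.n_channels, n_active))
            data[:, pos:pos + n_active] += act[c][:, None] * env[None, :] * carrier
            ann[pos:pos + n_active] = f"class{c}"
            pos += n_trial
    t = np.arange(n_total) / spec.rate
    data += spec.line_amp * np.sin(2 * np.pi * spec.line_hz * t)[None, :]

    names = ["TA", "Gas", "Sol", "RF"][:spec.n_channels]
    names += [f"ch{i}" for i in range(len(names), spec.n_channels)]
    return SignalRecording(data=data, rate=spec.rate, channel_names=names,
                           annotations=ann, rest_label=REST)
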