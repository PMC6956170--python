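"""Time-domain sEMG features computed per window, per channel.

The classical amplitude/complexity descriptors of the myoelectric
literature:

    MAV   mean absolute value            RMS   root mean square
    WL    waveform length (sum |diff|)   VAR   unbiased variance
    ZC    zero crossings above a threshold
    SSC   slope-sign changes above a threshold
    IEMG  integrated EMG (sum |w|)       LOG   log detector exp(mean log|w|)

ZC counts sample pairs whose product is <= 0 (a sampled zero at a crossing
still counts) with an amplitude gap above the threshold; SSC counts interior
samples where the slope changes sign and at least one adjacent difference
exceeds the threshold.  Thresholds default to 1% of the window's own RMS,
which adapts the noise gate to the window's amplitude; pass explicit
thresholds to pin them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base_svm import LabeledDataset

__all__ = ["FeatureSetSpec", "FEATURE_NAMES", "FEATURE_CODES",
           "feature_value", "extract_features"]

FEATURE_NAMES = ("MAV", "RMS", "WL", "ZC", "SSC", "VAR", "IEMG", "LOG")

# Mapping from integer feature-set codes to concrete sets.  The codes come
# from benchmark configuration tables whose key is not published; this
# mapping is provisional package configuration, not an established standard.
FEATURE_CODES = {
    11: ("MAV", "WL", "ZC"),
    13: ("MAV", "RMS", "WL", "ZC"),
    14: ("MAV", "RMS", "WL", "ZC", "SSC"),
}

_LOG_EPS = 1e-12


@dataclass(frozen=True)
class FeatureSetSpec:
    names: tuple = ("MAV", "RMS", "WL", "ZC", "SSC")
    zc_threshold: float | None = None     # None -> 0.01 * RMS of the window
    ssc_threshold: float | None = None
    code: int | None = None

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("feature set must be nonempty")
        bad = [n for n in self.names if n not in FEATURE_NAMES]
        if bad:
            raise ValueError(f"unknown feature names {bad}; known: {FEATURE_NAMES}")
        for t in (self.zc_threshold, self.ssc_threshold):
            if t is not None and t < 0:
                raise ValueError(f"thresholds must be >= 0, got {t}")

    @classmethod
    def from_code(cls, code: int) -> "FeatureSetSpec":
        if code not in FEATURE_CODES:
            raise ValueError(f"unknown feature code {code}; known: {sorted(FEATURE_CODES)}")
        return cls(names=FEATURE_CODES[code], code=code)


def _resolve_threshold(explicit: float | None, w: np.ndarray) -> float:
    if explicit is not None:
        return explicit
    return 0.01 * float(np.sqrt(np.mean(w ** 2)))


def feature_value(name: str, w, spec: FeatureSetSpec | None = None) -> float:
    """One feature of one single-channel window."""
    spec = spec or FeatureSetSpec()
    w = np.asarray(w, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("cannot compute features of an empty window")
    if name == "MAV":
        return float(np.mean(np.abs(w)))
    if name == "RMS":
        return float(np.sqrt(np.mean(w ** 2)))
    if name == "WL":
        return float(np.sum(np.abs(np.diff(w))))
    if name == "IEMG":
        return float(np.sum(np.abs(w)))
    if name == "VAR":
        return float(np.var(w, ddof=1)) if w.size > 1 else 0.0
    if name == "LOG":
        return float(np.exp(np.mean(np.log(np.abs(w) + _LOG_EPS))))
    if name == "ZC":
        thr = _resolve_threshold(spec.zc_threshold, w)
        prod = w[:-1] * w[1:]
        gap = np.abs(np.diff(w))
        return float(np.count_nonzero((prod <= 0) & (gap > thr)
                                      & ~((w[:-1] == 0) & (w[1:] == 0))))
    if name == "SSC":
        thr = _resolve_threshold(spec.ssc_threshold, w)
        d1 = w[1:-1] - w[:-2]
        d2 = w[1:-1] - w[2:]
        return float(np.count_nonzero((d1 * d2 > 0)
                                      & ((np.abs(d1) >= thr) | (np.abs(d2) >= thr))))
    raise ValueError(f"unknown feature name {name!r}; known: {FEATURE_NAMES}")


def extract_features(windows, labels, spec: FeatureSetSpec | None = None
                     ) -> LabeledDataset:
    """Turn a (nwin, channels, size) window tensor into a LabeledDataset.

    The feature vector is the channel-major concatenation: all features of
    channel 0, then channel 1, ... so d = channels * len(spec.names).
    """
    spec = spec or FeatureSetSpec()
    windows = np.asarray(windows, dtype=float)
    if windows.ndim != 3:
        raise ValueError(f"expected (nwin, channels, size) tensor, got {windows.shape}")
    nwin, nch, _ = windows.shape
    X = np.empty((nwin, nch * len(spec.names)))
    for i in range(nwin):
        col = 0
        for c in range(nch):
            for name in spec.names:
                X[i, col] = feature_value(name, windows[i, c], spec)
                col += 1
    ds = LabeledDataset(X, np.asarray(labels))
    ds.metadata["feature_names"] = [f"ch{c}_{n}" for c in range(nch)
                                    for n in spec.names]
    return ds
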