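"""Surface-EMG signal conditioning and sliding-window segmentation.

The conditioning chain is the conventional one for surface EMG: a
zero-phase 4th-order Butterworth band-pass over the 25-550 Hz band where
the myoelectric signal lives, an IIR notch at the 50 Hz mains line
(quality factor 30), polyphase downsampling to 1000 Hz, then overlapping
windows (size/increment in samples) each labeled by the majority of its
per-sample annotations.  All filters are applied forward-backward
(zero phase), so window labels stay aligned with the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = ["SignalRecording", "WindowSpec", "bandpass_filter", "notch_filter",
           "resample", "segment_windows"]

REST = "rest"


@dataclass
class SignalRecording:
    """A channels x samples recording with per-sample class annotations."""

    data: np.ndarray                  # (channels, samples), mV nominal
    rate: float                       # Hz
    channel_names: list = field(default_factory=list)
    annotations: np.ndarray | None = None   # (samples,) labels / rest marker
    rest_label: object = REST

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.rate}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations)
            if len(self.annotations) != self.data.shape[1]:
                raise ValueError(
                    f"annotations length {len(self.annotations)} != "
                    f"sample count {self.data.shape[1]}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def _replace_data(self, data: np.ndarray) -> "SignalRecording":
        return SignalRecording(data=data, rate=self.rate,
                               channel_names=list(self.channel_names),
                               annotations=None if self.annotations is None
                               else self.annotations.copy(),
                               rest_label=self.rest_label)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window size W and hop I, both in samples."""

    size: int
    increment: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"window size must be >= 1, got {self.size}")
        if not (1 <= self.increment <= self.size):
            raise ValueError(
                f"increment must lie in [1, size={self.size}], got {self.increment}")


def bandpass_filter(rec: SignalRecording, low: float = 25.0,
                    high: float = 550.0, order: int = 4) -> SignalRecording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    if not (0 < low < high):
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= rec.rate / 2:
        raise ValueError(
            f"band edge {high} Hz reaches the Nyquist frequency of a "
            f"{rec.rate} Hz recording")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    return rec._replace_data(sps.sosfiltfilt(sos, rec.data, axis=1))


def notch_filter(rec: SignalRecording, freq: float = 50.0,
                 quality: float = 30.0) -> SignalRecording:
    """Zero-phase IIR notch at ``freq`` (line interference removal)."""
    if not (0 < freq < rec.rate / 2):
        raise ValueError(
            f"notch frequency {freq} Hz outside (0, Nyquist) for a "
            f"{rec.rate} Hz recording")
    b, a = sps.iirnotch(freq, quality, fs=rec.rate)
    return rec._replace_data(sps.filtfilt(b, a, rec.data, axis=1))


def resample(rec: SignalRecording, target_rate: float) -> SignalRecording:
    """Polyphase resampling to ``target_rate``; annotations follow by
    nearest original index."""
    if target_rate <= 0:
        raise ValueError(f"target rate must be > 0, got {target_rate}")
    if target_rate == rec.rate:
        return rec._replace_data(rec.data.copy())
    frac = Fraction(target_rate / rec.rate).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    data = sps.resample_poly(rec.data, up, down, axis=1)
    ann = None
    if rec.annotations is not None:
        src = np.clip(np.round(np.arange(data.shape[1]) * rec.rate / target_rate),
                      0, rec.n_samples - 1).astype(int)
        ann = rec.annotations[src]
    return SignalRecording(data=data, rate=target_rate,
                           channel_names=list(rec.channel_names),
                           annotations=ann, rest_label=rec.rest_label)


def segment_windows(rec: SignalRecording, spec: WindowSpec,
                    drop_rest: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Cut (nwin, channels, size) windows with hop ``increment``.

    nwin = floor((samples - size)/increment) + 1 (0 when the recording is
    shorter than one window).  Each window's label is the majority of its
    per-sample annotations, ties broken toward the earlier label in sorted
    class order; windows labeled with the rest marker are dropped when
    ``drop_rest`` and annotations exist.
    """
    n = rec.n_samples
    if n < spec.size:
        return (np.zeros((0, rec.n_channels, spec.size)), np.zeros(0, dtype=object))
    starts = np.arange(0, n - spec.size + 1, spec.increment)
    windows = np.stack([rec.data[:, s:s + spec.size] for s in starts])
    if rec.annotations is None:
        return windows, np.full(len(starts), None, dtype=object)
    class_order = sorted(set(rec.annotations.tolist()), key=str)
    rank = {c: i for i, c in enumerate(class_order)}
    labels = []
    for s in starts:
        seg = rec.annotations[s:s + spec.size].tolist()
        counts: dict = {}
        for v in seg:
            counts[v] = counts.get(v, 0) + 1
        best = max(counts, key=lambda c: (counts[c], -rank[c]))
        labels.append(best)
    labels = np.asarray(labels, dtype=object)
    if drop_rest:
        keep = labels != rec.rest_label
        windows, labels = windows[keep], labels[keep]
    return windows, labels
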