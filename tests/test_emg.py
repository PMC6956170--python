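import numpy as np
import pytest

from lsasvm import (SignalRecording, WindowSpec, bandpass_filter,
                    notch_filter, resample, segment_windows)


def _tone(freq, rate=2000.0, seconds=2.0):
    t = np.arange(int(rate * seconds)) / rate
    return SignalRecording(data=np.sin(2 * np.pi * freq * t)[None, :], rate=rate)


def _power(rec):
    return float(np.mean(rec.data ** 2))


class TestBandpass:
    def test_dc_is_suppressed(self):
        rec = SignalRecording(data=np.ones((1, 4000)), rate=2000.0)
        out = bandpass_filter(rec)
        assert _power(out) < 1e-6 * _power(rec)

    def test_passband_tone_preserved_within_3db(self):
        rec = _tone(200.0)
        out = bandpass_filter(rec)
        assert _power(out) > 0.5 * _power(rec)   # -3 dB in power

    def test_band_edge_errors(self):
        rec = _tone(100.0)
        with pytest.raises(ValueError, match="low"):
            bandpass_filter(rec, low=300.0, high=200.0)
        with pytest.raises(ValueError, match="2000"):
            bandpass_filter(rec, low=25.0, high=1000.0)


class TestNotch:
    def test_line_tone_attenuated_20db(self):
        rec = _tone(50.0, seconds=4.0)
        out = notch_filter(rec, 50.0)
        # compare steady state (middle half), away from filtfilt edge transients
        mid = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)
        assert np.mean(out.data[:, mid] ** 2) < 0.01 * np.mean(rec.data[:, mid] ** 2)

    def test_distant_tone_untouched_within_1db(self):
        rec = _tone(200.0)
        out = notch_filter(rec, 50.0)
        assert _power(out) > 10 ** (-0.1) * _power(rec)

    def test_nyquist_error(self):
        with pytest.raises(ValueError, match="Nyquist"):
            notch_filter(_tone(100.0), 1500.0)


class TestResample:
    def test_halving_rate_halves_samples(self):
        rec = SignalRecording(data=np.random.default_rng(0).normal(size=(2, 2000)),
                              rate=2000.0,
                              annotations=np.array(["a"] * 1000 + ["b"] * 1000))
        out = resample(rec, 1000.0)
        assert out.n_samples == 1000 and out.rate == 1000.0
        assert out.annotations[0] == "a" and out.annotations[-1] == "b"

    def test_identity_when_target_equals_source(self):
        rec = _tone(100.0)
        out = resample(rec, rec.rate)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_above_target_nyquist_suppressed(self):
        rec = _tone(800.0, rate=2000.0)      # above the 500 Hz target Nyquist
        out = resample(rec, 1000.0)
        assert _power(out) < 0.01 * _power(rec)


class TestSegmentation:
    def _rec(self, n, ann=None):
        return SignalRecording(data=np.arange(n, dtype=float)[None, :],
                               rate=1000.0, annotations=ann)

    @pytest.mark.parametrize("n,size,inc,expected", [
        (1000, 50, 15, 64),
        (50, 50, 50, 1),
        (49, 50, 50, 0),
    ])
    def test_window_counts(self, n, size, inc, expected):
        w, _ = segment_windows(self._rec(n), WindowSpec(size, inc))
        assert w.shape[0] == expected

    def test_majority_label_and_tie_break(self):
        ann = np.array(["b"] * 25 + ["a"] * 25)
        _, labels = segment_windows(self._rec(50, ann), WindowSpec(50, 50))
        assert labels[0] == "a"              # tie -> earlier label in class order
        ann2 = np.array(["b"] * 30 + ["a"] * 20)
        _, labels2 = segment_windows(self._rec(50, ann2), WindowSpec(50, 50))
        assert labels2[0] == "b"

    def test_rest_windows_dropped(self):
        ann = np.array(["rest"] * 50 + ["a"] * 50)
        w, labels = segment_windows(self._rec(100, ann), WindowSpec(50, 50))
        assert labels.tolist() == ["a"] and w.shape[0] == 1

    def test_windows_reconstruct_from_start_indices(self):
        rec = self._rec(200)
        spec = WindowSpec(30, 7)
        w, _ = segment_windows(rec, spec)
        for k in range(w.shape[0]):
            start = k * spec.increment
            assert start + spec.size <= rec.n_samples
            np.testing.assert_array_equal(w[k, 0], rec.data[0, start:start + spec.size])

    def test_window_spec_validation(self):
        with pytest.raises(ValueError, match="increment"):
            WindowSpec(10, 11)
        with pytest.raises(ValueError, match="size"):
            WindowSpec(0, 1)


def test_filtering_is_linear():
    rng = np.random.default_rng(1)
    rec = SignalRecording(data=rng.normal(size=(1, 4000)), rate=2000.0)
    scaled = SignalRecording(data=3.0 * rec.data, rate=2000.0)
    np.testing.assert_allclose(bandpass_filter(scaled).data,
                               3.0 * bandpass_filter(rec).data, atol=1e-9)


def test_full_chain_preserves_channels_and_is_deterministic():
    rng = np.random.default_rng(2)
    ann = np.array(["a"] * 4000 + ["rest"] * 4000)
    rec = SignalRecording(data=rng.normal(size=(4, 8000)), rate=2000.0,
                          annotations=ann)

    def chain(r):
        r = notch_filter(bandpass_filter(r), 50.0)
        r = resample(r, 1000.0)
        return segment_windows(r, WindowSpec(50, 15))

    w1, l1 = chain(rec)
    w2, l2 = chain(rec)
    assert w1.shape[1] == 4
    np.testing.assert_array_equal(w1, w2)
    np.testing.assert_array_equal(l1, l2)
    assert np.all(np.isfinite(w1))
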