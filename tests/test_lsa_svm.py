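import numpy as np
import pytest

from lsasvm import (AdvisedModel, BlobSpec, KernelSpec, LabeledDataset,
                    MisclassifiedSet, encode_labels, find_misclassified,
                    fit_lsa_svm, label_advised_weight,
                    label_neighborhood_lengths, lsa_predict, make_blobs,
                    predict, train_svm)
from lsasvm.lsa_svm import LabelEncoding, default_encoding_scheme


class TestLabelEncoding:
    def test_signed_binary_sorted_convention(self):
        M, enc = encode_labels(["B", "A", "A"], "signed_binary")
        assert enc.classes == ["A", "B"]
        np.testing.assert_array_equal(M.ravel(), [1.0, -1.0, -1.0])

    def test_one_hot_unit_basis(self):
        M, enc = encode_labels(["A", "B", "C"], "one_hot")
        np.testing.assert_array_equal(M, np.eye(3))

    def test_round_trip_all_schemes(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["x", "y", "z"], size=40)
        for scheme in ("one_hot", "integer_code"):
            M, enc = encode_labels(labels, scheme)
            np.testing.assert_array_equal(enc.decode(M), labels)
        two = rng.choice(["p", "q"], size=40)
        M, enc = encode_labels(two, "signed_binary")
        np.testing.assert_array_equal(enc.decode(M), two)

    def test_signed_binary_requires_two_classes(self):
        with pytest.raises(ValueError, match="exactly 2"):
            encode_labels(["a", "b", "c"], "signed_binary")

    def test_default_scheme_rule(self):
        assert default_encoding_scheme(2) == "signed_binary"
        assert default_encoding_scheme(4) == "one_hot"


def _md(points, labels, indices=None, nl=None):
    m = len(labels)
    return MisclassifiedSet(
        indices=np.arange(m) if indices is None else indices,
        points=points, labels=labels,
        nl=np.full(m, np.nan) if nl is None else nl)


def test_binary_label_nl_is_exactly_two(noisy, noisy_model):
    """Signed encoding, plain distance: every MD point with a qualifying
    neighbor gets NL = |(-1) - (+1)| = 2 exactly."""
    md = find_misclassified(noisy_model, noisy)
    _, enc = encode_labels(noisy.y, "signed_binary")
    md = label_neighborhood_lengths(md, noisy, enc)
    assert np.all(md.nl[md.active] == 2.0)
    assert md.active.all()


def test_binary_label_nl_with_label_rbf():
    gamma = 0.7
    train = LabeledDataset(np.array([[0.0], [1.0], [2.0]]), np.array([0, 1, 1]))
    md = _md(np.array([[0.0]]), np.array([0]))
    _, enc = encode_labels(train.y, "signed_binary")
    out = label_neighborhood_lengths(md, train, enc,
                                     label_kernel=KernelSpec("rbf", gamma=gamma))
    expected = np.sqrt(2 - 2 * np.exp(-4 * gamma))
    assert out.nl[0] == pytest.approx(expected)


def test_one_hot_label_nl_is_sqrt_two():
    train = LabeledDataset(np.zeros((6, 2)) + np.arange(6)[:, None],
                           np.array([0, 0, 1, 1, 2, 2]))
    md = _md(train.X[:1], train.y[:1], indices=np.array([0]))
    _, enc = encode_labels(train.y, "one_hot")
    out = label_neighborhood_lengths(md, train, enc)
    assert out.nl[0] == pytest.approx(np.sqrt(2))


class _StubBase:
    def __init__(self, kernel):
        self.kernel = kernel


def _label_model(md, classes=(-1, 1)):
    enc = LabelEncoding(scheme="signed_binary", classes=list(classes))
    return AdvisedModel(base=_StubBase(KernelSpec("rbf", gamma=1.0)), md=md,
                        space="label", label_encoding=enc)


def test_law_zero_when_md_empty():
    adv = _label_model(_md(np.zeros((0, 2)), np.array([], dtype=int)))
    assert label_advised_weight(adv, [1.0]) == 0.0


def test_law_is_fraction_of_md_sharing_the_predicted_label():
    """Binary, plain distance: distances are 0 or 2 and NL = 2, so every
    MD point qualifies and LAW = fraction of MD labeled like the query."""
    md = _md(np.zeros((5, 2)), np.array([1, 1, 1, -1, -1]),
             nl=np.full(5, 2.0))
    adv = _label_model(md)
    assert label_advised_weight(adv, [1.0]) == pytest.approx(3 / 5)
    assert label_advised_weight(adv, [-1.0]) == pytest.approx(2 / 5)
    # coincident label contributes exactly 1
    single = _label_model(_md(np.zeros((1, 2)), np.array([1]), nl=np.array([2.0])))
    assert label_advised_weight(single, [1.0]) == pytest.approx(1.0)


def test_empty_md_reduces_to_base_predict(separable, rbf):
    base = train_svm(separable, "c", rbf, 100.0)
    adv = fit_lsa_svm(base, separable)
    assert adv.md.is_empty
    Xt = np.random.default_rng(5).normal(0, 3, size=(25, 2))
    np.testing.assert_array_equal(lsa_predict(adv, Xt), predict(base, Xt))


def test_relabel_branch_flips_low_confidence_point(separable, rbf):
    """Rule mechanics: a test point whose base prediction is shared by
    most MD points (high LAW) but whose nearest MD point in feature space
    carries the other label gets relabeled to that other label."""
    base = train_svm(separable, "c", rbf, 100.0)
    pred = predict(base, separable.X)
    # a low-|h| probe: midpoint between the class centers
    centers = [separable.X[separable.y == c].mean(axis=0) for c in separable.classes]
    probe = np.mean(centers, axis=0)
    base_label = predict(base, probe.reshape(1, -1))[0]
    other = [c for c in separable.classes if c != base_label][0]
    # hand-built MD: 4 points far away sharing the base label (LAW = 4/5),
    # 1 point on the probe carrying the other label (nearest in feature space)
    pts = np.vstack([np.full((4, 2), 50.0), probe])
    md = _md(pts, np.array([base_label] * 4 + [other]), nl=np.full(5, 2.0))
    enc = LabelEncoding("signed_binary", classes=list(separable.classes))
    adv = AdvisedModel(base=base, md=md, space="label", label_encoding=enc)
    # batch: deep-cluster points give the scale; probe's scaled |h| ~ 0
    Xt = np.vstack([separable.X[:10], probe])
    out = lsa_predict(adv, Xt)
    assert out[-1] == other != base_label


def test_lsa_labels_stay_in_class_set(noisy, noisy_model):
    adv = fit_lsa_svm(noisy_model, noisy)
    Xt = np.random.default_rng(6).normal(0, 4, size=(50, noisy.d))
    assert set(lsa_predict(adv, Xt).tolist()) <= set(noisy.classes)


def test_label_space_advising_touches_fewer_numbers_than_feature_space():
    """The advising pass cost scales with |MD| * n_test * vector length;
    encoded labels are no longer than feature vectors, so the label-space
    operation count never exceeds the feature-space count."""
    ds = make_blobs(BlobSpec(n_per_class=30, n_classes=4, dim=12, spread=2.5,
                             label_noise=0.1, seed=2))
    base = train_svm(ds, "c", KernelSpec("rbf", gamma=0.1), 1.0)
    adv = fit_lsa_svm(base, ds)
    n_test = 100
    label_ops = len(adv.md) * n_test * adv.label_encoding.dim
    feature_ops = len(adv.md) * n_test * ds.d
    assert adv.label_encoding.dim <= ds.d
    assert label_ops <= feature_ops
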