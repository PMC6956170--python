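import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lsasvm import (AdvisedModel, BlobSpec, KernelSpec, LabeledDataset,
                    MisclassifiedSet, advised_predict, advised_weight,
                    find_misclassified, fit_sa_svm, make_blobs,
                    neighborhood_lengths, predict, scale_decision_values,
                    train_svm)
from lsasvm.kernels import induced_distance


def test_separable_fit_has_empty_misclassified_set(separable, rbf):
    base = train_svm(separable, "c", rbf, 100.0)
    md = find_misclassified(base, separable)
    assert md.is_empty


def test_misclassified_set_equals_definitional_comprehension(noisy, noisy_model):
    md = find_misclassified(noisy_model, noisy)
    pred = predict(noisy_model, noisy.X)
    expected = [i for i in range(noisy.n) if pred[i] != noisy.y[i]]
    assert md.indices.tolist() == expected
    assert len(md) > 0  # the noisy fixture must actually exercise the layer


def test_neighborhood_length_single_qualifying_neighbor(linear):
    """MD point (0,0) labeled +1; non-MD neighbors (0,3) labeled -1 and
    (1,0) labeled +1: only the opposite-label point qualifies, NL = 3."""
    train = LabeledDataset(np.array([[0.0, 0.0], [0.0, 3.0], [1.0, 0.0]]),
                           np.array([1, -1, 1]))
    md = MisclassifiedSet(indices=[0], points=[[0.0, 0.0]], labels=[1],
                          nl=[np.nan])
    md = neighborhood_lengths(md, train, linear)
    assert md.nl[0] == pytest.approx(3.0)


def test_neighborhood_lengths_match_double_loop_oracle(noisy, noisy_model):
    kernel = noisy_model.kernel
    md = neighborhood_lengths(find_misclassified(noisy_model, noisy),
                              noisy, kernel)
    in_md = set(md.indices.tolist())
    for r, i in enumerate(md.indices):
        best = np.inf
        for j in range(noisy.n):
            if j in in_md or noisy.y[j] == noisy.y[i]:
                continue
            best = min(best, induced_distance(kernel, noisy.X[i], noisy.X[j]))
        if np.isinf(best):
            assert not np.isfinite(md.nl[r])
        else:
            assert md.nl[r] == pytest.approx(best, abs=1e-12)


def test_no_qualifying_neighbor_is_flagged_and_excluded(linear):
    """All non-MD points share the MD point's label: NL stays NaN and the
    point contributes nothing to advising."""
    train = LabeledDataset(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
                           np.array([1, 1, 1]))
    md = MisclassifiedSet(indices=[0], points=[[0.0, 0.0]], labels=[1], nl=[np.nan])
    md = neighborhood_lengths(md, train, linear)
    assert not np.isfinite(md.nl[0])
    assert not md.active.any()


def _advised(base, md):
    return AdvisedModel(base=base, md=md, space="feature")


def test_advised_weight_zero_branches_and_coincident_point(separable, rbf):
    base = train_svm(separable, "c", rbf, 100.0)
    empty = MisclassifiedSet(indices=[], points=np.zeros((0, 2)), labels=[], nl=[])
    assert advised_weight(_advised(base, empty), [0.0, 0.0]) == 0.0
    # a far test point outside every neighborhood
    md = MisclassifiedSet(indices=[0], points=[[0.0, 0.0]], labels=[1], nl=[1.0])
    assert advised_weight(_advised(base, md), [50.0, 50.0]) == 0.0
    # coincident with a single MD point of NL=1 -> full weight
    assert advised_weight(_advised(base, md), [0.0, 0.0]) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_advised_weight_bounded_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    kernel = KernelSpec("rbf", gamma=0.5)
    m = rng.integers(1, 6)
    md = MisclassifiedSet(indices=np.arange(m),
                          points=rng.normal(size=(m, 3)),
                          labels=rng.integers(0, 2, m),
                          nl=rng.uniform(0.1, 2.0, m))
    class _Stub:
        pass
    stub = _Stub()
    stub.kernel = kernel
    adv = AdvisedModel(base=stub, md=md, space="feature")
    xk = rng.normal(size=3)
    assert 0.0 <= advised_weight(adv, xk) <= 1.0


def test_scale_decision_values_examples_and_properties():
    np.testing.assert_allclose(scale_decision_values([-2.0, 1.0, 0.0]),
                               [1.0, 0.5, 0.0])
    np.testing.assert_allclose(scale_decision_values([0.0, 0.0]), [0.0, 0.0])
    assert scale_decision_values([]).size == 0
    rng = np.random.default_rng(4)
    v = rng.normal(size=30)
    s = scale_decision_values(v)
    assert np.all((0 <= s) & (s <= 1))
    # order of magnitudes preserved
    assert np.array_equal(np.argsort(np.abs(v)), np.argsort(s, kind="stable"))


def test_empty_md_reduces_to_base_predict_over_seeds():
    for seed in range(20):
        ds = make_blobs(BlobSpec(n_per_class=20, spread=0.4, seed=seed))
        base = train_svm(ds, "c", KernelSpec("rbf", gamma=1.0), 100.0)
        adv = fit_sa_svm(base, ds)
        assert adv.md.is_empty
        Xt = np.random.default_rng(seed).normal(0, 3, size=(15, 2))
        np.testing.assert_array_equal(advised_predict(adv, Xt), predict(base, Xt))


def test_planted_fixture_correction(planted):
    """On the self-verified planted fixture the advised rule flips every
    expected test index and strictly improves on the base SVM."""
    train, test, expected = planted
    kernel = KernelSpec("rbf", gamma=train.metadata["gamma"])
    base = train_svm(train, "c", kernel, train.metadata["C"])
    adv = fit_sa_svm(base, train)
    base_pred = predict(base, test.X)
    adv_pred = advised_predict(adv, test.X)
    assert np.all(adv_pred[expected] != base_pred[expected])
    assert np.all(adv_pred[expected] == test.y[expected])
    assert np.mean(adv_pred == test.y) > np.mean(base_pred == test.y)


def test_advised_labels_stay_in_training_class_set(noisy, noisy_model):
    adv = fit_sa_svm(noisy_model, noisy)
    Xt = np.random.default_rng(9).normal(0, 4, size=(50, noisy.d))
    assert set(advised_predict(adv, Xt).tolist()) <= set(noisy.classes)
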