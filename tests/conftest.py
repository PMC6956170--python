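import numpy as np
import pytest

from lsasvm import (BlobSpec, KernelSpec, LabeledDataset, make_blobs,
                    make_planted_fixture, train_svm)

RBF1 = KernelSpec(kind="rbf", gamma=1.0)
LINEAR = KernelSpec(kind="linear")


@pytest.fixture(scope="session")
def rbf():
    return RBF1


@pytest.fixture(scope="session")
def linear():
    return LINEAR


@pytest.fixture(scope="session")
def separable():
    """Two well-separated Gaussian blobs: an SVM fits them perfectly."""
    return make_blobs(BlobSpec(n_per_class=30, n_classes=2, spread=0.5, seed=42))


@pytest.fixture(scope="session")
def noisy():
    """Overlapping blobs with 10% flipped labels: guarantees a nonempty
    misclassified set for a moderately regularized SVM."""
    return make_blobs(BlobSpec(n_per_class=30, n_classes=2, spread=1.5,
                               label_noise=0.1, seed=7))


@pytest.fixture(scope="session")
def noisy_model(noisy):
    return train_svm(noisy, "c", KernelSpec(kind="rbf", gamma=0.3), 1.0)


@pytest.fixture(scope="session")
def planted():
    return make_planted_fixture(seed=1)
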