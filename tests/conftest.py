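import numpy as np
import pytest

from pddm.kernels import GramMatrix, KernelConfig, compute_gram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_config():
    return KernelConfig(family="gaussian", sigma=1.5, theta=1.0)


def linear_gram(features: np.ndarray) -> GramMatrix:
    """Linear-kernel Gram, for which RKHS formulas have an explicit
    feature-space counterpart usable as an oracle."""
    features = np.asarray(features, dtype=float)
    return GramMatrix(values=features @ features.T, sample_count=features.shape[0])


@pytest.fixture
def small_two_domain(rng):
    """A tiny labeled source / unlabeled target pair (C = 2, d = 2)."""
    n, m = 12, 10
    source = np.vstack(
        [rng.normal([0, 0], 0.3, size=(6, 2)), rng.normal([3, 3], 0.3, size=(6, 2))]
    )
    source_labels = np.repeat([1, 2], 6)
    target = np.vstack(
        [rng.normal([0.2, 0], 0.3, size=(5, 2)), rng.normal([3.2, 3], 0.3, size=(5, 2))]
    )
    target_labels = np.repeat([1, 2], 5)
    return source, source_labels, target, target_labels


def pooled_gram(source, target, config=None):
    if config is None:
        config = KernelConfig(family="gaussian", sigma=2.0)
    pooled = np.vstack([source, target])
    return compute_gram(pooled, config)
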