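"""Gram construction, blended class means and kernel-space distances."""

import numpy as np
import pytest

from pddm.kernels import (
    INACTIVE_SENTINEL,
    KernelConfig,
    class_mean_coefficients,
    compute_gram,
    default_bandwidth,
    median_pairwise_bandwidth,
    rkhs_mean_distances,
)

from conftest import linear_gram

FAMILIES = ["gaussian", "inverse_square_distance", "laplacian_kernel", "inverse_distance"]


class TestComputeGram:
    def test_gaussian_unit_diagonal_and_closed_form(self):
        sigma = 1.7
        X = np.array([[0.0, 0.0], [0.0, 2.0 * sigma]])
        gram = compute_gram(X, KernelConfig(family="gaussian", sigma=sigma))
        assert np.allclose(np.diag(gram.values), 1.0)
        # ||x_i - x_j|| = 2 sigma  =>  exp(-4 sigma^2 / (2 sigma^2)) = exp(-2)
        assert gram.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_generalized_bandwidth_matches_scalar_evaluation(self, rng):
        X = rng.normal(size=(10, 3))
        sigma, theta = 1.3, 2.0
        gram = compute_gram(X, KernelConfig(family="gaussian", sigma=sigma, theta=theta))
        for i in range(10):
            for j in range(10):
                expected = np.exp(
                    -np.sum((X[i] - X[j]) ** 2) / (2.0 * (sigma / theta) ** 2)
                )
                assert gram.values[i, j] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_symmetric_and_psd(self, family, rng):
        X = rng.normal(size=(15, 4))
        gram = compute_gram(X, KernelConfig(family=family, sigma=0.8))
        K = gram.values
        assert np.allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_multi_kernel_is_sum_of_components(self, rng):
        X = rng.normal(size=(8, 3))
        parts = (
            KernelConfig(family="gaussian", sigma=1.0),
            KernelConfig(family="laplacian_kernel", sigma=0.5),
        )
        combined = compute_gram(X, KernelConfig(components=parts))
        expected = sum(compute_gram(X, p).values for p in parts)
        assert np.allclose(combined.values, expected, atol=1e-12)

    def test_larger_theta_never_increases_offdiagonal(self, rng):
        X = rng.normal(size=(12, 3))
        g1 = compute_gram(X, KernelConfig(family="gaussian", sigma=1.0, theta=1.0)).values
        g2 = compute_gram(X, KernelConfig(family="gaussian", sigma=1.0, theta=3.0)).values
        off = ~np.eye(12, dtype=bool)
        assert np.all(g2[off] <= g1[off] + 1e-15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            KernelConfig(family="gaussian", sigma=0.0)
        with pytest.raises(ValueError, match="theta"):
            KernelConfig(family="gaussian", sigma=1.0, theta=0.5)
        with pytest.raises(ValueError, match="non-finite"):
            compute_gram(np.array([[np.nan, 1.0]]), KernelConfig())
        with pytest.raises(ValueError, match="non-empty"):
            KernelConfig(components=())


class TestBandwidthHeuristics:
    def test_average_norm_rule(self):
        X = np.array([[3.0, 4.0], [3.0, 4.0]])  # norms all 5
        assert default_bandwidth(X, n_classes=2) == pytest.approx(np.sqrt(5.0))
        assert default_bandwidth(X, n_classes=3) == pytest.approx(3 * np.sqrt(5.0))

    def test_median_pairwise(self):
        X = np.array([[0.0], [1.0], [3.0]])
        assert median_pairwise_bandwidth(X) == pytest.approx(2.0)


class TestClassMeanCoefficients:
    def test_single_pair_midpoint(self):
        means = class_mean_coefficients([1], [1], delta=0.5)
        assert np.allclose(means.coefficients[0], [0.5, 0.5])

    def test_delta_one_supported_on_source_only(self):
        means = class_mean_coefficients([1, 2], [1, 2], delta=1.0)
        assert np.all(means.coefficients[:, 2:] == 0.0)

    def test_three_class_weights_and_normalization(self):
        source = [1, 1, 2, 3]
        target = [1, 1, 1, 2, 3]
        means = class_mean_coefficients(source, target, delta=0.5)
        a1 = means.coefficients[1]
        assert np.allclose(a1[:2], 0.25)
        assert np.allclose(a1[4:7], 1.0 / 6.0)
        assert means.coefficients[1:].sum(axis=1) == pytest.approx(np.ones(3))

    def test_empty_side_gets_full_weight(self):
        means = class_mean_coefficients([1, 2], [1, 1], delta=0.5)
        # class 2 has no target members: full weight to the single source row
        assert np.allclose(means.coefficients[2], [0.0, 1.0, 0.0, 0.0])
        assert means.active[2]

    def test_both_sides_empty_flags_inactive(self):
        means = class_mean_coefficients([1, 1], [1], delta=0.5, n_classes=2)
        assert not means.active[2]
        assert np.all(means.coefficients[2] == 0.0)

    def test_invalid_delta_and_labels(self):
        with pytest.raises(ValueError, match="delta"):
            class_mean_coefficients([1], [1], delta=1.5)
        with pytest.raises(ValueError, match="labels"):
            class_mean_coefficients([0], [1], delta=0.5)


class TestRkhsMeanDistances:
    def test_single_sample_equal_to_mean_has_zero_distance(self):
        from pddm.kernels import ClassMeanCoefficients

        gram = linear_gram(np.array([[2.0, 1.0]]))
        means = ClassMeanCoefficients(coefficients=np.array([[1.0]]), delta=0.5)
        d = rkhs_mean_distances(gram, means)
        assert d[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_kernel_matches_explicit_feature_space(self, rng):
        for _ in range(20):
            n, m = 3, 3
            X = rng.normal(size=(n + m, 2))
            src = rng.integers(1, 3, size=n)
            tgt = rng.integers(1, 3, size=m)
            means = class_mean_coefficients(src, tgt, delta=0.5, n_classes=2)
            d = rkhs_mean_distances(linear_gram(X), means)
            for c in range(3):
                if not means.active[c]:
                    continue
                mu = means.coefficients[c] @ X
                explicit = np.sum((X - mu) ** 2, axis=1)
                assert np.allclose(d[:, c], explicit, atol=1e-12)

    def test_duplicated_domains_give_paired_distances(self, rng):
        X = rng.normal(size=(5, 3))
        pooled = np.vstack([X, X])
        gram = compute_gram(pooled, KernelConfig(family="gaussian", sigma=1.0))
        labels = np.ones(5, dtype=int)
        means = class_mean_coefficients(labels, labels, delta=0.5, n_classes=1)
        d = rkhs_mean_distances(gram, means)
        assert np.allclose(d[:5, 0], d[5:, 0], atol=1e-12)

    def test_inactive_class_column_is_sentinel(self):
        gram = linear_gram(np.array([[1.0], [2.0]]))
        means = class_mean_coefficients([1], [1], delta=0.5, n_classes=2)
        d = rkhs_mean_distances(gram, means)
        assert np.all(d[:, 2] == INACTIVE_SENTINEL)
        assert np.all(d[:, :2] >= 0.0)
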