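"""Empirical MMD, its one-cluster-center bound, and the membership update."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pddm.kernels import KernelConfig, compute_gram
from pddm.metric import (
    DistanceBundle,
    MembershipMatrix,
    mmd_empirical,
    one_cluster_bound,
    pddm_objective,
    update_memberships,
)

from conftest import linear_gram


def _bundle(d, e):
    return DistanceBundle(mean_distances=np.atleast_2d(d), residuals=np.atleast_1d(e))


class TestMmdEmpirical:
    def test_identical_multisets_zero(self, rng):
        X = rng.normal(size=(6, 3))
        gram = compute_gram(np.vstack([X, X]), KernelConfig(sigma=1.0))
        assert mmd_empirical(gram, np.arange(6), np.arange(6, 12)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_single_pair_linear_kernel_is_squared_distance(self):
        x_s, x_t = np.array([1.0, 2.0]), np.array([3.0, -1.0])
        gram = linear_gram(np.vstack([x_s, x_t]))
        assert mmd_empirical(gram, [0], [1]) == pytest.approx(
            np.sum((x_s - x_t) ** 2), abs=1e-12
        )

    def test_matches_bruteforce_double_sum(self, rng):
        X = rng.normal(size=(16, 4))
        gram = compute_gram(X, KernelConfig(sigma=1.2))
        src, tgt = np.arange(8), np.arange(8, 16)
        K = gram.values
        total = 0.0
        for i in src:
            for j in src:
                total += K[i, j] / 64
        for i in tgt:
            for j in tgt:
                total += K[i, j] / 64
        for i in src:
            for j in tgt:
                total -= 2 * K[i, j] / 64
        assert mmd_empirical(gram, src, tgt) == pytest.approx(max(total, 0.0), abs=1e-12)

    def test_empty_or_overlapping_sets_rejected(self, rng):
        gram = compute_gram(rng.normal(size=(4, 2)), KernelConfig())
        with pytest.raises(ValueError):
            mmd_empirical(gram, [], [1])
        with pytest.raises(ValueError):
            mmd_empirical(gram, [0, 1], [1, 2])


class TestOneClusterBound:
    def test_single_point_pair_zero(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0]])
        gram = linear_gram(X)
        assert one_cluster_bound(gram, [0], [1], 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_scaled_bound_dominates_mmd(self, rng):
        # the derivable inequality: MMD <= 2 max(n, m) * one-cluster bound
        # (||a - b||^2 <= 2||a||^2 + 2||b||^2 plus Cauchy-Schwarz on the sums)
        for _ in range(50):
            X = rng.normal(size=(20, 5))
            gram = compute_gram(X, KernelConfig(sigma=1.0))
            src, tgt = np.arange(10), np.arange(10, 20)
            bound = one_cluster_bound(gram, src, tgt, 0.5)
            assert 2 * 10 * bound >= mmd_empirical(gram, src, tgt) - 1e-12

    def test_identical_domains_trivially_bounded(self, rng):
        # duplicated sample multisets: MMD is exactly 0, the bound non-negative
        X = rng.normal(size=(8, 4))
        gram = compute_gram(np.vstack([X, X]), KernelConfig(sigma=1.5))
        src, tgt = np.arange(8), np.arange(8, 16)
        assert mmd_empirical(gram, src, tgt) == pytest.approx(0.0, abs=1e-12)
        assert one_cluster_bound(gram, src, tgt, 0.5) >= 0.0

    def test_matches_termwise_weighted_sum(self, rng):
        # scalar re-evaluation: varsigma_k ||phi(x_k) - mu||^2 summed explicitly
        X = rng.normal(size=(9, 3))
        gram = compute_gram(X, KernelConfig(sigma=1.2))
        src, tgt = np.arange(4), np.arange(4, 9)
        delta = 0.3
        K = gram.values
        a = np.zeros(9)
        a[src] = delta / 4
        a[tgt] = (1 - delta) / 5
        expected = 0.0
        for k in range(9):
            sq = K[k, k] - 2 * a @ K[k] + a @ K @ a
            expected += sq / (16 if k < 4 else 25)
        assert one_cluster_bound(gram, src, tgt, delta) == pytest.approx(
            expected, abs=1e-12
        )


class TestPddmObjective:
    def test_all_ones_memberships(self):
        d = np.array([[0.5, 1.0], [0.25, 2.0]])
        beta = 0.7
        lam = MembershipMatrix(values=np.ones_like(d), beta=beta)
        # ln 1 = 0 so the entropy part is -beta per entry
        assert pddm_objective(lam, d) == pytest.approx(d.sum() - beta * d.size)

    def test_all_zero_memberships(self):
        d = np.array([[0.5, np.inf]])
        lam = MembershipMatrix(values=np.zeros_like(d), beta=1.0)
        assert pddm_objective(lam, d) == 0.0

    def test_matches_termwise_evaluation(self, rng):
        d = rng.uniform(0, 3, size=(6, 3))
        values = rng.uniform(0.05, 1.0, size=(6, 3))
        beta = 1.3
        lam = MembershipMatrix(values=values, beta=beta)
        expected = 0.0
        for k in range(6):
            for c in range(3):
                sq = values[k, c] ** 2
                expected += sq * d[k, c] + beta * (sq * np.log(sq) - sq)
        assert pddm_objective(lam, d) == pytest.approx(expected, abs=1e-12)


class TestUpdateMemberships:
    def test_zero_distance_gives_full_membership(self):
        lam = update_memberships(_bundle([[0.0]], [0.0]), beta=1.0)
        assert lam.values[0, 0] == 1.0

    def test_huge_beta_gives_full_membership(self):
        lam = update_memberships(_bundle([[5.0, 2.0]], [3.0]), beta=1e9)
        assert np.allclose(lam.values, 1.0, atol=1e-8)

    def test_matches_grid_search_minimizer(self, rng):
        grid = np.linspace(1e-6, 1.0, 200_001)
        for _ in range(20):
            d = rng.uniform(0, 4)
            e = rng.uniform(0, 2)
            beta = rng.uniform(0.3, 3.0)
            g = grid**2 * (d + e) + beta * (grid**2 * np.log(grid**2) - grid**2)
            best = grid[np.argmin(g)]
            lam = update_memberships(_bundle([[d]], [e]), beta)
            assert lam.values[0, 0] == pytest.approx(best, abs=2 * (grid[1] - grid[0]))

    def test_stationary_point_of_objective(self, rng):
        d = rng.uniform(0, 3, size=(4, 2))
        e = rng.uniform(0, 1, size=4)
        beta = 0.9
        lam = update_memberships(_bundle(d, e), beta)
        # numeric gradient of the per-element objective at the returned lambda
        h = 1e-7
        for k in range(4):
            for c in range(2):
                def g(v):
                    sq = v**2
                    return sq * (d[k, c] + e[k]) + beta * (sq * np.log(sq) - sq)

                v0 = lam.values[k, c]
                grad = (g(v0 + h) - g(v0 - h)) / (2 * h)
                assert abs(grad) < 1e-6

    @given(
        d1=st.floats(0.0, 10.0),
        d2=st.floats(0.0, 10.0),
        e=st.floats(0.0, 5.0),
        beta=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_membership_strictly_decreases_in_distance(self, d1, d2, e, beta):
        lo, hi = sorted([d1, d2])
        lam = update_memberships(_bundle([[lo, hi]], [e]), beta)
        assert lam.values[0, 1] <= lam.values[0, 0]
        if (hi - lo) / beta > 1e-12:  # difference resolvable in float
            assert lam.values[0, 1] < lam.values[0, 0]

    def test_update_does_not_increase_objective(self, rng):
        d = rng.uniform(0, 3, size=(5, 3))
        e = rng.uniform(0, 1, size=5)
        beta = 1.1
        before = MembershipMatrix(values=rng.uniform(0.01, 1.0, size=(5, 3)), beta=beta)
        after = update_memberships(_bundle(d, e), beta)

        def full(lam):
            sq = lam.values**2
            risk = (sq.sum(axis=1) * e).sum()
            return pddm_objective(lam, d) + risk

        assert full(after) <= full(before) + 1e-12

    def test_underflow_produces_exact_zero(self):
        lam = update_memberships(_bundle([[1e6]], [0.0]), beta=1.0)
        assert lam.values[0, 0] == 0.0

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            update_memberships(_bundle([[1.0]], [0.0]), beta=0.0)
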