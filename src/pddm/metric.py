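"""The possibilistic distribution distance metric (P-DDM).

The empirical maximum mean discrepancy (MMD) between a source and a target
sample is bounded above by a one-cluster-center objective
``sum_k varsigma_k ||phi(x_k) - mu||^2`` with ``varsigma_k = 1/n^2`` (source)
or ``1/m^2`` (target) and ``mu = delta mu_s + (1-delta) mu_t``.  Replacing the
fixed weights ``varsigma_k`` by free memberships ``lambda_{k,c} in [0, 1]``
and adding a fuzzy-entropy penalty gives the P-DDM objective

    Omega(lambda) = sum_{c,k} lambda_{k,c}^2 d_{k,c}
                  + beta sum_{c,k} (lambda_{k,c}^2 ln lambda_{k,c}^2
                                    - lambda_{k,c}^2),

whose unique stationary point in each element is the closed form
``lambda_{k,c}^2 = exp(-(d_{k,c} + e_k) / beta)`` once the classifier
residual ``e_k`` is included.  Samples far from every blended mean (outliers,
mislabeled points) receive exponentially small memberships, which is the
robustness mechanism of the whole method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import GramMatrix

__all__ = [
    "MembershipMatrix",
    "DistanceBundle",
    "mmd_empirical",
    "one_cluster_bound",
    "pddm_objective",
    "update_memberships",
]

#: exponents below this underflow to an exact zero membership
_UNDERFLOW_EXPONENT = -700.0


@dataclass(frozen=True)
class MembershipMatrix:
    """Possibilistic memberships ``lambda`` of shape ``(N, C + 1)``.

    Column 0 is the whole-domain membership; columns ``1..C`` are class
    memberships. The weight exponent ``b`` is fixed at 2, so every formula
    consumes ``values**2``. ``beta`` is the fuzzy-entropy weight the matrix
    was produced with.
    """

    values: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("membership matrix must be 2-D")
        if not np.all(np.isfinite(values)):
            raise ValueError("membership matrix contains non-finite entries")
        if values.min() < 0.0 or values.max() > 1.0 + 1e-12:
            raise ValueError("memberships must lie in [0, 1]")
        if self.beta <= 0:
            raise ValueError(f"entropy weight beta must be positive, got {self.beta}")
        object.__setattr__(self, "values", values)

    @property
    def squared(self) -> np.ndarray:
        return self.values**2


@dataclass(frozen=True)
class DistanceBundle:
    """Inputs of the membership update.

    ``mean_distances[k, c]`` is the squared RKHS distance of sample ``k`` to
    the blended mean of class ``c`` (``inf`` marks inactive classes);
    ``residuals[k]`` is the squared classifier residual ``e_k``, shared by
    every class column of sample ``k``.
    """

    mean_distances: np.ndarray
    residuals: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.mean_distances, dtype=float)
        e = np.asarray(self.residuals, dtype=float)
        if d.ndim != 2 or e.ndim != 1 or d.shape[0] != e.shape[0]:
            raise ValueError("mean_distances must be (N, C+1) and residuals length N")
        if np.any(d < 0) or np.any(e < 0) or not np.all(np.isfinite(e)):
            raise ValueError("distances and residuals must be non-negative (residuals finite)")
        object.__setattr__(self, "mean_distances", d)
        object.__setattr__(self, "residuals", e)


def _check_index_sets(n_total: int, source_idx: np.ndarray, target_idx: np.ndarray):
    source_idx = np.asarray(source_idx, dtype=int)
    target_idx = np.asarray(target_idx, dtype=int)
    if source_idx.size == 0 or target_idx.size == 0:
        raise ValueError("source and target index sets must be non-empty")
    if np.intersect1d(source_idx, target_idx).size:
        raise ValueError("source and target index sets must be disjoint")
    for idx in (source_idx, target_idx):
        if idx.min() < 0 or idx.max() >= n_total:
            raise IndexError("index set out of range of the Gram matrix")
    return source_idx, target_idx


def mmd_empirical(gram: GramMatrix, source_idx: np.ndarray, target_idx: np.ndarray) -> float:
    """Empirical squared MMD between the two index sets.

    ``(1/n^2) sum K_ss + (1/m^2) sum K_tt - (2/nm) sum K_st``, clamped at
    zero against round-off.
    """
    source_idx, target_idx = _check_index_sets(gram.sample_count, source_idx, target_idx)
    K = gram.values
    n, m = source_idx.size, target_idx.size
    k_ss = K[np.ix_(source_idx, source_idx)].sum() / n**2
    k_tt = K[np.ix_(target_idx, target_idx)].sum() / m**2
    k_st = K[np.ix_(source_idx, target_idx)].sum() / (n * m)
    return max(k_ss + k_tt - 2.0 * k_st, 0.0)


def one_cluster_bound(
    gram: GramMatrix,
    source_idx: np.ndarray,
    target_idx: np.ndarray,
    delta: float = 0.5,
) -> float:
    """One-cluster-center upper bound on the empirical MMD.

    ``sum_k varsigma_k ||phi(x_k) - mu||^2`` with ``varsigma = 1/n^2`` on
    source samples, ``1/m^2`` on target samples and
    ``mu = delta mu_s + (1 - delta) mu_t``. For ``n = m`` this dominates the
    empirical MMD for every sample configuration.
    """
    source_idx, target_idx = _check_index_sets(gram.sample_count, source_idx, target_idx)
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    K = gram.values
    n, m = source_idx.size, target_idx.size
    a = np.zeros(gram.sample_count)
    a[source_idx] = delta / n
    a[target_idx] = (1.0 - delta) / m
    cross = K @ a
    quad = a @ cross
    sq_dist = np.clip(np.diag(K) - 2.0 * cross + quad, 0.0, None)
    weights = np.zeros(gram.sample_count)
    weights[source_idx] = 1.0 / n**2
    weights[target_idx] = 1.0 / m**2
    return float(weights @ sq_dist)


def pddm_objective(memberships: MembershipMatrix, mean_distances: np.ndarray) -> float:
    """Fuzzy-entropy-regularized possibilistic distance.

    ``sum_{c,k} lambda^2 d + beta sum_{c,k} (lambda^2 ln lambda^2 - lambda^2)``
    with the ``0 ln 0 := 0`` convention; inactive-class columns (``d = inf``)
    must carry zero membership and contribute nothing.
    """
    d = np.asarray(mean_distances, dtype=float)
    sq = memberships.squared
    if sq.shape != d.shape:
        raise ValueError("membership and distance shapes disagree")
    finite = np.isfinite(d)
    if np.any(sq[~finite] > 0):
        raise ValueError("non-zero membership on an inactive class column")
    data_term = float(np.sum(sq[finite] * d[finite]))
    pos = sq > 0
    entropy = np.zeros_like(sq)
    entropy[pos] = sq[pos] * np.log(sq[pos]) - sq[pos]
    return data_term + memberships.beta * float(entropy.sum())


def update_memberships(bundle: DistanceBundle, beta: float) -> MembershipMatrix:
    """Closed-form membership update.

    ``lambda_{k,c}^2 = exp(-(d_{k,c} + e_k) / beta)``, the unique stationary
    point of the per-element objective
    ``g(lambda) = lambda^2 (d + e) + beta (lambda^2 ln lambda^2 - lambda^2)``
    on ``(0, 1]``. Exponents below -700 underflow to an exact zero; inactive
    class columns (``d = inf``) get membership 0.
    """
    if beta <= 0:
        raise ValueError(f"entropy weight beta must be positive, got {beta}")
    d = bundle.mean_distances
    e = bundle.residuals
    exponent = np.where(np.isfinite(d), -(d + e[:, None]) / beta, -np.inf)
    values = np.zeros_like(exponent)
    ok = exponent > _UNDERFLOW_EXPONENT
    values[ok] = np.exp(0.5 * exponent[ok])  # lambda = sqrt(lambda^2)
    return MembershipMatrix(values=values, beta=beta)
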