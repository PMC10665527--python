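"""Gram-matrix construction and kernel-space distances to blended class means.

All distribution distances used by the P-DDM criterion are computed in a
reproducing kernel Hilbert space (RKHS): samples enter only through a Gram
matrix ``K`` with ``K[i, j] = <phi(x_i), phi(x_j)>``, and domain / class mean
embeddings are finite kernel expansions ``mu_c = sum_k a_c[k] phi(x_k)``.
This module builds the Gram matrices (four kernel families, a generalized
bandwidth ``sigma / theta``, and a uniform multi-kernel sum) and evaluates
squared RKHS distances from every sample to every blended class mean without
ever materializing the feature map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

__all__ = [
    "KernelConfig",
    "GramMatrix",
    "ClassMeanCoefficients",
    "compute_gram",
    "class_mean_coefficients",
    "rkhs_mean_distances",
    "default_bandwidth",
    "median_pairwise_bandwidth",
]

_FAMILIES = ("gaussian", "inverse_square_distance", "laplacian_kernel", "inverse_distance")

#: squared distances more negative than this trip an internal-consistency error
_NEGATIVE_TOL = -1e-10

#: sentinel written into distance columns of inactive classes
INACTIVE_SENTINEL = np.inf


@dataclass(frozen=True)
class KernelConfig:
    """Kernel family plus bandwidth parameterization.

    Parameters
    ----------
    family:
        One of ``gaussian`` (``exp(-||x-y||^2 / (2 (sigma/theta)^2))``),
        ``inverse_square_distance`` (``1 / (1 + s ||x-y||^2)``),
        ``laplacian_kernel`` (``exp(-s ||x-y||)``) or
        ``inverse_distance`` (``1 / (1 + s ||x-y||)``), where for the three
        non-Gaussian families ``s = sigma * theta`` plays the role of an
        inverse length scale (larger ``theta`` always narrows the kernel).
    sigma:
        Base bandwidth, > 0.
    theta:
        Bandwidth divisor in ``[1, theta_max]``; ``theta = 1`` recovers the
        plain kernel.
    components:
        Optional list of :class:`KernelConfig`; when given, the Gram matrix is
        the entrywise sum of the component Grams (the Gram of the concatenated
        feature map) and the top-level family/sigma are ignored.
    """

    family: str = "gaussian"
    sigma: float = 1.0
    theta: float = 1.0
    components: tuple["KernelConfig", ...] | None = None

    def __post_init__(self) -> None:
        if self.components is not None:
            components = tuple(self.components)
            if len(components) == 0:
                raise ValueError("multi-kernel mode requires a non-empty component list")
            object.__setattr__(self, "components", components)
            return
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {_FAMILIES}")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"kernel bandwidth sigma must be positive, got {self.sigma}")
        if not np.isfinite(self.theta) or self.theta < 1:
            raise ValueError(f"bandwidth divisor theta must be >= 1, got {self.theta}")


@dataclass(frozen=True)
class GramMatrix:
    """Symmetric PSD kernel matrix over the pooled ``N = n + m`` samples."""

    values: np.ndarray
    sample_count: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("Gram matrix must be square")
        if values.shape[0] != self.sample_count:
            raise ValueError("sample_count does not match matrix order")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("Gram matrix must be symmetric to within 1e-10")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ClassMeanCoefficients:
    """Kernel-expansion coefficients of the blended domain/class means.

    ``coefficients`` has shape ``(C + 1, N)``. Row 0 expands the whole-domain
    mean ``mu = delta * mu_s + (1 - delta) * mu_t``; row ``c >= 1`` expands the
    blended mean of class ``c`` over source samples of class ``c`` (weight
    ``delta / n_c``) and target samples of class ``c`` (weight
    ``(1 - delta) / m_c``). ``active[c]`` is False when class ``c`` has no
    member on either side, in which case row ``c`` is all-zero and downstream
    distances to it are undefined.
    """

    coefficients: np.ndarray
    delta: float
    active: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        coefficients = np.asarray(self.coefficients, dtype=float)
        if coefficients.ndim != 2:
            raise ValueError("coefficients must be a (C+1, N) matrix")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")
        active = self.active
        if active is None:
            active = np.ones(coefficients.shape[0], dtype=bool)
        active = np.asarray(active, dtype=bool)
        object.__setattr__(self, "coefficients", coefficients)
        object.__setattr__(self, "active", active)

    @property
    def n_classes(self) -> int:
        return self.coefficients.shape[0] - 1


def _validate_features(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ValueError("features must be a non-empty 2-D sample-by-feature matrix")
    if not np.all(np.isfinite(features)):
        raise ValueError("features contain non-finite values")
    return features


def compute_gram(features: np.ndarray, config: KernelConfig) -> GramMatrix:
    """Evaluate the configured kernel on all sample pairs.

    In multi-kernel mode the Gram of the concatenated feature map
    ``phi~ = [phi_1; ...; phi_A]`` is returned, i.e. the entrywise sum of the
    component Gram matrices.
    """
    features = _validate_features(features)
    n = features.shape[0]
    if config.components is not None:
        total = np.zeros((n, n))
        for component in config.components:
            total += compute_gram(features, component).values
        return GramMatrix(values=_symmetrize(total), sample_count=n)

    if config.family == "gaussian":
        bandwidth = config.sigma / config.theta
        sq = euclidean_distances(features, squared=True)
        values = np.exp(-sq / (2.0 * bandwidth**2))
        np.fill_diagonal(values, 1.0)
    else:
        scale = config.sigma * config.theta
        if config.family == "inverse_square_distance":
            sq = euclidean_distances(features, squared=True)
            values = 1.0 / (1.0 + scale * sq)
        elif config.family == "laplacian_kernel":
            dist = euclidean_distances(features)
            values = np.exp(-scale * dist)
        else:  # inverse_distance
            dist = euclidean_distances(features)
            values = 1.0 / (1.0 + scale * dist)
    return GramMatrix(values=_symmetrize(values), sample_count=n)


def _symmetrize(values: np.ndarray) -> np.ndarray:
    return 0.5 * (values + values.T)


def default_bandwidth(features: np.ndarray, n_classes: int = 2) -> float:
    """Average-norm bandwidth heuristic.

    ``sigma = sqrt(mean_i ||x_i||_2)``, multiplied by the class count for
    multi-class (``C > 2``) problems.
    """
    features = _validate_features(features)
    norms = np.linalg.norm(features, axis=1)
    sigma = float(np.sqrt(np.mean(norms)))
    if n_classes > 2:
        sigma *= n_classes
    if sigma <= 0:
        raise ValueError("degenerate all-zero features: bandwidth heuristic undefined")
    return sigma


def median_pairwise_bandwidth(features: np.ndarray) -> float:
    """Median pairwise Euclidean distance, the usual alternative heuristic."""
    features = _validate_features(features)
    dist = euclidean_distances(features)
    upper = dist[np.triu_indices_from(dist, k=1)]
    positive = upper[upper > 0]
    if positive.size == 0:
        raise ValueError("all samples coincide: median-distance heuristic undefined")
    return float(np.median(positive))


def class_mean_coefficients(
    source_labels: np.ndarray,
    target_labels: np.ndarray,
    delta: float,
    n_classes: int | None = None,
) -> ClassMeanCoefficients:
    """Coefficient vectors of the blended domain and class means.

    Labels are 1-based class codes over the pooled ordering
    ``[source; target]``. Row 0 blends the two full-domain means with weight
    ``delta`` on the source; row ``c`` blends the per-class means with the
    same weight. When one side's class subset is empty the populated side
    receives full weight; classes empty on both sides are flagged inactive.
    """
    source_labels = np.asarray(source_labels, dtype=int)
    target_labels = np.asarray(target_labels, dtype=int)
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    n, m = source_labels.size, target_labels.size
    if n == 0 or m == 0:
        raise ValueError("both domains must be non-empty")
    if n_classes is None:
        n_classes = int(max(source_labels.max(), target_labels.max()))
    if n_classes < 1:
        raise ValueError("at least one class is required")
    for name, labels in (("source", source_labels), ("target", target_labels)):
        if labels.min() < 1 or labels.max() > n_classes:
            raise ValueError(f"{name} labels must lie in 1..{n_classes}")

    N = n + m
    coefficients = np.zeros((n_classes + 1, N))
    active = np.ones(n_classes + 1, dtype=bool)
    coefficients[0, :n] = delta / n
    coefficients[0, n:] = (1.0 - delta) / m
    for c in range(1, n_classes + 1):
        src = np.flatnonzero(source_labels == c)
        tgt = n + np.flatnonzero(target_labels == c)
        if src.size == 0 and tgt.size == 0:
            active[c] = False
            continue
        if src.size == 0:
            coefficients[c, tgt] = 1.0 / tgt.size
        elif tgt.size == 0:
            coefficients[c, src] = 1.0 / src.size
        else:
            coefficients[c, src] = delta / src.size
            coefficients[c, tgt] = (1.0 - delta) / tgt.size
    return ClassMeanCoefficients(coefficients=coefficients, delta=delta, active=active)


def rkhs_mean_distances(gram: GramMatrix, means: ClassMeanCoefficients) -> np.ndarray:
    """Squared RKHS distance of every sample to every blended mean.

    ``D[k, c] = K_kk - 2 (K a_c)_k + a_c^T K a_c``, clamped at zero after
    round-off. Columns of inactive classes are filled with ``inf`` so that
    exponential downweighting sends their memberships to zero and they drop
    out of all downstream sums.
    """
    K = gram.values
    A = means.coefficients
    if A.shape[1] != gram.sample_count:
        raise ValueError("Gram matrix and mean coefficients cover different sample sets")
    cross = K @ A.T  # (N, C+1)
    quad = np.einsum("ci,ij,cj->c", A, K, A)
    distances = np.diag(K)[:, None] - 2.0 * cross + quad[None, :]
    if distances.min() < _NEGATIVE_TOL:
        raise FloatingPointError(
            f"negative squared RKHS distance {distances.min():.3e} exceeds round-off tolerance"
        )
    distances = np.clip(distances, 0.0, None)
    distances[:, ~means.active] = INACTIVE_SENTINEL
    return distances
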