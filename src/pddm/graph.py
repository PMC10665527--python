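"""k-NN affinity graph, graph Laplacian and the spectral label update.

Label propagation penalizes label disagreement across graph edges through
``tr(Y^T L Y)`` with ``L = D - M`` the combinatorial Laplacian of a
symmetrized k-nearest-neighbour Gaussian affinity graph.  The joint label
update reduces to a trace minimization ``min_{Y^T Y = I} tr(Y^T H Y)`` whose
relaxed solution is the eigenvectors of the ``C`` smallest eigenvalues of
``H``; target rows are then rounded to one-hot labels after a Procrustes
rotation that aligns the relaxed basis with the fixed source labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "AffinityGraph",
    "LabelMatrix",
    "build_affinity",
    "label_propagation_loss",
    "update_labels",
    "one_hot",
]

#: k-neighbour grid searched in practice
K_NEIGHBOR_GRID = (3, 5, 10, 15, 17)


@dataclass(frozen=True)
class AffinityGraph:
    """Symmetrized k-NN Gaussian affinity with degree and Laplacian."""

    affinity: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray
    n_neighbors: int
    sigma_graph: float

    @property
    def n_samples(self) -> int:
        return self.affinity.shape[0]

    def edge_list(self) -> np.ndarray:
        """Edges as (i, j, weight) rows with i < j, for text export."""
        i, j = np.nonzero(np.triu(self.affinity, k=1))
        return np.column_stack([i, j, self.affinity[i, j]])


@dataclass(frozen=True)
class LabelMatrix:
    """Joint label matrix ``Y = [Y_s; Y_t]`` in relaxed and discrete form.

    ``relaxed`` is the orthonormal trace minimizer (``Y^T Y = I``) after
    Procrustes alignment to the source block; ``values`` is the discretized
    one-hot matrix with source rows restored to their fixed labels;
    ``labels`` are the corresponding 1-based class codes.
    """

    values: np.ndarray
    relaxed: np.ndarray
    labels: np.ndarray
    source_mask: np.ndarray
    trace_value: float


def build_affinity(features: np.ndarray, k: int, sigma_graph: float | None = None) -> AffinityGraph:
    """Symmetrized k-NN Gaussian affinity graph.

    ``M_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`` whenever ``x_i`` is among
    the ``k`` nearest neighbours of ``x_j`` or vice versa, zero otherwise
    (zero diagonal). ``sigma_graph`` defaults to the median of the included
    neighbour distances.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be 2-D")
    n = features.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < N = {n}, got {k}")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(features)
    neighbor_dist, neighbor_idx = nn.kneighbors(features)
    # drop self-edges; with duplicates the self column need not be column 0
    mask = np.ones((n, k + 1), dtype=bool)
    rows = np.arange(n)
    self_col = np.argmax(neighbor_idx == rows[:, None], axis=1)
    mask[rows, self_col] = False

    adjacency = np.zeros((n, n), dtype=bool)
    adjacency[np.repeat(rows, k), neighbor_idx[mask]] = True
    np.fill_diagonal(adjacency, False)
    adjacency |= adjacency.T

    if sigma_graph is None:
        included = neighbor_dist[mask]
        positive = included[included > 0]
        sigma_graph = float(np.median(positive)) if positive.size else 1.0
    if sigma_graph <= 0:
        raise ValueError(f"graph bandwidth must be positive, got {sigma_graph}")

    sq = euclidean_distances(features, squared=True)
    affinity = np.where(adjacency, np.exp(-sq / (2.0 * sigma_graph**2)), 0.0)
    affinity = 0.5 * (affinity + affinity.T)
    degree = affinity.sum(axis=1)
    laplacian = np.diag(degree) - affinity
    return AffinityGraph(
        affinity=affinity,
        degree=degree,
        laplacian=laplacian,
        n_neighbors=k,
        sigma_graph=sigma_graph,
    )


def label_propagation_loss(graph: AffinityGraph, labels: np.ndarray) -> float:
    """Smoothness penalty ``tr(Y^T L Y) = 1/2 sum_ij M_ij ||y_i - y_j||^2``."""
    Y = np.asarray(labels, dtype=float)
    if Y.shape[0] != graph.n_samples:
        raise ValueError("label matrix and graph cover different sample sets")
    return float(np.trace(Y.T @ graph.laplacian @ Y))


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """1-based integer labels to an ``(N, C)`` one-hot matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > n_classes:
        raise ValueError(f"labels must lie in 1..{n_classes}")
    Y = np.zeros((labels.size, n_classes))
    Y[np.arange(labels.size), labels - 1] = 1.0
    return Y


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: largest-magnitude entry positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def update_labels(
    H: np.ndarray,
    n_classes: int,
    source_labels: np.ndarray,
    source_mask: np.ndarray,
) -> LabelMatrix:
    """Orthogonality-constrained label update ``min_{Y^T Y = I} tr(Y^T H Y)``.

    The relaxed solution spans the eigenvectors of the ``n_classes`` smallest
    eigenvalues of the symmetrized ``H``.  Because any rotation ``Y R`` is
    equally optimal, the basis is aligned to the known one-hot source block by
    the orthogonal Procrustes rotation minimizing
    ``||Y[source] R - Y_s||_F``; target rows are then discretized by row-wise
    argmax (ties toward the lowest class index) and source rows restored.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("H must be square")
    H = 0.5 * (H + H.T)
    N = H.shape[0]
    if n_classes < 1 or n_classes > N:
        raise ValueError("class count must lie in 1..N")
    source_mask = np.asarray(source_mask, dtype=bool)
    if source_mask.shape != (N,):
        raise ValueError("source_mask must be length N")

    try:
        eigenvalues, eigenvectors = scipy.linalg.eigh(
            H, subset_by_index=(0, n_classes - 1)
        )
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        cond = np.linalg.cond(H)
        raise FloatingPointError(
            f"eigen-decomposition of H failed (condition number {cond:.3e})"
        ) from exc
    relaxed = _fix_signs(eigenvectors)
    trace_value = float(eigenvalues.sum())

    Y_source = one_hot(source_labels, n_classes)
    rotation, _ = scipy.linalg.orthogonal_procrustes(relaxed[source_mask], Y_source)
    aligned = relaxed @ rotation

    # row-wise argmax rounds toward the lowest index on exact ties
    labels = np.argmax(aligned, axis=1) + 1
    labels[source_mask] = np.asarray(source_labels, dtype=int)
    values = one_hot(labels, n_classes)
    return LabelMatrix(
        values=values,
        relaxed=aligned,
        labels=labels,
        source_mask=source_mask,
        trace_value=trace_value,
    )
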