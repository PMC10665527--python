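"""Membership-weighted, row-sparse (l2,1) least-squares classifier.

The structural-risk term of the joint objective is a weighted least-squares
loss ``sum_k w_k ||x~_k^T W - y_k||^2`` plus the row-sparsity penalty
``rho ||W||_{2,1} = rho sum_i ||w^i||`` (bias handled by augmenting features
with a constant-1 column).  The minimizer is found by iteratively reweighted
least squares (IRLS): alternate the closed form
``W = (X~^T Omega X~ + rho U)^{-1} X~^T Omega Y`` with the refresh
``U_ii = 1 / (2 ||w^i|| + eps)``, the standard majorize-minimize scheme whose
objective is non-increasing at every step.

The same normal-equation matrix yields the hat matrix ``P = X~ A`` mapping
targets to fitted values, from which the label-update matrix
``H = alpha L + B^T Omega B`` with ``B = P - I`` is assembled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.kernel_approximation import RBFSampler

from .graph import AffinityGraph

__all__ = [
    "LinearClassifier",
    "fit_weighted_l21",
    "residuals",
    "hat_operator",
    "assemble_H",
    "augment",
    "l21_norm",
    "make_feature_map",
]

#: floor added to row norms when refreshing the IRLS diagonal; kept tiny so
#: the majorize-minimize descent argument holds to well below trace tolerances
EPS_REG = 1e-12


@dataclass
class LinearClassifier:
    """Bias-augmented linear decision function ``F(x) = x~^T W``.

    ``weights`` is ``(d + 1, C)`` with the bias row last. ``irls_objectives``
    traces the IRLS objective (asserted non-increasing); ``reweight_diagonal``
    is the converged IRLS diagonal ``U_ii = 1/(2||w^i|| + eps)`` reused when
    assembling the label-update matrix.
    """

    weights: np.ndarray
    feature_map: str = "identity"
    irls_objectives: list[float] = field(default_factory=list)
    reweight_diagonal: np.ndarray | None = None

    def decision_function(self, features_aug: np.ndarray) -> np.ndarray:
        return np.asarray(features_aug, dtype=float) @ self.weights

    def predict(self, features_aug: np.ndarray) -> np.ndarray:
        """1-based class codes by row-wise argmax of the decision values."""
        return np.argmax(self.decision_function(features_aug), axis=1) + 1


def augment(features: np.ndarray) -> np.ndarray:
    """Append the constant-1 bias column."""
    features = np.asarray(features, dtype=float)
    return np.hstack([features, np.ones((features.shape[0], 1))])


def l21_norm(W: np.ndarray) -> float:
    """Sum of Euclidean row norms."""
    return float(np.linalg.norm(W, axis=1).sum())


def make_feature_map(
    kind: str = "identity",
    sigma: float = 1.0,
    dimension: int = 300,
    seed: int | None = None,
):
    """Explicit feature map used by the classifier.

    ``identity`` returns features unchanged (linear classifier, the reference
    realization); ``random_fourier`` draws a seeded random-Fourier
    approximation of the Gaussian kernel of bandwidth ``sigma`` so that the
    l2,1 penalty stays well-defined on explicit feature rows.
    """
    if kind == "identity":
        return lambda X: np.asarray(X, dtype=float)
    if kind == "random_fourier":
        sampler = RBFSampler(
            gamma=1.0 / (2.0 * sigma**2), n_components=dimension, random_state=seed
        )
        fitted: dict[str, RBFSampler] = {}

        def transform(X: np.ndarray) -> np.ndarray:
            X = np.asarray(X, dtype=float)
            if "sampler" not in fitted:
                fitted["sampler"] = sampler.fit(X)
            return fitted["sampler"].transform(X)

        return transform
    raise ValueError(f"unknown feature map {kind!r}")


def _irls_objective(X: np.ndarray, Y: np.ndarray, w: np.ndarray, rho: float, W: np.ndarray) -> float:
    resid = X @ W - Y
    return float(w @ np.einsum("ij,ij->i", resid, resid)) + rho * l21_norm(W)


def fit_weighted_l21(
    features_aug: np.ndarray,
    targets: np.ndarray,
    sample_weights: np.ndarray,
    rho: float,
    max_irls: int = 100,
    tol: float = 1e-10,
    initial_weights: np.ndarray | None = None,
) -> LinearClassifier:
    """Minimize ``sum_k w_k ||x~_k^T W - y_k||^2 + rho ||W||_{2,1}``.

    Alternates the closed-form solve with the diagonal refresh until the
    relative objective change drops below ``tol``.  With ``rho = 0`` and a
    singular normal matrix the pseudo-inverse solution is returned with a
    warning.  ``initial_weights`` warm-starts the majorize-minimize loop,
    which guarantees the final objective does not exceed the objective at the
    starting point.
    """
    X = np.asarray(features_aug, dtype=float)
    Y = np.asarray(targets, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("targets must be (N, C) matching the feature rows")
    w = np.asarray(sample_weights, dtype=float)
    if w.shape != (X.shape[0],) or np.any(w < 0):
        raise ValueError("sample_weights must be a length-N non-negative vector")
    if not np.any(w > 0):
        raise ValueError("at least one sample weight must be positive")
    if rho < 0:
        raise ValueError(f"rho must be non-negative, got {rho}")

    XtW = X.T * w  # (d+1, N)
    G = XtW @ X
    R = XtW @ Y

    if rho == 0.0:
        try:
            W = scipy.linalg.solve(G, R, assume_a="pos")
        except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
            warnings.warn(
                "singular normal matrix with rho = 0; falling back to the "
                "pseudo-inverse (minimum-norm) solution",
                RuntimeWarning,
            )
            W = np.linalg.pinv(G) @ R
        obj = _irls_objective(X, Y, w, rho, W)
        return LinearClassifier(
            weights=W,
            irls_objectives=[obj],
            reweight_diagonal=np.full(X.shape[1], 1.0 / EPS_REG),
        )

    if initial_weights is not None:
        W = np.asarray(initial_weights, dtype=float).copy()
    else:
        W = scipy.linalg.lstsq(G + rho * np.eye(G.shape[0]), R)[0]
    objectives = [_irls_objective(X, Y, w, rho, W)]
    U = None
    for _ in range(max_irls):
        row_norms = np.linalg.norm(W, axis=1)
        U = 1.0 / (2.0 * row_norms + EPS_REG)
        W = scipy.linalg.solve(G + rho * np.diag(U), R, assume_a="pos")
        objectives.append(_irls_objective(X, Y, w, rho, W))
        if abs(objectives[-2] - objectives[-1]) <= tol * max(1.0, abs(objectives[-2])):
            break
    # refresh once more so the stored diagonal is the fixed point of W
    row_norms = np.linalg.norm(W, axis=1)
    U = 1.0 / (2.0 * row_norms + EPS_REG)
    return LinearClassifier(weights=W, irls_objectives=objectives, reweight_diagonal=U)


def residuals(
    classifier: LinearClassifier, features_aug: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Per-sample squared residuals ``e_k = ||x~_k^T W - y_k||^2``."""
    diff = classifier.decision_function(features_aug) - np.asarray(targets, dtype=float)
    return np.einsum("ij,ij->i", diff, diff)


def hat_operator(
    features_aug: np.ndarray,
    sample_weights: np.ndarray,
    rho: float,
    reweight_diagonal: np.ndarray | None = None,
) -> np.ndarray:
    """Linear map ``A = (X~^T Omega X~ + rho U)^{-1} X~^T Omega``.

    ``A`` turns a target matrix ``Y`` into the closed-form classifier
    ``W = A Y`` of the weighted l2,1 problem linearized at the diagonal
    ``U``; ``X~ A`` is the corresponding hat matrix.
    """
    X = np.asarray(features_aug, dtype=float)
    w = np.asarray(sample_weights, dtype=float)
    if reweight_diagonal is None:
        reweight_diagonal = np.ones(X.shape[1])
    U = np.asarray(reweight_diagonal, dtype=float)
    XtW = X.T * w
    G = XtW @ X + rho * np.diag(U)
    try:
        return scipy.linalg.solve(G, XtW, assume_a="pos")
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        return np.linalg.pinv(G) @ XtW


def assemble_H(
    graph: AffinityGraph,
    features_aug: np.ndarray,
    sample_weights: np.ndarray,
    alpha: float,
    rho: float,
    reweight_diagonal: np.ndarray | None = None,
    include_penalty: bool = False,
) -> np.ndarray:
    """Matrix of the spectral label update ``min_{Y^T Y = I} tr(Y^T H Y)``.

    With the hat matrix ``P = X~ A``, ``A = (X~^T Omega X~ + rho U)^{-1}
    X~^T Omega`` and ``B = P - I``, returns ``H = alpha L + B^T Omega B``
    symmetrized.  ``include_penalty`` adds the majorized row-sparsity term
    ``rho A^T U A`` so the trace equals the full weighted risk of the
    substituted classifier ``W = A Y`` (used by the solver's descent
    accounting).
    """
    X = np.asarray(features_aug, dtype=float)
    w = np.asarray(sample_weights, dtype=float)
    if w.shape != (X.shape[0],):
        raise ValueError("sample_weights must be length N")
    U = reweight_diagonal
    A = hat_operator(X, w, rho, U)
    if U is None:
        U = np.ones(X.shape[1])
    U = np.asarray(U, dtype=float)
    P = X @ A
    B = P - np.eye(X.shape[0])
    H = alpha * graph.laplacian + (B.T * w) @ B
    if include_penalty:
        H = H + rho * (A.T * U) @ A
    return 0.5 * (H + H.T)
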