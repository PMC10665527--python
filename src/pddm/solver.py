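"""The C-PDDM domain-adaptation classifier (alternating optimization).

``CPDDMClassifier`` couples three ingredients in one objective:

* the fuzzy-entropy-regularized possibilistic distance of every sample to
  the blended domain and class mean embeddings (robust distribution
  alignment),
* a graph-Laplacian label-propagation penalty over the pooled samples
  (geometric consistency), and
* a membership-weighted least-squares classifier with an l2,1 row-sparsity
  penalty (structural risk).

The three blocks — memberships ``lambda``, classifier ``W`` and the
orthonormal label matrix ``Y`` — each admit a closed-form update
(exponential memberships, IRLS normal equations, smallest eigenvectors),
alternated until the objective change drops below ``epsilon_stop``.  Target
predictions come from fusing a source-refit and a target-refit classifier
with weight ``upsilon`` on the source.

The estimator follows the scikit-learn semi-supervised convention: ``fit``
takes the pooled sample matrix with ``y = -1`` marking the unlabeled target
rows (the transductive pseudo-labels are exposed as ``transduction_``), and
``predict`` scores arbitrary new samples with the fused classifier.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, confusion_matrix
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted, validate_data

from . import classifier as clf_mod
from . import graph as graph_mod
from . import kernels as kernel_mod
from . import metric as metric_mod

__all__ = ["CPDDMClassifier", "fit_cpddm", "evaluate", "mean_alignment_baseline"]


def evaluate(predicted: np.ndarray, truth: np.ndarray, n_classes: int | None = None):
    """Accuracy and per-class confusion matrix (rows = true, cols = predicted)."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predicted.shape != truth.shape:
        raise ValueError("prediction and truth lengths differ")
    if n_classes is None:
        n_classes = int(max(predicted.max(), truth.max()))
    for name, vec in (("predicted", predicted), ("truth", truth)):
        if vec.min() < 1 or vec.max() > n_classes:
            raise ValueError(f"{name} labels must lie in 1..{n_classes}")
    labels = np.arange(1, n_classes + 1)
    return (
        float(accuracy_score(truth, predicted)),
        confusion_matrix(truth, predicted, labels=labels),
    )


class CPDDMClassifier(ClassifierMixin, BaseEstimator):
    """Robust kernel domain adaptation via possibilistic distribution alignment.

    Parameters
    ----------
    alpha, beta, rho : float
        Balance weights of the label-propagation term, the fuzzy-entropy
        term and the l2,1 penalty (typically grid-searched over
        ``10^-6 .. 10^6``). Default 1.
    delta : float
        Source share of the blended domain/class means
        ``mu_c = delta mu_{s,c} + (1 - delta) mu_{t,c}``; 0.5 blends both
        domains equally.
    upsilon : float
        Source weight of the final classifier fusion
        ``upsilon f_s + (1 - upsilon) f_t``; 0.9 by convention.
    k_neighbors : int
        Neighbourhood size of the affinity graph (practical grid
        ``{3, 5, 10, 15, 17}``).
    kernel : str or KernelConfig
        Kernel family for the Gram matrix, or a full
        :class:`~pddm.kernels.KernelConfig` (e.g. multi-kernel).
    sigma : float or None
        Kernel bandwidth; ``None`` uses the average-norm heuristic
        (times the class count for multi-class problems).
    theta : float
        Bandwidth divisor >= 1 of the generalized Gaussian kernel.
    epsilon_stop : float
        Absolute stopping threshold on the objective change.
    max_iter : int
        Iteration cap ``Z``; 0 returns the initialization unchanged.
    refresh_pseudo_labels : bool
        Re-estimate the blended class means from the current target
        pseudo-labels every iteration (dynamic pseudo-labeling); ``False``
        freezes them at their initial values.
    feature_map : str
        ``identity`` (bias-augmented linear classifier) or
        ``random_fourier`` (seeded Gaussian-kernel approximation).
    rf_dim : int
        Dimension of the random-Fourier map.
    random_state : int, RandomState or None
        Seeds the random-Fourier draw; every other step is deterministic.

    Attributes
    ----------
    classes_ : original class labels of the labeled rows
    transduction_ : fused predictions for the unlabeled (target) rows
    memberships_ : final ``(N, C+1)`` possibilistic membership matrix
    sample_weights_ : final per-sample residual weights (membership row sums)
    objective_trace_ : joint objective at the discretized labels, per iteration
    relaxed_block_trace_ : per-iteration dicts of the relaxed objective after
        each block update (``start >= lambda >= W >= Y`` within round-off)
    n_iter_, converged_ : iterations run and stopping-rule flag
    """

    def __init__(
        self,
        alpha: float = 1.0,
        beta: float = 1.0,
        rho: float = 1.0,
        delta: float = 0.5,
        upsilon: float = 0.9,
        k_neighbors: int = 5,
        kernel: str | kernel_mod.KernelConfig = "gaussian",
        sigma: float | None = None,
        theta: float = 1.0,
        epsilon_stop: float = 1e-5,
        max_iter: int = 50,
        refresh_pseudo_labels: bool = True,
        feature_map: str = "identity",
        rf_dim: int = 300,
        random_state=None,
    ):
        self.alpha = alpha
        self.beta = beta
        self.rho = rho
        self.delta = delta
        self.upsilon = upsilon
        self.k_neighbors = k_neighbors
        self.kernel = kernel
        self.sigma = sigma
        self.theta = theta
        self.epsilon_stop = epsilon_stop
        self.max_iter = max_iter
        self.refresh_pseudo_labels = refresh_pseudo_labels
        self.feature_map = feature_map
        self.rf_dim = rf_dim
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        """Run the alternating optimization on pooled source + target rows.

        ``y`` holds the source labels, with ``-1`` marking unlabeled target
        rows. Both blocks must be non-empty and every class must appear in
        the source.
        """
        X, y = validate_data(self, X, y, dtype=float)
        y = np.asarray(y)
        self._check_config()
        source_mask = y != -1
        if not source_mask.any() or source_mask.all():
            raise ValueError("need both labeled (source) and unlabeled (y = -1) rows")
        classes = np.unique(y[source_mask])
        if classes.size < 2:
            raise ValueError("the source must contain at least two classes")
        self.classes_ = classes
        C = classes.size
        y_src = np.searchsorted(classes, y[source_mask]) + 1  # 1..C internal codes

        rng = check_random_state(self.random_state)
        self._map = clf_mod.make_feature_map(
            self.feature_map,
            sigma=self._resolve_sigma(X, C),
            dimension=self.rf_dim,
            seed=rng.randint(2**31 - 1),
        )
        # reorder rows to the canonical [source; target] pooled layout
        order = np.concatenate([np.flatnonzero(source_mask), np.flatnonzero(~source_mask)])
        Xp = X[order]
        n, m = int(source_mask.sum()), int((~source_mask).sum())
        pooled_source_mask = np.zeros(n + m, dtype=bool)
        pooled_source_mask[:n] = True
        self._order = order
        self._pooled_source_mask = pooled_source_mask

        config = self._resolve_kernel(Xp, C)
        gram = kernel_mod.compute_gram(Xp, config)
        graph = graph_mod.build_affinity(Xp, self.k_neighbors)
        X_aug = clf_mod.augment(self._map(Xp))

        state = self._initialize(gram, graph, X_aug, y_src, n, m, C)
        state = self._iterate(state, gram, graph, X_aug, y_src, n, m, C)
        self._finalize(state, X_aug, y_src, n, C)
        self.kernel_config_ = config
        self.graph_ = graph
        return self

    def _check_config(self) -> None:
        for name in ("alpha", "beta", "rho"):
            if getattr(self, name) < 0 or (name == "beta" and self.beta <= 0):
                raise ValueError(f"{name} must be positive (alpha, rho non-negative)")
        for name in ("delta", "upsilon"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.epsilon_stop <= 0:
            raise ValueError("epsilon_stop must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be non-negative")

    def _resolve_sigma(self, X: np.ndarray, n_classes: int) -> float:
        if self.sigma is not None:
            return float(self.sigma)
        return kernel_mod.default_bandwidth(X, n_classes)

    def _resolve_kernel(self, X: np.ndarray, n_classes: int) -> kernel_mod.KernelConfig:
        if isinstance(self.kernel, kernel_mod.KernelConfig):
            return self.kernel
        return kernel_mod.KernelConfig(
            family=self.kernel, sigma=self._resolve_sigma(X, n_classes), theta=self.theta
        )

    # ------------------------------------------------------- internal steps

    def _distances(self, gram, y_src, pseudo, C):
        means = kernel_mod.class_mean_coefficients(y_src, pseudo, self.delta, C)
        return kernel_mod.rkhs_mean_distances(gram, means)

    def _initialize(self, gram, graph, X_aug, y_src, n, m, C):
        """Hot start: source-only classifier -> pseudo-labels -> lambda, W, Y."""
        Y_src = graph_mod.one_hot(y_src, C)
        source_clf = clf_mod.fit_weighted_l21(
            X_aug[:n], Y_src, np.ones(n), self.rho
        )
        pseudo = source_clf.predict(X_aug[n:])
        self.initial_pseudo_labels_ = pseudo.copy()

        d = self._distances(gram, y_src, pseudo, C)
        labels_all = np.concatenate([y_src, pseudo])
        Y_disc = graph_mod.one_hot(labels_all, C)
        e = clf_mod.residuals(source_clf, X_aug, Y_disc)
        lam = metric_mod.update_memberships(
            metric_mod.DistanceBundle(mean_distances=d, residuals=e), self.beta
        )
        weights = lam.squared.sum(axis=1)
        W_init = clf_mod.fit_weighted_l21(X_aug, Y_disc, weights, self.rho)
        H = clf_mod.assemble_H(
            graph, X_aug, weights, self.alpha, self.rho,
            reweight_diagonal=W_init.reweight_diagonal, include_penalty=True,
        )
        label_matrix = graph_mod.update_labels(H, C, y_src, self._pooled_source_mask)
        A = clf_mod.hat_operator(X_aug, weights, self.rho, W_init.reweight_diagonal)
        W = A @ label_matrix.relaxed  # classifier on the relaxed label scale
        state = {
            "lambda": lam,
            "W": W,
            "U": W_init.reweight_diagonal,
            "labels": label_matrix,
            "distances": d,
            "pseudo": pseudo,
        }
        theta0 = self._discrete_objective(state, graph, X_aug, y_src, C)
        self.objective_trace_ = [theta0]
        self.relaxed_block_trace_ = []
        self.history_ = []
        return state

    def _relaxed_objective(self, lam, W, Y_rel, d, graph, X_aug) -> float:
        """Joint objective on the orthonormal label matrix (the relaxed trace)."""
        data = metric_mod.pddm_objective(lam, d)
        smooth = self.alpha * graph_mod.label_propagation_loss(graph, Y_rel)
        resid = np.einsum("ij,ij->i", X_aug @ W - Y_rel, X_aug @ W - Y_rel)
        weights = lam.squared.sum(axis=1)
        return data + smooth + float(weights @ resid) + self.rho * clf_mod.l21_norm(W)

    def _discrete_objective(self, state, graph, X_aug, y_src, C) -> float:
        """Joint objective evaluated with the current discretized labels."""
        lam = state["lambda"]
        W = state["W"]
        Y_disc = state["labels"].values
        data = metric_mod.pddm_objective(lam, state["distances"])
        smooth = self.alpha * graph_mod.label_propagation_loss(graph, Y_disc)
        diff = X_aug @ W - Y_disc
        resid = np.einsum("ij,ij->i", diff, diff)
        weights = lam.squared.sum(axis=1)
        return data + smooth + float(weights @ resid) + self.rho * clf_mod.l21_norm(W)

    def _iterate(self, state, gram, graph, X_aug, y_src, n, m, C):
        self.converged_ = False
        self.n_iter_ = 0
        for _ in range(self.max_iter):
            self.n_iter_ += 1
            if self.refresh_pseudo_labels:
                state["pseudo"] = state["labels"].labels[n:]
                state["distances"] = self._distances(gram, y_src, state["pseudo"], C)
            d = state["distances"]
            lam, W, label_matrix = state["lambda"], state["W"], state["labels"]
            Y_rel = label_matrix.relaxed
            block = {"start": self._relaxed_objective(lam, W, Y_rel, d, graph, X_aug)}

            # lambda step: exact elementwise minimizer
            e = np.einsum("ij,ij->i", X_aug @ W - Y_rel, X_aug @ W - Y_rel)
            lam = metric_mod.update_memberships(
                metric_mod.DistanceBundle(mean_distances=d, residuals=e), self.beta
            )
            block["lambda"] = self._relaxed_objective(lam, W, Y_rel, d, graph, X_aug)

            # W step: warm-started IRLS (majorize-minimize descent)
            weights = lam.squared.sum(axis=1)
            fitted = clf_mod.fit_weighted_l21(
                X_aug, Y_rel, weights, self.rho, initial_weights=W
            )
            W, U = fitted.weights, fitted.reweight_diagonal
            block["W"] = self._relaxed_objective(lam, W, Y_rel, d, graph, X_aug)

            # Y step: spectral update with the l2,1 majorizer folded into H
            H = clf_mod.assemble_H(
                graph, X_aug, weights, self.alpha, self.rho,
                reweight_diagonal=U, include_penalty=True,
            )
            label_matrix = graph_mod.update_labels(H, C, y_src, self._pooled_source_mask)
            A = clf_mod.hat_operator(X_aug, weights, self.rho, U)
            W = A @ label_matrix.relaxed
            block["Y"] = self._relaxed_objective(
                lam, W, label_matrix.relaxed, d, graph, X_aug
            )
            self.relaxed_block_trace_.append(block)

            labels_changed = int(np.sum(label_matrix.labels != state["labels"].labels))
            state.update({"lambda": lam, "W": W, "U": U, "labels": label_matrix})
            theta = self._discrete_objective(state, graph, X_aug, y_src, C)
            if not np.isfinite(theta):
                raise FloatingPointError(
                    f"non-finite objective at iteration {self.n_iter_}"
                )
            self.objective_trace_.append(theta)
            quantiles = np.quantile(lam.squared.sum(axis=1), [0.1, 0.5, 0.9])
            self.history_.append(
                {
                    "iter": self.n_iter_,
                    "theta_relaxed": block["Y"],
                    "theta_discrete": theta,
                    "labels_changed": labels_changed,
                    "lambda_q10": quantiles[0],
                    "lambda_q50": quantiles[1],
                    "lambda_q90": quantiles[2],
                }
            )
            if abs(self.objective_trace_[-1] - self.objective_trace_[-2]) < self.epsilon_stop:
                self.converged_ = True
                break
        return state

    def _finalize(self, state, X_aug, y_src, n, C):
        lam = state["lambda"]
        weights = lam.squared.sum(axis=1)
        pseudo = state["labels"].labels[n:]

        self.memberships_ = lam.values
        self.sample_weights_ = weights
        self.label_matrix_ = state["labels"]
        self.pseudo_labels_ = pseudo

        # fusion classifiers: source refit on true labels, target on inferred
        # ones, both carrying the learned robustness weights
        self.source_classifier_ = clf_mod.fit_weighted_l21(
            X_aug[:n], graph_mod.one_hot(y_src, C), weights[:n], self.rho
        )
        self.target_classifier_ = clf_mod.fit_weighted_l21(
            X_aug[n:], graph_mod.one_hot(pseudo, C), weights[n:], self.rho
        )
        fused = self._fuse(X_aug[n:])
        inverse = np.empty_like(self._order)
        inverse[self._order] = np.arange(self._order.size)
        pooled = np.concatenate([self.classes_[y_src - 1], self.classes_[fused - 1]])
        self.transduction_ = pooled[inverse]

    def _fuse(self, X_aug: np.ndarray) -> np.ndarray:
        scores = self.decision_function_aug(X_aug)
        return np.argmax(scores, axis=1) + 1

    def decision_function_aug(self, X_aug: np.ndarray) -> np.ndarray:
        """Fused scores ``upsilon f_s + (1 - upsilon) f_t`` on augmented rows."""
        return self.upsilon * self.source_classifier_.decision_function(
            X_aug
        ) + (1.0 - self.upsilon) * self.target_classifier_.decision_function(X_aug)

    # -------------------------------------------------------------- predict

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False, dtype=float)
        return self.decision_function_aug(clf_mod.augment(self._map(X)))

    def predict(self, X) -> np.ndarray:
        """Fused class predictions for arbitrary samples."""
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def score_target(self, truth: np.ndarray) -> float:
        """Transductive accuracy of the unlabeled rows against held-out truth."""
        check_is_fitted(self)
        truth = np.asarray(truth)
        target_rows = np.ones(self.transduction_.size, dtype=bool)
        target_rows[self._order[: self._pooled_source_mask.sum()]] = False
        return float(np.mean(self.transduction_[target_rows] == truth))


def fit_cpddm(
    source_features: np.ndarray,
    source_labels: np.ndarray,
    target_features: np.ndarray,
    **params,
) -> CPDDMClassifier:
    """Fit :class:`CPDDMClassifier` from separate source and target tables."""
    source_features = np.asarray(source_features, dtype=float)
    target_features = np.asarray(target_features, dtype=float)
    X = np.vstack([source_features, target_features])
    y = np.concatenate(
        [np.asarray(source_labels, dtype=int), np.full(target_features.shape[0], -1)]
    )
    return CPDDMClassifier(**params).fit(X, y)


def mean_alignment_baseline(
    source_features: np.ndarray,
    source_labels: np.ndarray,
    target_features: np.ndarray,
    rho: float = 1.0,
) -> np.ndarray:
    """Plain mean-alignment baseline: translate the target by the gap of the
    empirical domain means, then predict with a source-only classifier.

    This is the non-possibilistic reference whose mean estimate outliers can
    drag arbitrarily far.
    """
    source_features = np.asarray(source_features, dtype=float)
    target_features = np.asarray(target_features, dtype=float)
    source_labels = np.asarray(source_labels, dtype=int)
    C = int(source_labels.max())
    shift = source_features.mean(axis=0) - target_features.mean(axis=0)
    X_aug = clf_mod.augment(source_features)
    fitted = clf_mod.fit_weighted_l21(
        X_aug, graph_mod.one_hot(source_labels, C), np.ones(source_features.shape[0]), rho
    )
    return fitted.predict(clf_mod.augment(target_features + shift))
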