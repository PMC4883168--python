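"""Detection models: logistic model trees, ridge multinomial logit, SVM.

The logistic model tree (LMT) combines tree induction with additive
logistic regression: every node carries a committee of one-feature linear
functions accumulated by LogitBoost, children are warm-started from their
parent's committee, nodes split on an information-gain criterion while at
least ``min_split`` training instances remain, and the grown tree is cut
back by cost-complexity pruning with internal cross-validation.  Because
the base learners are linear, a node's committee collapses to a single
linear model per class, stored here as a (J × p+1) coefficient matrix.

Ridge multinomial logistic regression (MLR) maximises the multinomial
log-likelihood minus an L2 penalty on the non-intercept coefficients by
damped Newton iterations; the penalty keeps estimates finite and unique
even on separable data.

The SVM is deliberately an adapter over scikit-learn's libsvm wrapper
(RBF kernel, C=1, γ=1/p, one-against-one decomposition, Platt probability
outputs) rather than a re-implementation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .eeg_io import CLASS_ORDER
from .exceptions import CapabilityError, ConvergenceError, ValidationError

_Z_MAX = 3.0  # working-response clip in LogitBoost
_W_MIN = 1e-10


# ---------------------------------------------------------------------------
# shared utilities
# ---------------------------------------------------------------------------

def ordered_classes(y) -> np.ndarray:
    """Unique labels in canonical order (healthy < seizure-free < seizure,
    other labels after, sorted by string form)."""
    uniq = set(np.asarray(y).tolist())

    def key(label):
        return (
            CLASS_ORDER.index(label) if label in CLASS_ORDER else len(CLASS_ORDER),
            str(label),
        )

    return np.asarray(sorted(uniq, key=key))


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D array of shape (n_instances, n_features)")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    return X


def _check_columns(model, X: np.ndarray) -> None:
    if X.shape[1] != model.n_features_:
        raise ValidationError(
            f"expected {model.n_features_} feature columns, got {X.shape[1]}"
        )


def _softmax(F: np.ndarray) -> np.ndarray:
    F = F - F.max(axis=1, keepdims=True)
    P = np.exp(F)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _stratified_fold_indices(
    y_idx: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal each class's shuffled indices round-robin into k folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in np.unique(y_idx):
        members = np.flatnonzero(y_idx == c)
        members = members[rng.permutation(members.size)]
        for pos, idx in enumerate(members):
            folds[pos % k].append(int(idx))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class ClassifierSpec:
    """Named classifier plus hyperparameters (defaults mirror common toolkit
    defaults; see each fit function)."""

    name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in {"LMT", "MLR", "SVM"}:
            raise ValidationError(f"unknown classifier name {self.name!r}")


# ---------------------------------------------------------------------------
# LogitBoost with one-feature linear base learners
# ---------------------------------------------------------------------------

class _Boost:
    """Mutable LogitBoost state for a J-class additive linear model.

    ``coef`` is (J, p+1) with the intercept first; F = [1 X] @ coef.T is
    maintained incrementally.  An optional validation matrix is tracked so
    cross-validation can read the per-iteration error.
    """

    def __init__(self, X, Y, coef=None, X_val=None):
        self.X = X
        self.Y = Y
        n, p = X.shape
        self.J = Y.shape[1]
        self.coef = (
            np.zeros((self.J, p + 1)) if coef is None else np.array(coef, dtype=float)
        )
        self.F = X @ self.coef[:, 1:].T + self.coef[:, 0]
        self.X_val = X_val
        self.F_val = (
            None
            if X_val is None
            else X_val @ self.coef[:, 1:].T + self.coef[:, 0]
        )

    def iterate(self) -> None:
        X, Y, J = self.X, self.Y, self.J
        P = _softmax(self.F)
        G = np.zeros_like(self.coef)  # raw per-class simple-regression fits
        for j in range(J):
            pj = P[:, j]
            w = np.maximum(pj * (1.0 - pj), _W_MIN)
            z = np.clip((Y[:, j] - pj) / w, -_Z_MAX, _Z_MAX)
            sw = w.sum()
            xbar = (w @ X) / sw
            zbar = (w @ z) / sw
            sxz = (w * z) @ X - sw * xbar * zbar
            sxx = w @ (X**2) - sw * xbar**2
            szz = w @ (z**2) - sw * zbar**2
            with np.errstate(divide="ignore", invalid="ignore"):
                slope = np.where(sxx > 1e-12, sxz / sxx, 0.0)
            sse = szz - slope * sxz
            f_star = int(np.argmin(sse))
            a = float(slope[f_star])
            b = float(zbar - a * xbar[f_star])
            G[j, 0] = b
            G[j, 1 + f_star] = a
        update = (J - 1) / J * (G - G.mean(axis=0, keepdims=True))
        self.coef += update
        self.F += X @ update[:, 1:].T + update[:, 0]
        if self.X_val is not None:
            self.F_val += self.X_val @ update[:, 1:].T + update[:, 0]

    def val_errors(self, y_val_idx: np.ndarray) -> int:
        return int(np.sum(np.argmax(self.F_val, axis=1) != y_val_idx))


def _boost_iterations_cv(
    X: np.ndarray,
    Y: np.ndarray,
    y_idx: np.ndarray,
    max_iters: int,
    rng: np.random.Generator,
    n_folds: int = 5,
) -> int:
    """Pick the LogitBoost iteration count by stratified CV (first argmin)."""
    min_class = int(np.min(np.bincount(y_idx)))
    n_folds = min(n_folds, min_class)
    if n_folds < 2:
        return min(30, max_iters)  # too little data to cross-validate
    folds = _stratified_fold_indices(y_idx, n_folds, rng)
    errs = np.zeros(max_iters)
    for val_idx in folds:
        mask = np.ones(len(y_idx), dtype=bool)
        mask[val_idx] = False
        boost = _Boost(X[mask], Y[mask], X_val=X[val_idx])
        for it in range(max_iters):
            boost.iterate()
            errs[it] += boost.val_errors(y_idx[val_idx])
    return int(np.argmin(errs)) + 1


# ---------------------------------------------------------------------------
# logistic model tree
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = (
        "coef",
        "feature",
        "threshold",
        "left",
        "right",
        "n",
        "error",
        "depth",
    )

    def __init__(self):
        self.coef = None
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None
        self.n = 0
        self.error = 0  # node-model misclassifications on its training slice
        self.depth = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def copy(self) -> "_Node":
        out = _Node()
        out.coef = self.coef
        out.feature = self.feature
        out.threshold = self.threshold
        out.n = self.n
        out.error = self.error
        out.depth = self.depth
        if self.left is not None:
            out.left = self.left.copy()
            out.right = self.right.copy()
        return out


def _entropy(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) along the last axis of count vectors."""
    totals = counts.sum(axis=-1, keepdims=True)
    frac = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
    logs = np.log2(np.where(frac > 0, frac, 1.0))
    return -(frac * logs).sum(axis=-1)


def _best_split(
    X: np.ndarray, y_idx: np.ndarray, J: int, min_leaf: int
) -> tuple[float, int | None, float | None]:
    """Best (gain, feature, threshold) over midpoint thresholds of every feature."""
    n, p = X.shape
    onehot = np.eye(J)[y_idx]
    parent_h = float(_entropy(onehot.sum(axis=0)))
    best_gain, best_feat, best_thr = 0.0, None, None
    for f in range(p):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        cum = np.cumsum(onehot[order], axis=0)
        total = cum[-1]
        i = np.arange(1, n)  # split after position i-1: left size i
        valid = (xs[1:] > xs[:-1]) & (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        left = cum[:-1][valid]
        sizes_l = i[valid]
        right = total - left
        h_l = _entropy(left)
        h_r = _entropy(right)
        gain = parent_h - (sizes_l / n) * h_l - ((n - sizes_l) / n) * h_r
        k = int(np.argmax(gain))
        if gain[k] > best_gain + 1e-12:
            best_gain = float(gain[k])
            best_feat = f
            pos = np.flatnonzero(valid)[k]
            best_thr = float((xs[pos] + xs[pos + 1]) / 2.0)
    return best_gain, best_feat, best_thr


def _grow_tree(
    X: np.ndarray,
    Y: np.ndarray,
    y_idx: np.ndarray,
    parent_coef: np.ndarray | None,
    depth: int,
    n_iter: int,
    min_split: int,
    min_leaf: int,
    max_depth: int | None,
) -> _Node:
    node = _Node()
    node.n = len(y_idx)
    node.depth = depth
    boost = _Boost(X, Y, coef=parent_coef)
    for _ in range(n_iter):
        boost.iterate()
    node.coef = boost.coef
    node.error = int(np.sum(np.argmax(boost.F, axis=1) != y_idx))

    pure = np.unique(y_idx).size <= 1
    depth_ok = max_depth is None or depth < max_depth
    if pure or not depth_ok or node.n < min_split:
        return node
    gain, feat, thr = _best_split(X, y_idx, Y.shape[1], min_leaf)
    if feat is None or gain <= 1e-10:
        return node
    node.feature = feat
    node.threshold = thr
    mask = X[:, feat] <= thr
    node.left = _grow_tree(
        X[mask], Y[mask], y_idx[mask], node.coef, depth + 1, n_iter,
        min_split, min_leaf, max_depth,
    )
    node.right = _grow_tree(
        X[~mask], Y[~mask], y_idx[~mask], node.coef, depth + 1, n_iter,
        min_split, min_leaf, max_depth,
    )
    return node


def _subtree_leaves_error(node: _Node) -> tuple[int, int]:
    if node.is_leaf:
        return 1, node.error
    ll, le = _subtree_leaves_error(node.left)
    rl, re = _subtree_leaves_error(node.right)
    return ll + rl, le + re


def _collect_alphas(node: _Node, N: int, out: list[float]) -> None:
    if node.is_leaf:
        return
    leaves, err = _subtree_leaves_error(node)
    if leaves > 1:
        g = (node.error - err) / (N * (leaves - 1))
        out.append(max(g, 0.0))
    _collect_alphas(node.left, N, out)
    _collect_alphas(node.right, N, out)


def _prune_tree(node: _Node, alpha: float, N: int) -> _Node:
    """Cost-complexity pruning (bottom-up) on a copy; error rates per N."""
    out = node.copy()

    def rec(t: _Node) -> None:
        if t.is_leaf:
            return
        rec(t.left)
        rec(t.right)
        leaves, err = _subtree_leaves_error(t)
        if t.error / N <= err / N + alpha * (leaves - 1) + 1e-12:
            t.feature = None
            t.threshold = None
            t.left = None
            t.right = None

    rec(out)
    return out


def _tree_predict_F(node: _Node, X: np.ndarray) -> np.ndarray:
    """Route rows to leaves and evaluate the leaf committees."""
    n = X.shape[0]
    J = node.coef.shape[0]
    F = np.empty((n, J))

    def rec(t: _Node, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if t.is_leaf:
            F[idx] = X[idx] @ t.coef[:, 1:].T + t.coef[:, 0]
            return
        mask = X[idx, t.feature] <= t.threshold
        rec(t.left, idx[mask])
        rec(t.right, idx[~mask])

    rec(node, np.arange(n))
    return F


class LMTModel:
    """Fitted logistic model tree."""

    def __init__(self, classes, root, n_features, n_boost_iterations, pruning_alpha):
        self.classes_ = np.asarray(classes)
        self.root = root
        self.n_features_ = n_features
        self.n_boost_iterations = n_boost_iterations
        self.pruning_alpha = pruning_alpha

    def predict_proba(self, X) -> np.ndarray:
        X = _as_matrix(X)
        _check_columns(self, X)
        P = _softmax(_tree_predict_F(self.root, X))
        return P / P.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    @property
    def n_leaves(self) -> int:
        return _subtree_leaves_error(self.root)[0]


class ConstantModel:
    """Degenerate model predicting fixed class probabilities."""

    def __init__(self, classes, probs, n_features):
        self.classes_ = np.asarray(classes)
        self.probs = np.asarray(probs, dtype=float)
        self.n_features_ = n_features

    def predict_proba(self, X) -> np.ndarray:
        X = _as_matrix(X)
        _check_columns(self, X)
        return np.tile(self.probs, (X.shape[0], 1))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_lmt(X, y, spec: ClassifierSpec | None = None, seed: int = 0) -> LMTModel | ConstantModel:
    """Fit a logistic model tree.

    Hyperparameters (via ``spec.params``): ``max_boost_iterations`` (200),
    ``min_split`` (15), ``min_leaf`` (2), ``max_depth`` (None; 0 gives the
    pure boosted logistic model), ``cv_folds`` (5), ``prune`` (True),
    ``n_iterations`` (override the cross-validated count).
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    if len(y) != X.shape[0]:
        raise ValidationError("X and y length mismatch")
    params = dict(spec.params) if spec is not None else {}
    max_boost = int(params.get("max_boost_iterations", 200))
    min_split = int(params.get("min_split", 15))
    min_leaf = int(params.get("min_leaf", 2))
    max_depth = params.get("max_depth", None)
    cv_folds = int(params.get("cv_folds", 5))
    prune = bool(params.get("prune", True))

    classes = ordered_classes(y)
    if classes.size < 2:
        warnings.warn("single-class training data: returning a constant model")
        probs = np.ones(1)
        return ConstantModel(classes, probs, X.shape[1])
    y_idx = np.array([int(np.flatnonzero(classes == label)[0]) for label in y])
    J = classes.size
    Y = np.eye(J)[y_idx]
    rng = np.random.default_rng(seed)

    n_iter = params.get("n_iterations")
    if n_iter is None:
        n_iter = _boost_iterations_cv(X, Y, y_idx, max_boost, rng, cv_folds)
    n_iter = int(n_iter)

    root = _grow_tree(
        X, Y, y_idx, None, 0, n_iter, min_split, min_leaf, max_depth
    )

    alpha_star = 0.0
    if prune and not root.is_leaf:
        N = len(y_idx)
        raw: list[float] = []
        _collect_alphas(root, N, raw)
        raw = sorted(set(raw))
        candidates = [0.0]
        for a, b in zip(raw, raw[1:]):
            candidates.append(float(np.sqrt(max(a, 1e-12) * max(b, 1e-12))))
        if raw:
            candidates.append(raw[-1] * 2 + 1e-6)
        candidates.append(np.inf)
        min_class = int(np.min(np.bincount(y_idx)))
        folds_k = min(cv_folds, min_class)
        if folds_k >= 2:
            folds = _stratified_fold_indices(y_idx, folds_k, rng)
            errs = np.zeros(len(candidates))
            for val_idx in folds:
                mask = np.ones(N, dtype=bool)
                mask[val_idx] = False
                fold_tree = _grow_tree(
                    X[mask], Y[mask], y_idx[mask], None, 0, n_iter,
                    min_split, min_leaf, max_depth,
                )
                for ci, alpha in enumerate(candidates):
                    pruned = _prune_tree(fold_tree, alpha, int(mask.sum()))
                    pred = np.argmax(_tree_predict_F(pruned, X[val_idx]), axis=1)
                    errs[ci] += np.sum(pred != y_idx[val_idx])
            # ties favour the larger alpha (smaller tree)
            best = int(len(candidates) - 1 - np.argmin(errs[::-1]))
            alpha_star = candidates[best]
            root = _prune_tree(root, alpha_star, N)

    return LMTModel(classes, root, X.shape[1], n_iter, alpha_star)


def fit_simple_logistic(X, y, seed: int = 0, n_iterations: int | None = None):
    """Pure additive (boosted) logistic regression: an LMT of depth 0."""
    params = {"max_depth": 0}
    if n_iterations is not None:
        params["n_iterations"] = n_iterations
    return fit_lmt(X, y, ClassifierSpec("LMT", params), seed=seed)


# ---------------------------------------------------------------------------
# ridge multinomial logistic regression
# ---------------------------------------------------------------------------

class RidgeMLRModel:
    """Reference-class multinomial logit with L2-penalised coefficients.

    ``coef_`` is (J−1, p+1) on standardized features, intercept first; the
    last class in canonical order is the reference with logit 0.
    """

    def __init__(self, classes, coef, mean, scale, ridge, diagnostics):
        self.classes_ = np.asarray(classes)
        self.coef_ = coef
        self.mean_ = mean
        self.scale_ = scale
        self.ridge = ridge
        self.diagnostics = diagnostics
        self.n_features_ = mean.size

    def _logits(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean_) / self.scale_
        L = Z @ self.coef_[:, 1:].T + self.coef_[:, 0]
        return np.column_stack([L, np.zeros(len(Z))])

    def predict_proba(self, X) -> np.ndarray:
        X = _as_matrix(X)
        _check_columns(self, X)
        P = _softmax(self._logits(X))
        return P / P.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_ridge_mlr(
    X,
    y,
    ridge: float = 1e-8,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RidgeMLRModel:
    """Fit MLR by damped Newton iterations to gradient-norm tolerance.

    Minimises −log-likelihood + ridge·Σ coef² (intercepts unpenalised) on
    internally standardized features.  Raises :class:`ConvergenceError`
    carrying the last iterate if the cap is hit.
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    if ridge < 0:
        raise ValidationError("ridge penalty must be >= 0")
    classes = ordered_classes(y)
    J = classes.size
    if J < 2:
        raise ValidationError("need at least two classes")
    y_idx = np.array([int(np.flatnonzero(classes == label)[0]) for label in y])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    n, p = Z.shape
    Z1 = np.column_stack([np.ones(n), Z])
    Y = np.eye(J)[y_idx][:, :-1]  # reference class dropped
    D = (J - 1) * (p + 1)
    B = np.zeros((J - 1, p + 1))
    pen_mask = np.ones(p + 1)
    pen_mask[0] = 0.0

    def nll(Bm: np.ndarray) -> float:
        L = np.column_stack([Z1 @ Bm.T, np.zeros(n)])
        L -= L.max(axis=1, keepdims=True)
        logZ = np.log(np.exp(L).sum(axis=1))
        ll = L[np.arange(n), y_idx] - logZ
        return -ll.sum() + ridge * float(np.sum((Bm * pen_mask) ** 2))

    grad_norm = np.inf
    for iteration in range(max_iter):
        L = np.column_stack([Z1 @ B.T, np.zeros(n)])
        P = _softmax(L)[:, :-1]  # (n, J-1)
        G = Z1.T @ (P - Y)  # (p+1, J-1)
        G = G.T + 2.0 * ridge * B * pen_mask
        grad_norm = float(np.max(np.abs(G)))
        if grad_norm < tol:
            break
        # Hessian of the penalised NLL, blocked over class pairs
        H = np.zeros((D, D))
        for r in range(J - 1):
            for s in range(r, J - 1):
                w = P[:, r] * ((1.0 if r == s else 0.0) - P[:, s])
                block = Z1.T @ (Z1 * w[:, None])
                if r == s:
                    block = block + 2.0 * ridge * np.diag(pen_mask)
                H[
                    r * (p + 1) : (r + 1) * (p + 1), s * (p + 1) : (s + 1) * (p + 1)
                ] = block
                if r != s:
                    H[
                        s * (p + 1) : (s + 1) * (p + 1),
                        r * (p + 1) : (r + 1) * (p + 1),
                    ] = block
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(D), G.ravel())
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, G.ravel(), rcond=None)[0]
        step = step.reshape(J - 1, p + 1)
        current = nll(B)
        t = 1.0
        while t > 1e-8 and nll(B - t * step) > current + 1e-12:
            t /= 2.0
        B = B - t * step
    else:
        raise ConvergenceError(
            f"ridge MLR did not converge in {max_iter} iterations "
            f"(gradient norm {grad_norm:.3e})",
            last_iterate=B,
            diagnostics={"grad_norm": grad_norm, "iterations": max_iter},
        )

    return RidgeMLRModel(
        classes,
        B,
        mean,
        scale,
        ridge,
        {"grad_norm": grad_norm, "iterations": iteration + 1},
    )


# ---------------------------------------------------------------------------
# SVM adapter
# ---------------------------------------------------------------------------

class SVMModel:
    """Thin wrapper exposing the native predict/predict_proba contract."""

    def __init__(self, classes, svc, mean, scale):
        self.classes_ = np.asarray(classes)
        self._svc = svc
        self.mean_ = mean
        self.scale_ = scale
        self.n_features_ = mean.size

    def predict_proba(self, X) -> np.ndarray:
        X = _as_matrix(X)
        _check_columns(self, X)
        P = self._svc.predict_proba((X - self.mean_) / self.scale_)
        return P / P.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        # argmax of the probability outputs, ties to the lowest class index
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def fit_svm(X, y, spec: ClassifierSpec | None = None, seed: int = 0) -> SVMModel:
    """Fit the delegated SVM (RBF, C=1, γ=1/p, one-vs-one, probabilities)."""
    try:
        from sklearn.svm import SVC
    except ImportError as exc:  # pragma: no cover - backend always present here
        raise CapabilityError("scikit-learn SVM backend unavailable") from exc
    X = _as_matrix(X)
    y = np.asarray(y)
    params = dict(spec.params) if spec is not None else {}
    classes = ordered_classes(y)
    y_idx = np.array([int(np.flatnonzero(classes == label)[0]) for label in y])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    with warnings.catch_warnings():
        # libsvm's built-in Platt scaling is the intended probability path
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        svc = SVC(
            C=float(params.get("C", 1.0)),
            kernel=params.get("kernel", "rbf"),
            gamma=params.get("gamma", 1.0 / X.shape[1]),
            probability=True,
            random_state=int(seed) % 2**31,
        )
        svc.fit((X - mean) / scale, y_idx)
    return SVMModel(classes, svc, mean, scale)


# ---------------------------------------------------------------------------
# dispatch and shared prediction surface
# ---------------------------------------------------------------------------

def fit_model(spec: ClassifierSpec, X, y, seed: int = 0):
    """Fit the classifier named by the spec; deterministic given seed."""
    if spec.name == "LMT":
        return fit_lmt(X, y, spec, seed=seed)
    if spec.name == "MLR":
        return fit_ridge_mlr(
            X,
            y,
            ridge=float(spec.params.get("ridge", 1e-8)),
            tol=float(spec.params.get("tol", 1e-8)),
            max_iter=int(spec.params.get("max_iter", 200)),
        )
    return fit_svm(X, y, spec, seed=seed)


def predict_proba(model, X) -> np.ndarray:
    """Per-instance class-probability vectors (rows sum to 1 within 1e−9)."""
    return model.predict_proba(X)


def predict(model, X) -> np.ndarray:
    """Class labels by probability argmax, ties broken by class order."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# model persistence (versioned JSON for the native models)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _node_to_dict(node: _Node) -> dict:
    d = {
        "coef": node.coef.tolist(),
        "n": node.n,
        "error": node.error,
        "depth": node.depth,
    }
    if not node.is_leaf:
        d["feature"] = node.feature
        d["threshold"] = node.threshold
        d["left"] = _node_to_dict(node.left)
        d["right"] = _node_to_dict(node.right)
    return d


def _node_from_dict(d: dict) -> _Node:
    node = _Node()
    node.coef = np.asarray(d["coef"], dtype=float)
    node.n = d["n"]
    node.error = d["error"]
    node.depth = d["depth"]
    if "feature" in d:
        node.feature = d["feature"]
        node.threshold = d["threshold"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def save_model(model, path) -> None:
    """Serialize an LMT or MLR model as versioned JSON."""
    if isinstance(model, LMTModel):
        payload = {
            "format_version": _FORMAT_VERSION,
            "kind": "LMT",
            "classes": model.classes_.tolist(),
            "n_features": model.n_features_,
            "n_boost_iterations": model.n_boost_iterations,
            "pruning_alpha": float(model.pruning_alpha)
            if np.isfinite(model.pruning_alpha)
            else "inf",
            "root": _node_to_dict(model.root),
        }
    elif isinstance(model, RidgeMLRModel):
        payload = {
            "format_version": _FORMAT_VERSION,
            "kind": "MLR",
            "classes": model.classes_.tolist(),
            "coef": model.coef_.tolist(),
            "mean": model.mean_.tolist(),
            "scale": model.scale_.tolist(),
            "ridge": model.ridge,
        }
    else:
        raise CapabilityError(
            "only the native LMT and MLR models support JSON persistence"
        )
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Load a model previously written by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValidationError("unsupported model format version")
    if payload["kind"] == "LMT":
        alpha = payload["pruning_alpha"]
        return LMTModel(
            payload["classes"],
            _node_from_dict(payload["root"]),
            payload["n_features"],
            payload["n_boost_iterations"],
            np.inf if alpha == "inf" else float(alpha),
        )
    return RidgeMLRModel(
        payload["classes"],
        np.asarray(payload["coef"], dtype=float),
        np.asarray(payload["mean"], dtype=float),
        np.asarray(payload["scale"], dtype=float),
        payload["ridge"],
        {},
    )
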