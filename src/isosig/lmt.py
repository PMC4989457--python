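"""A compact logistic model tree (LMT) learner.

The model is a classification tree whose leaves carry additive logistic
regression functions built by LogitBoost with simple (one-attribute)
least-squares regressors.  Because every base learner is linear, a
leaf's committee collapses into an intercept plus one weight per
feature.  The number of boosting iterations is chosen by internal
5-fold cross-validation at the root and reused in the subtrees; the tree
is grown by information-gain splits and pruned bottom-up wherever the
cross-validated error of a single leaf model is no worse than that of
the subtree.

This is a simplified but faithful rendition of the classic LMT
algorithm; exact reproduction of any particular toolkit is not a goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.special import expit

from .infotheory import entropy_bits

_Z_MAX = 4.0          # working-response clip, standard LogitBoost guard
_W_FLOOR = 1e-6       # weight floor to keep the WLS problems well-posed
_SHRINKAGE = 0.5      # damping of each boosting step


@dataclass(frozen=True)
class LmtConfig:
    max_boost_iterations: int = 200
    min_samples_split: int = 15
    min_leaf: int = 5
    max_depth: int = 4
    inner_cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


# ---------------------------------------------------------------------------
# LogitBoost with simple-regression base learners ("simple logistic")
# ---------------------------------------------------------------------------


def _boost_path(
    X: np.ndarray, y: np.ndarray, n_iter: int
) -> np.ndarray:
    """Run LogitBoost for *n_iter* rounds; return the coefficient path.

    Output shape (n_iter + 1, p + 1): row m holds [intercept, weights]
    after m rounds.  Each round fits a weighted least-squares line on the
    single attribute that best reduces the squared working-response error.
    """
    n, p = X.shape
    coefs = np.zeros((n_iter + 1, p + 1))
    beta = np.zeros(p + 1)
    F = np.zeros(n)
    for m in range(1, n_iter + 1):
        prob = expit(F)
        w = np.clip(prob * (1.0 - prob), _W_FLOOR, None)
        z = np.clip((y - prob) / w, -_Z_MAX, _Z_MAX)
        sw = w.sum()
        zbar = (w * z).sum() / sw
        xbar = (w[:, None] * X).sum(axis=0) / sw
        xc = X - xbar
        cov = (w[:, None] * xc * (z - zbar)[:, None]).sum(axis=0)
        var = (w[:, None] * xc * xc).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(var > 1e-12, cov / np.where(var > 1e-12, var, 1.0), 0.0)
        # weighted-SSE reduction: the intercept part (common to all
        # attributes) plus the slope part of the best attribute
        gain = slope * cov
        j = int(np.argmax(gain))
        if sw * zbar * zbar + max(gain[j], 0.0) <= 1e-10:
            coefs[m:] = beta
            return coefs
        if gain[j] <= 0.0:  # intercept-only step (e.g. a pure node)
            slope[j] = 0.0
        b = slope[j]
        a = zbar - b * xbar[j]
        F = F + _SHRINKAGE * (a + b * X[:, j])
        beta[0] += _SHRINKAGE * a
        beta[j + 1] += _SHRINKAGE * b
        coefs[m] = beta
    return coefs


def _logloss(y: np.ndarray, F: np.ndarray) -> float:
    # numerically safe -sum log p(y)
    return float(np.logaddexp(0.0, -(2.0 * y - 1.0) * F).sum())


def _choose_iterations(
    X: np.ndarray, y: np.ndarray, cfg: LmtConfig, rng: np.random.Generator
) -> int:
    """Pick the boosting iteration count by stratified k-fold CV log-loss."""
    n = len(y)
    n_pos, n_neg = int(y.sum()), int(n - y.sum())
    folds = min(cfg.inner_cv_folds, n_pos, n_neg)
    if folds < 2:
        return min(20, cfg.max_boost_iterations)
    fold_of = np.empty(n, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    losses = np.zeros(cfg.max_boost_iterations + 1)
    ones = np.ones
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        if len(np.unique(y[tr])) < 2:
            continue
        path = _boost_path(X[tr], y[tr], cfg.max_boost_iterations)
        Xte = np.column_stack([ones(te.sum()), X[te]])
        F_te = Xte @ path.T  # (n_te, n_iter+1)
        yy = (2.0 * y[te] - 1.0)[:, None]
        losses += np.logaddexp(0.0, -yy * F_te).sum(axis=0)
    best = int(np.argmin(losses))
    return max(1, best)


@dataclass
class SimpleLogistic:
    """Additive logistic model: intercept + per-feature weights."""

    coef: np.ndarray  # shape (p + 1,)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.coef[0] + X @ self.coef[1:]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision(X))


def fit_simple_logistic(
    X: np.ndarray, y: np.ndarray, n_iter: int
) -> SimpleLogistic:
    path = _boost_path(X, y, n_iter)
    return SimpleLogistic(coef=path[n_iter].copy())


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


@dataclass
class LmtNode:
    """Split node (feature, threshold, children) or leaf (model)."""

    model: SimpleLogistic
    feature: int | None = None
    threshold: float | None = None
    left: "LmtNode | None" = None
    right: "LmtNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.is_leaf:
            return self.model.predict_proba(X)
        out = np.empty(len(X))
        mask = X[:, self.feature] <= self.threshold
        if mask.any():
            out[mask] = self.left.predict_proba(X[mask])
        if (~mask).any():
            out[~mask] = self.right.predict_proba(X[~mask])
        return out

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def to_dict(self) -> dict[str, Any]:
        if self.is_leaf:
            return {"kind": "leaf", "coef": [float(c) for c in self.model.coef]}
        return {
            "kind": "split",
            "feature": int(self.feature),
            "threshold": float(self.threshold),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
            "coef": [float(c) for c in self.model.coef],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "LmtNode":
        model = SimpleLogistic(coef=np.asarray(d["coef"], dtype=float))
        if d["kind"] == "leaf":
            return cls(model=model)
        return cls(
            model=model,
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _best_ig_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) by label information gain."""
    n, p = X.shape
    base = entropy_bits(np.bincount(y))
    best: tuple[int, float, float] | None = None
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        pos_left = np.cumsum(ys)
        total_pos = pos_left[-1]
        for i in range(min_leaf, n - min_leaf + 1):
            if i < n and xs[i - 1] == xs[i]:
                continue
            lp, ln = pos_left[i - 1], i - pos_left[i - 1]
            rp, rn = total_pos - lp, (n - i) - (total_pos - lp)
            if i > n - min_leaf:
                continue
            e = (i / n) * entropy_bits(np.array([lp, ln])) + (
                (n - i) / n
            ) * entropy_bits(np.array([rp, rn]))
            gain = base - e
            if best is None or gain > best[2]:
                best = (j, (xs[i - 1] + xs[i]) / 2.0, gain)
    if best is not None and best[2] <= 1e-12:
        return None
    return best


def _cv_error(
    X: np.ndarray, y: np.ndarray, n_iter: int, folds: int, rng: np.random.Generator
) -> float:
    """Cross-validated misclassification count of a simple-logistic fit."""
    n = len(y)
    n_pos, n_neg = int(y.sum()), int(n - y.sum())
    k = min(folds, n_pos, n_neg)
    if k < 2:  # too small / pure: resubstitution error of the majority class
        return float(min(n_pos, n_neg))
    fold_of = np.empty(n, dtype=int)
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(y == cls))
        fold_of[idx] = np.arange(len(idx)) % k
    errors = 0.0
    for f in range(k):
        tr, te = fold_of != f, fold_of == f
        model = fit_simple_logistic(X[tr], y[tr], n_iter)
        pred = model.predict_proba(X[te]) >= 0.5
        errors += float((pred != (y[te] == 1)).sum())
    return errors


def fit_lmt(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LmtConfig = LmtConfig(),
    seed: int = 0,
) -> LmtNode:
    """Fit a logistic model tree on samples × features data.

    X must be complete (impute upstream).  Raises on single-class y.
    With max_depth 0 the result is a single boosted logistic leaf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values; impute before fitting")
    if len(np.unique(y)) < 2:
        raise ValueError("y has a single class")
    rng = np.random.default_rng(seed)
    n_iter = _choose_iterations(X, y, cfg, rng)
    root, _ = _grow(X, y, cfg, n_iter, depth=0, rng=rng)
    return root


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    cfg: LmtConfig,
    n_iter: int,
    depth: int,
    rng: np.random.Generator,
) -> tuple[LmtNode, float]:
    """Grow and prune; returns (node, cv_error_of_node)."""
    model = fit_simple_logistic(X, y, n_iter)
    leaf_error = _cv_error(X, y, n_iter, cfg.inner_cv_folds, rng)
    node = LmtNode(model=model)
    n = len(y)
    if (
        depth >= cfg.max_depth
        or n < cfg.min_samples_split
        or len(np.unique(y)) < 2
    ):
        return node, leaf_error
    split = _best_ig_split(X, y, cfg.min_leaf)
    if split is None:
        return node, leaf_error
    j, thr, _gain = split
    mask = X[:, j] <= thr
    left, err_l = _grow(X[mask], y[mask], cfg, n_iter, depth + 1, rng)
    right, err_r = _grow(X[~mask], y[~mask], cfg, n_iter, depth + 1, rng)
    subtree_error = err_l + err_r
    if leaf_error <= subtree_error:  # prune: the leaf model is no worse
        return node, leaf_error
    node.feature, node.threshold = j, float(thr)
    node.left, node.right = left, right
    return node, subtree_error
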