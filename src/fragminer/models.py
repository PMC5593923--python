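"""Activity models on substructure descriptors.

Classification uses ridge-penalized logistic regression fitted by Newton
iteration: the log-likelihood sum_j log p(A_j | L_j, W) minus the
Gaussian-prior penalty ||W||^2 / (2 sigma^2) is maximized exactly (the
objective is strictly concave, so Newton steps with step-halving
converge to the unique optimum).  Regression uses epsilon-insensitive
support-vector regression with the RBF kernel
k(x, y) = exp(-||x - y||^2 / (2 sigma^2)); predictions are the usual
dual expansion sum_j alpha_j k(L_j, L_i) + b.

Evaluation follows the random sub-sampling protocol for classification
(split into 3 subsets, train on 2, validate on 1, average over repeats)
and seeded k-fold cross-validation (MSE and Pearson r) for regression.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVR as _SkSVR

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Regularized logistic regression
# ---------------------------------------------------------------------------


@dataclass
class RLRModel:
    W: np.ndarray
    sigma: float
    n_iter: int
    grad_norm: float
    converged: bool
    feature_keys: list[str] | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return expit(X @ self.W)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "rlr",
                "version": 1,
                "W": self.W.tolist(),
                "sigma": self.sigma,
                "n_iter": self.n_iter,
                "grad_norm": self.grad_norm,
                "converged": self.converged,
                "feature_keys": self.feature_keys,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RLRModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["W"], dtype=float),
            d["sigma"],
            d["n_iter"],
            d["grad_norm"],
            d["converged"],
            d.get("feature_keys"),
        )


def rlr_probability(W: np.ndarray, x: np.ndarray) -> float:
    """Active-class probability exp(W.x) / (1 + exp(W.x)), overflow-safe."""
    W = np.asarray(W, dtype=float)
    x = np.asarray(x, dtype=float)
    if W.shape != x.shape:
        raise ModelError("weight/descriptor length mismatch")
    return float(expit(W @ x))


def rlr_objective(W: np.ndarray, X: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Penalized log-likelihood maximized by :func:`fit_rlr`."""
    z = X @ W
    # log p = y*z - log(1 + e^z), computed stably
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    return ll - float(W @ W) / (2.0 * sigma**2)


def fit_rlr(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 100,
    feature_keys: list[str] | None = None,
) -> RLRModel:
    """Newton fit of the ridge-penalized logistic model.

    ``X`` is samples x features (descriptor vectors as rows), ``y`` the
    0/1 activity labels.  Iterates until the gradient norm drops below
    ``tol``; a step that would decrease the objective is halved (the
    concave objective makes the iterate sequence non-decreasing).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ModelError("X/y shape mismatch")
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise ModelError("labels must be binary 0/1")
    if len(classes) < 2:
        raise ModelError("both classes must be present")
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ModelError("need at least 2 samples per class")
    if sigma <= 0:
        raise ModelError("sigma must be positive")

    n = X.shape[1]
    W = np.zeros(n)
    inv_s2 = 1.0 / sigma**2
    obj = rlr_objective(W, X, y, sigma)
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ W)
        grad = X.T @ (y - p) - inv_s2 * W
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < tol:
            break
        r = np.maximum(p * (1.0 - p), 1e-12)
        H = (X.T * r) @ X + inv_s2 * np.eye(n)
        step = np.linalg.solve(H, grad)
        alpha = 1.0
        while alpha > 1e-8:
            W_new = W + alpha * step
            obj_new = rlr_objective(W_new, X, y, sigma)
            if obj_new >= obj - 1e-12:
                break
            alpha /= 2.0
        W = W + alpha * step
        obj = rlr_objective(W, X, y, sigma)
    converged = grad_norm < tol
    if not converged:
        logger.warning("RLR Newton did not converge: |grad|=%.3g", grad_norm)
    return RLRModel(W, sigma, it, grad_norm, converged, feature_keys)


# ---------------------------------------------------------------------------
# Classification metrics and CV
# ---------------------------------------------------------------------------


@dataclass
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    roc_auc: float
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_auc": self.roc_auc,
            "accuracy": self.accuracy,
        }


def evaluate_classification(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ClassificationMetrics:
    """Threshold metrics plus rank-based (Mann-Whitney) ROC AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ModelError("scores/labels length mismatch")
    if len(set(labels.tolist())) < 2:
        raise ModelError("both classes required for evaluation")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    return ClassificationMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        roc_auc=float(roc_auc_score(labels, scores)),
        accuracy=(tp + tn) / len(labels),
    )


def cv_random_subsampling(
    X: np.ndarray,
    y: np.ndarray,
    n_subsets: int = 3,
    repeats: int = 10,
    seed: int = 0,
    sigma: float = 1.0,
    max_retries: int = 20,
) -> ClassificationMetrics:
    """Random sub-sampling CV: split into subsets, train on all but one.

    Each repeat partitions the samples into ``n_subsets`` random subsets,
    trains on ``n_subsets - 1`` of them (a 2:1 train/validation ratio at
    the default 3) and evaluates on the held-out subset; metrics are
    averaged over repeats.  Fully seeded.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    m = len(y)
    if m < n_subsets:
        raise ModelError("not enough samples for the requested subsets")
    rng = np.random.default_rng(seed)
    collected: list[ClassificationMetrics] = []
    for _ in range(repeats):
        for attempt in range(max_retries):
            perm = rng.permutation(m)
            folds = np.array_split(perm, n_subsets)
            hold = int(rng.integers(n_subsets))
            val_idx = folds[hold]
            train_idx = np.concatenate([f for i, f in enumerate(folds) if i != hold])
            ok = (
                len(set(y[train_idx].tolist())) == 2
                and np.sum(y[train_idx] == 1) >= 2
                and np.sum(y[train_idx] == 0) >= 2
                and len(set(y[val_idx].tolist())) == 2
            )
            if ok:
                break
        else:
            raise ModelError("could not form a valid split (degenerate labels)")
        model = fit_rlr(X[train_idx], y[train_idx], sigma=sigma)
        scores = model.predict_proba(X[val_idx])
        collected.append(evaluate_classification(scores, y[val_idx]))
    return ClassificationMetrics(
        sensitivity=float(np.mean([c.sensitivity for c in collected])),
        specificity=float(np.mean([c.specificity for c in collected])),
        roc_auc=float(np.mean([c.roc_auc for c in collected])),
        accuracy=float(np.mean([c.accuracy for c in collected])),
    )


# ---------------------------------------------------------------------------
# RBF-kernel support vector regression
# ---------------------------------------------------------------------------


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """exp(-||x1 - x2||^2 / (2 sigma^2)); 1 at zero distance."""
    if sigma <= 0:
        raise ModelError("sigma must be positive")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ModelError("vector length mismatch")
    d2 = float(np.sum((x1 - x2) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


@dataclass
class SVRModel:
    alpha: np.ndarray          # signed dual coefficients of the support vectors
    b: float
    sigma: float               # kernel width
    box_constraint: float
    epsilon: float
    support_vectors: np.ndarray
    constant_fallback: float | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.constant_fallback is not None:
            return np.full(X.shape[0], self.constant_fallback)
        # dual expansion sum_j alpha_j k(SV_j, x) + b
        d2 = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-np.maximum(d2, 0.0) / (2.0 * self.sigma**2))
        return K @ self.alpha + self.b

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "svr",
                "version": 1,
                "alpha": self.alpha.tolist(),
                "b": self.b,
                "sigma": self.sigma,
                "box_constraint": self.box_constraint,
                "epsilon": self.epsilon,
                "support_vectors": self.support_vectors.tolist(),
                "constant_fallback": self.constant_fallback,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SVRModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["alpha"], dtype=float),
            d["b"],
            d["sigma"],
            d["box_constraint"],
            d["epsilon"],
            np.asarray(d["support_vectors"], dtype=float),
            d.get("constant_fallback"),
        )


def default_kernel_sigma(n_features: int) -> float:
    return float(np.sqrt(n_features / 2.0))


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    sigma: float | None = None,
    box_constraint: float = 10.0,
    epsilon: float = 0.1,
) -> SVRModel:
    """Epsilon-insensitive RBF-kernel SVR on descriptor vectors.

    ``sigma`` defaults to sqrt(n_features / 2).  A constant target is
    handled by predicting the constant (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ModelError("X/y shape mismatch")
    if X.shape[0] < 5:
        raise ModelError("need at least 5 training samples")
    if box_constraint <= 0 or epsilon < 0:
        raise ModelError("hyperparameters must be positive")
    if sigma is None:
        sigma = default_kernel_sigma(X.shape[1])
    if sigma <= 0:
        raise ModelError("sigma must be positive")
    if np.ptp(y) == 0:
        logger.warning("constant regression target; predicting the constant")
        return SVRModel(
            np.zeros(0), float(y[0]), sigma, box_constraint, epsilon,
            np.zeros((0, X.shape[1])), constant_fallback=float(y[0]),
        )
    gamma = 1.0 / (2.0 * sigma**2)
    sk = _SkSVR(kernel="rbf", gamma=gamma, C=box_constraint, epsilon=epsilon)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sk.fit(X, y)
    return SVRModel(
        alpha=sk.dual_coef_.ravel().copy(),
        b=float(sk.intercept_[0]),
        sigma=float(sigma),
        box_constraint=box_constraint,
        epsilon=epsilon,
        support_vectors=np.asarray(sk.support_vectors_, dtype=float),
    )


# ---------------------------------------------------------------------------
# Regression metrics and CV
# ---------------------------------------------------------------------------


@dataclass
class RegressionMetrics:
    mse: float
    pearson_r: float

    def as_dict(self) -> dict:
        return {"mse": self.mse, "pearson_r": self.pearson_r}


def cv_kfold_regression(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    sigma: float | None = None,
    box_constraint: float = 10.0,
    epsilon: float = 0.1,
) -> RegressionMetrics:
    """Seeded k-fold CV; fold-averaged MSE and Pearson correlation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ModelError("k exceeds the number of samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    mses, rs = [], []
    for i in range(k):
        val_idx = folds[i]
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = fit_svr(
            X[train_idx], y[train_idx],
            sigma=sigma, box_constraint=box_constraint, epsilon=epsilon,
        )
        pred = model.predict(X[val_idx])
        mses.append(float(np.mean((pred - y[val_idx]) ** 2)))
        if np.std(pred) == 0 or np.std(y[val_idx]) == 0:
            rs.append(0.0)
        else:
            rs.append(float(np.corrcoef(pred, y[val_idx])[0, 1]))
    return RegressionMetrics(mse=float(np.mean(mses)), pearson_r=float(np.mean(rs)))


def grid_search_svr(
    X: np.ndarray,
    y: np.ndarray,
    sigmas: Sequence[float],
    boxes: Sequence[float],
    epsilons: Sequence[float] = (0.1,),
    k: int = 5,
    seed: int = 0,
) -> tuple[dict, RegressionMetrics]:
    """Pick SVR hyperparameters by k-fold MSE; deterministic tie-break."""
    best = None
    for s in sigmas:
        for c in boxes:
            for e in epsilons:
                m = cv_kfold_regression(
                    X, y, k=k, seed=seed, sigma=s, box_constraint=c, epsilon=e
                )
                cand = (m.mse, s, c, e, m)
                if best is None or cand[:4] < best[:4]:
                    best = cand
    assert best is not None
    _, s, c, e, m = best
    return {"sigma": s, "box_constraint": c, "epsilon": e}, m
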