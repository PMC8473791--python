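"""From-scratch binary classifiers used by the impairment-prediction step.

Three classifiers, each exposing ``fit(X, y, class_weight=None)`` and
``predict_score(X)`` returning an impairment score in [0, 1] whose ranking
drives the ROC/PR analysis:

* :class:`GaussianNaiveBayes` — per-class per-feature Gaussian likelihoods
  with uniform class priors (the priors themselves act as the class
  balancing; no extra likelihood weighting).
* :class:`RBFSupportVectorMachine` — soft-margin SVM with a Gaussian RBF
  kernel, solved in the dual by sequential minimal optimization with
  maximal-violating-pair working-set selection; class weighting scales the
  per-class box constraint C.
* :class:`NeuralNetClassifier` — a fixed feed-forward net (inputs -> 16 ->
  8 -> 1, ReLU hidden, sigmoid output) trained by full-batch gradient
  descent on class-weighted binary cross-entropy.

The SVM and the network expect standardized features; wrap them in
:class:`Standardized` (the LOOCV driver does this) so the scaling is
re-estimated on every training fold.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, log_expit
from scipy.stats import norm


class ConvergenceError(RuntimeError):
    """Solver failed to reach its stopping tolerance within the budget."""


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if y.shape != (X.shape[0],):
        raise ValueError("y must be one label per row of X")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return X, y.astype(int)


def class_weights(labels) -> dict[int, float]:
    """Balanced inverse-frequency weights w_c = N / (2 N_c)."""
    y = np.asarray(labels).astype(int)
    n = y.size
    counts = {c: int((y == c).sum()) for c in (0, 1)}
    if 0 in counts.values():
        raise ValueError("both classes must be present to derive class weights")
    return {c: n / (2.0 * nc) for c, nc in counts.items()}


class GaussianNaiveBayes:
    """Gaussian naive Bayes with configurable (default uniform) priors.

    The posterior is the Bayes product of per-feature Gaussian likelihoods,
    evaluated in log space and normalized with log-sum-exp, so queries far
    outside the training range stay finite.
    """

    def __init__(self, priors: tuple[float, float] | str = (0.5, 0.5),
                 var_floor_frac: float = 1e-9):
        self.priors = priors
        self.var_floor_frac = var_floor_frac
        self.theta_: np.ndarray | None = None  # (2, d) means
        self.var_: np.ndarray | None = None  # (2, d) variances

    def fit(self, X, y, class_weight=None):
        X, y = _check_xy(X, y)
        if set(np.unique(y)) != {0, 1}:
            raise ValueError("training data must contain both classes")
        theta = np.vstack([X[y == c].mean(axis=0) for c in (0, 1)])
        var = np.vstack([X[y == c].var(axis=0) for c in (0, 1)])
        floor = self.var_floor_frac * max(X.var(axis=0).max(), 1e-12)
        self.var_ = np.maximum(var, floor)
        self.theta_ = theta
        if self.priors == "empirical":
            self.class_prior_ = np.array([(y == 0).mean(), (y == 1).mean()])
        else:
            p = np.asarray(self.priors, dtype=float)
            if p.shape != (2,) or not np.isclose(p.sum(), 1.0):
                raise ValueError("priors must be two values summing to 1")
            self.class_prior_ = p
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.theta_.shape[1]:
            raise ValueError(
                f"expected {self.theta_.shape[1]} features, got {X.shape[1]}"
            )
        jll = np.empty((X.shape[0], 2))
        for c in (0, 1):
            jll[:, c] = np.log(self.class_prior_[c]) + norm.logpdf(
                X, loc=self.theta_[c], scale=np.sqrt(self.var_[c])
            ).sum(axis=1)
        return jll

    def predict_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)  # log-sum-exp stabilization
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict_score(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def to_dict(self) -> dict:
        return {
            "kind": "gnb",
            "theta": self.theta_.tolist(),
            "var": self.var_.tolist(),
            "priors": self.class_prior_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianNaiveBayes":
        obj = cls()
        obj.theta_ = np.asarray(d["theta"], dtype=float)
        obj.var_ = np.asarray(d["var"], dtype=float)
        obj.class_prior_ = np.asarray(d["priors"], dtype=float)
        return obj


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """K(a, b) = exp(-gamma * ||a - b||^2)."""
    sq = (
        (A * A).sum(axis=1)[:, None]
        + (B * B).sum(axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


class RBFSupportVectorMachine:
    """Soft-margin RBF-kernel SVM solved by SMO in the dual.

    Per-class penalties are C * class_weight[c], so the minority class
    receives a larger box constraint.  The solver picks the maximal
    violating pair at each step and stops when the KKT gap drops below
    ``tol``; the run is fully deterministic for a given training set.
    """

    def __init__(self, C: float = 1.0, gamma: float | str = "scale",
                 tol: float = 1e-3, max_iter: int = 100_000,
                 record_objective: bool = False):
        self.C = C
        self.gamma = gamma
        self.tol = tol
        self.max_iter = max_iter
        self.record_objective = record_objective

    def _resolve_gamma(self, X: np.ndarray) -> float:
        if self.gamma == "scale":
            v = X.var()
            return 1.0 / (X.shape[1] * v) if v > 0 else 1.0
        return float(self.gamma)

    def fit(self, X, y, class_weight=None):
        X, y01 = _check_xy(X, y)
        if set(np.unique(y01)) != {0, 1}:
            raise ValueError("training data must contain both classes")
        w = class_weight or {0: 1.0, 1: 1.0}
        n = X.shape[0]
        ysgn = np.where(y01 == 1, 1.0, -1.0)
        Cvec = np.array([self.C * w[c] for c in y01], dtype=float)
        gamma = self._resolve_gamma(X)
        K = rbf_kernel(X, X, gamma)

        alpha = np.zeros(n)
        u = np.zeros(n)  # u_i = sum_j alpha_j y_j K_ij (decision sans bias)
        self.dual_objective_history_: list[float] = []
        kkt_gap = np.inf
        pos_m, neg_m = ysgn > 0, ysgn < 0
        c_hi = Cvec - 1e-12
        it = 0
        for it in range(self.max_iter):
            neg_e = ysgn - u  # -E_t; b cancels in pair selection/update
            up = (pos_m & (alpha < c_hi)) | (neg_m & (alpha > 1e-12))
            low = (pos_m & (alpha > 1e-12)) | (neg_m & (alpha < c_hi))
            cand_up = np.where(up, neg_e, -np.inf)
            cand_low = np.where(low, neg_e, np.inf)
            i = int(np.argmax(cand_up))
            j = int(np.argmin(cand_low))
            if not (np.isfinite(cand_up[i]) and np.isfinite(cand_low[j])):
                kkt_gap = 0.0
                break
            kkt_gap = neg_e[i] - neg_e[j]
            if kkt_gap <= self.tol:
                break
            s = ysgn[i] * ysgn[j]
            if s < 0:
                L = max(0.0, alpha[j] - alpha[i])
                H = min(Cvec[j], Cvec[i] + alpha[j] - alpha[i])
            else:
                L = max(0.0, alpha[i] + alpha[j] - Cvec[i])
                H = min(Cvec[j], alpha[i] + alpha[j])
            eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
            ei, ej = u[i] - ysgn[i], u[j] - ysgn[j]
            if eta > 1e-12:
                aj_new = alpha[j] + ysgn[j] * (ei - ej) / eta
            else:
                # degenerate pair (duplicate points): the dual is linear
                # along the pair direction, so jump to the better box end
                def _dobj(a):
                    dj = a - alpha[j]
                    di = s * (alpha[j] - a)
                    return (
                        di + dj
                        - di * ysgn[i] * u[i] - dj * ysgn[j] * u[j]
                        - 0.5 * (di * di * K[i, i] + dj * dj * K[j, j])
                        - di * dj * s * K[i, j]
                    )
                aj_new = max((L, H), key=_dobj)
                if _dobj(aj_new) <= 0.0:
                    raise ConvergenceError(
                        f"SMO stalled at KKT gap {kkt_gap:.3e} (degenerate pair)"
                    )
            aj_new = min(max(aj_new, L), H)
            ai_new = alpha[i] + s * (alpha[j] - aj_new)
            du = (ai_new - alpha[i]) * ysgn[i] * K[i] + (aj_new - alpha[j]) * ysgn[j] * K[j]
            u += du
            alpha[i], alpha[j] = ai_new, aj_new
            if self.record_objective:
                self.dual_objective_history_.append(
                    float(alpha.sum() - 0.5 * np.dot(alpha * ysgn, u))
                )
        else:
            raise ConvergenceError(
                f"SMO did not converge in {self.max_iter} iterations "
                f"(KKT gap {kkt_gap:.3e} > tol {self.tol:.1e})"
            )

        self.n_iter_ = it
        free = (alpha > 1e-8) & (alpha < Cvec - 1e-8)
        neg_e = ysgn - u
        if free.any():
            b = float(neg_e[free].mean())
        else:
            hi = neg_e[up].max() if up.any() else 0.0
            lo = neg_e[low].min() if low.any() else 0.0
            b = float((hi + lo) / 2.0)
        keep = alpha > 1e-10
        self.support_vectors_ = X[keep]
        self.dual_coef_ = (alpha * ysgn)[keep]
        self.intercept_ = b
        self.gamma_ = gamma
        self.kkt_gap_ = float(max(kkt_gap, 0.0))
        self.C_vec_ = Cvec
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.support_vectors_.size == 0:
            return np.full(X.shape[0], self.intercept_)
        K = rbf_kernel(X, self.support_vectors_, self.gamma_)
        return K @ self.dual_coef_ + self.intercept_

    def predict_score(self, X) -> np.ndarray:
        # logistic squash: monotone in the margin, 0.5 exactly on the
        # hyperplane, so cutoff 0.5 reproduces the geometric sign rule
        return expit(self.decision_function(X))

    def to_dict(self) -> dict:
        return {
            "kind": "svm",
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "gamma": self.gamma_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RBFSupportVectorMachine":
        obj = cls()
        obj.support_vectors_ = np.asarray(d["support_vectors"], dtype=float)
        obj.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        obj.intercept_ = float(d["intercept"])
        obj.gamma_ = float(d["gamma"])
        return obj


class NeuralNetClassifier:
    """Feed-forward net, inputs -> 16 -> 8 -> 1, ReLU hidden, sigmoid out.

    Trained with full-batch gradient descent on class-weighted binary
    cross-entropy, computed on the logit scale for numerical stability.
    Initialization is small symmetric uniform noise from ``seed``, so a
    fixed seed gives bit-reproducible weights; ``zero_init=True`` starts
    from all-zero weights (initial output exactly 0.5 everywhere).
    """

    HIDDEN = (16, 8)

    def __init__(self, epochs: int = 300, learning_rate: float = 0.5,
                 seed: int = 0, init_scale: float = 0.1, zero_init: bool = False):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.init_scale = init_scale
        self.zero_init = zero_init

    def _init_params(self, n_features: int) -> list[np.ndarray]:
        sizes = (n_features, *self.HIDDEN, 1)
        rng = np.random.default_rng(self.seed)
        params = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            if self.zero_init:
                W = np.zeros((fan_in, fan_out))
            else:
                W = rng.uniform(-self.init_scale, self.init_scale, (fan_in, fan_out))
            params.extend([W, np.zeros(fan_out)])
        return params

    @staticmethod
    def _forward(params, X):
        W1, b1, W2, b2, W3, b3 = params
        z1 = X @ W1 + b1
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ W2 + b2
        a2 = np.maximum(z2, 0.0)
        z3 = (a2 @ W3 + b3).ravel()
        return z1, a1, z2, a2, z3

    @staticmethod
    def _loss_and_grad(params, X, y, sample_w):
        """Weighted BCE on logits and its gradient (backpropagation)."""
        W1, b1, W2, b2, W3, b3 = params
        n = X.shape[0]
        z1, a1, z2, a2, z3 = NeuralNetClassifier._forward(params, X)
        wsum = sample_w.sum()
        # -[y log p + (1-y) log(1-p)] = softplus(z) - y z, via log_expit
        loss = float((sample_w * (-(log_expit(z3)) + (1.0 - y) * z3)).sum() / wsum)
        dz3 = (sample_w * (expit(z3) - y) / wsum)[:, None]
        gW3 = a2.T @ dz3
        gb3 = dz3.sum(axis=0)
        da2 = dz3 @ W3.T
        dz2 = da2 * (z2 > 0)
        gW2 = a1.T @ dz2
        gb2 = dz2.sum(axis=0)
        da1 = dz2 @ W2.T
        dz1 = da1 * (z1 > 0)
        gW1 = X.T @ dz1
        gb1 = dz1.sum(axis=0)
        return loss, [gW1, gb1, gW2, gb2, gW3, gb3]

    def fit(self, X, y, class_weight=None):
        X, y01 = _check_xy(X, y)
        if set(np.unique(y01)) != {0, 1}:
            raise ValueError("training data must contain both classes")
        w = class_weight or {0: 1.0, 1: 1.0}
        sample_w = np.array([w[c] for c in y01], dtype=float)
        params = self._init_params(X.shape[1])
        yf = y01.astype(float)
        self.loss_history_: list[float] = []
        for _ in range(self.epochs):
            loss, grads = self._loss_and_grad(params, X, yf, sample_w)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss ({loss}); "
                                   "reduce the learning rate")
            self.loss_history_.append(loss)
            for p, g in zip(params, grads):
                p -= self.learning_rate * g
        self.params_ = params
        return self

    def predict_score(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.params_[0].shape[0]:
            raise ValueError(
                f"expected {self.params_[0].shape[0]} features, got {X.shape[1]}"
            )
        *_, z3 = self._forward(self.params_, X)
        return expit(z3)

    def to_dict(self) -> dict:
        return {"kind": "ann", "params": [p.tolist() for p in self.params_]}

    @classmethod
    def from_dict(cls, d: dict) -> "NeuralNetClassifier":
        obj = cls()
        obj.params_ = [np.asarray(p, dtype=float) for p in d["params"]]
        return obj


class Standardized:
    """Wrap a classifier with train-fold feature standardization."""

    def __init__(self, base):
        self.base = base

    def fit(self, X, y, class_weight=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 1e-12, sd, 1.0)
        self.base.fit((X - self.mean_) / self.scale_, y, class_weight=class_weight)
        return self

    def predict_score(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.base.predict_score((X - self.mean_) / self.scale_)


CLASSIFIER_NAMES = ("GNB", "SVM", "ANN")


def make_classifier(name: str, seed: int = 0, **hyper):
    """Fresh classifier by short name; SVM and ANN come standardized."""
    key = name.upper()
    if key == "GNB":
        return GaussianNaiveBayes(**hyper)
    if key == "SVM":
        return Standardized(RBFSupportVectorMachine(**hyper))
    if key == "ANN":
        return Standardized(NeuralNetClassifier(seed=seed, **hyper))
    raise ValueError(f"unknown classifier {name!r} (expected one of {CLASSIFIER_NAMES})")
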