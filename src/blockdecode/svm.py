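"""Linear soft-margin SVM for two-class brain-state discrimination.

The trained objective is the one usually written for fMRI decoding work,

    min_{w,b,xi}  ||w||^2 + C * sum_i xi_i
    s.t.          y_i (w.x_i + b) >= 1 - xi_i,   xi_i >= 0,

note: *no* 1/2 factor on ||w||^2.  Training is delegated to libsvm via
scikit-learn's ``SVC`` (the solver family standard in this field), with the
trade-off parameter mapped C_internal = C/2 since libsvm minimizes
(1/2)||w||^2 + C_internal * sum xi — the two problems share the same
(w, b) optimum.  A no-bias mode (decision function f(x) = w.x exactly)
solves the box-constrained dual directly.

:func:`reference_dual_solve` is a slow brute-force quadratic-programming
reference (SLSQP on the dual) kept for validating the fast path on small
instances; it is not used for normal training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.svm import SVC

from .dataset import ExampleSet

__all__ = [
    "SVMModel",
    "train_svm",
    "decision_values",
    "predict",
    "accuracy",
    "cross_run_accuracy",
    "paired_cross_run_accuracy",
    "primal_objective",
    "reference_dual_solve",
]


@dataclass
class SVMModel:
    """A trained linear decision rule f(x) = w.x + b."""

    w: np.ndarray
    b: float
    C: float
    support_indices: np.ndarray
    slacks: np.ndarray
    fit_bias: bool = True

    @property
    def objective(self) -> float:
        """||w||^2 + C * sum(slacks) — the trained objective value."""
        return float(self.w @ self.w + self.C * self.slacks.sum())

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "b": float(self.b),
            "C": float(self.C),
            "support_indices": self.support_indices.tolist(),
            "fit_bias": self.fit_bias,
        }


def _as_xy(s, y=None):
    if isinstance(s, ExampleSet):
        return s.features, s.labels
    return np.asarray(s, dtype=float), np.asarray(y)


def _slacks(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float) -> np.ndarray:
    return np.maximum(0.0, 1.0 - y * (X @ w + b))


def train_svm(s, y=None, C: float = 1.0, fit_bias: bool = True, tol: float = 1e-6) -> SVMModel:
    """Train the linear soft-margin SVM.

    Accepts an :class:`~.dataset.ExampleSet` or an (X, y) pair.  C is the
    misclassification trade-off of the no-half-factor objective above
    (default 1, the conventional value).  Deterministic for fixed inputs.
    """
    X, yy = _as_xy(s, y)
    if C <= 0:
        raise ValueError("C must be positive")
    yy = np.asarray(yy, dtype=float)
    if X.ndim != 2 or len(yy) != X.shape[0]:
        raise ValueError("X must be (n_examples, n_features) matching y")
    classes = np.unique(yy)
    if not np.array_equal(np.sort(classes), [-1.0, 1.0]):
        raise ValueError("both classes (+1 and -1) must be present")

    c_internal = C / 2.0  # libsvm uses (1/2)||w||^2 + C_internal * sum xi
    if fit_bias:
        clf = SVC(kernel="linear", C=c_internal, tol=tol, shrinking=True)
        clf.fit(X, yy)
        # reconstruct the full dual vector and polish it to a tighter KKT
        # gap than libsvm's stopping rule delivers
        alpha = np.zeros(len(yy))
        alpha[clf.support_] = np.abs(clf.dual_coef_.ravel())
        alpha, b = _smo_refine(X, yy, alpha, c_internal)
        w = (alpha * yy) @ X
    else:
        alpha = _cd_nobias(X, yy, c_internal)
        w = (alpha * yy) @ X
        b = 0.0
    support = np.flatnonzero(alpha > 1e-8 * max(c_internal, 1.0))
    return SVMModel(
        w=w,
        b=b,
        C=C,
        support_indices=np.asarray(support, dtype=int),
        slacks=_slacks(X, yy, w, b),
        fit_bias=fit_bias,
    )


def _smo_refine(X, y, alpha, c_up, tol=1e-8, max_pairs=None):
    """Polish a near-optimal dual vector by max-violating-pair SMO.

    Works on  min (1/2) a'Qa - 1'a  s.t.  a.y = 0,  0 <= a <= c_up,  with
    Q = (yy')(XX').  Starting from libsvm's solution this converges in a few
    pair updates; returns (alpha, b) with b = midpoint of the KKT interval.
    """
    n = len(y)
    if max_pairs is None:
        # libsvm's solution is already near-optimal; a small fixed budget is
        # enough to close its stopping-rule slack without dominating runtime
        max_pairs = 500
    Q = (y[:, None] * y[None, :]) * (X @ X.T)
    grad = Q @ alpha - 1.0  # G_i; note -y_i * G_i = y_i - w.x_i
    eps = 1e-12 * max(1.0, c_up)
    for _ in range(max_pairs):
        f = -y * grad
        up = ((alpha < c_up - eps) & (y > 0)) | ((alpha > eps) & (y < 0))
        low = ((alpha < c_up - eps) & (y < 0)) | ((alpha > eps) & (y > 0))
        if not up.any() or not low.any():
            break
        i = np.flatnonzero(up)[np.argmax(f[up])]
        j = np.flatnonzero(low)[np.argmin(f[low])]
        gap = f[i] - f[j]
        if gap < tol:
            break
        # move along (e_i * y_i - e_j * y_j): keeps a.y fixed
        eta = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        t_star = gap / eta if eta > 1e-15 else np.inf
        t_max_i = (c_up - alpha[i]) if y[i] > 0 else alpha[i]
        t_max_j = (c_up - alpha[j]) if y[j] < 0 else alpha[j]
        t = min(t_star, t_max_i, t_max_j)
        if t <= 0:
            break
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        alpha[i] = min(max(alpha[i], 0.0), c_up)
        alpha[j] = min(max(alpha[j], 0.0), c_up)
        grad += t * (y[i] * Q[i] - y[j] * Q[j])
    f = -y * grad
    up = ((alpha < c_up - eps) & (y > 0)) | ((alpha > eps) & (y < 0))
    low = ((alpha < c_up - eps) & (y < 0)) | ((alpha > eps) & (y > 0))
    hi = f[up].max() if up.any() else 0.0
    lo = f[low].min() if low.any() else 0.0
    return alpha, float(0.5 * (hi + lo))


def _cd_nobias(X, y, c_up, tol=1e-12, max_sweeps=10_000):
    """Exact coordinate descent on the box-constrained dual (b fixed at 0):
    min (1/2) a'Qa - 1'a,  0 <= a <= c_up.  No equality constraint, so each
    coordinate minimization is a closed-form clip."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * (X @ X.T)
    diag = np.diag(Q).copy()
    alpha = np.zeros(n)
    grad = -np.ones(n)  # Q @ alpha - 1
    for _ in range(max_sweeps):
        delta_max = 0.0
        for i in range(n):
            if diag[i] > 1e-15:
                new = min(max(alpha[i] - grad[i] / diag[i], 0.0), c_up)
            else:
                # linear in alpha_i: push to whichever bound lowers the dual
                new = 0.0 if grad[i] > 0 else c_up
            d = new - alpha[i]
            if d != 0.0:
                alpha[i] = new
                grad += d * Q[i]
                delta_max = max(delta_max, abs(d))
        if delta_max < tol * max(1.0, c_up):
            break
    return alpha


def decision_values(m: SVMModel, X) -> np.ndarray:
    """f(x) = w.x + b for every row of X."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(m.w):
        raise ValueError(
            f"feature count {X.shape[1]} does not match model dimension {len(m.w)}"
        )
    return X @ m.w + m.b


def predict(m: SVMModel, X) -> np.ndarray:
    """Class labels from the sign of the decision function (0 -> +1)."""
    d = decision_values(m, X)
    return np.where(d >= 0, 1, -1)


def accuracy(m: SVMModel, s, y=None) -> float:
    X, yy = _as_xy(s, y)
    return float(np.mean(predict(m, X) == np.asarray(yy)))


def cross_run_accuracy(train_set: ExampleSet, test_set: ExampleSet, C: float = 1.0, **kw) -> float:
    """Train on one run, test on the other; fraction correctly classified."""
    if not train_set.same_feature_space(test_set):
        raise ValueError("train and test sets use different feature spaces")
    model = train_svm(train_set, C=C, **kw)
    return accuracy(model, test_set)


def paired_cross_run_accuracy(s1: ExampleSet, s2: ExampleSet, C: float = 1.0, **kw) -> float:
    """Mean of the two train/test directions (run1->run2 and run2->run1)."""
    return 0.5 * (
        cross_run_accuracy(s1, s2, C, **kw) + cross_run_accuracy(s2, s1, C, **kw)
    )


def primal_objective(X, y, w, b, C) -> float:
    """||w||^2 + C * sum of hinge slacks at (w, b)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(w @ w + C * _slacks(X, y, np.asarray(w), b).sum())


def reference_dual_solve(X, y, C: float = 1.0, fit_bias: bool = True):
    """Brute-force reference solution of the SVM dual (small instances).

    Solves  min (1/2) a'Qa - 1'a  s.t. 0 <= a <= C/2  (and  a.y = 0 when a
    bias is fitted) with SLSQP from several starts, then recovers (w, b)
    from the KKT conditions.  Intended as an independent check of
    :func:`train_svm` on problems with a handful of examples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    c_up = C / 2.0
    Q = (y[:, None] * y[None, :]) * (X @ X.T)

    def fun(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    cons = []
    if fit_bias:
        cons.append({"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y})
    best = None
    for start in (
        np.zeros(n),
        np.full(n, 0.5 * c_up),
        np.full(n, c_up),
    ):
        res = minimize(
            fun,
            start,
            jac=jac,
            bounds=[(0.0, c_up)] * n,
            constraints=cons,
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 2000},
        )
        a = np.clip(res.x, 0.0, c_up)
        if fit_bias and n:
            # project tiny equality violations out along y
            a = np.clip(a - (a @ y) / (y @ y) * y, 0.0, c_up)
        if best is None or fun(a) < fun(best):
            best = a
    alpha = best
    w = (alpha * y) @ X
    if not fit_bias:
        return w, 0.0, alpha
    margin = 1e-6 * max(c_up, 1.0)
    free = (alpha > margin) & (alpha < c_up - margin)
    if free.any():
        b = float(np.mean(y[free] - X[free] @ w))
    else:
        # no free SVs: b lies in a feasibility interval; take its midpoint
        g = 1.0 - y * (X @ w)  # y*b must be >= g where alpha < C, <= g where alpha > 0
        lo, hi = -np.inf, np.inf
        for i in range(n):
            lo_i = g[i] * y[i] if y[i] > 0 else -np.inf
            hi_i = g[i] * y[i] if y[i] < 0 else np.inf
            if alpha[i] < c_up - margin:  # constraint must hold with >=
                if y[i] > 0:
                    lo = max(lo, g[i])
                else:
                    hi = min(hi, -g[i])
            if alpha[i] > margin:  # active constraint: <=
                if y[i] > 0:
                    hi = min(hi, g[i])
                else:
                    lo = max(lo, -g[i])
        if not np.isfinite(lo):
            lo = hi
        if not np.isfinite(hi):
            hi = lo
        b = float(0.5 * (lo + hi)) if np.isfinite(lo) else 0.0
    return w, b, alpha
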