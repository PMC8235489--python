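"""L2-regularized hinge-loss linear classification.

The binary problem solved here is

    min_w  sum_n max(0, 1 - y_n * (w . x_n))  +  alpha * ||w||^2,

with labels y_n in {-1, +1}.  This is the workhorse of both the per-subset
confusion classifiers and the final one-vs-all stage; any bias term is
handled by the caller appending a constant-1 column, so the bias is
regularized together with the weights and the objective above is exactly
what is optimized.

Solver
------
Rescaling by 1/(2*alpha) shows the problem is a standard soft-margin linear
SVM with box constant C = 1/(2*alpha); it is solved in the dual by cyclic
coordinate descent (the classic liblinear scheme), which is deterministic:
samples are visited in fixed index order, so two fits on identical inputs
produce bitwise-identical weights.  After every epoch the primal objective
is evaluated and the best (lowest-objective) iterate so far is retained;
the solver returns that best iterate and its per-epoch objective trace,
which is therefore non-increasing by construction while the monotone dual
ascent underneath guarantees convergence; iteration stops when the
primal-dual gap falls below a relative tolerance, which certifies the
suboptimality of the returned weights.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .errors import ConfigError, NumericError

__all__ = ["hinge_loss", "hinge_objective", "fit_binary_hinge",
           "fit_standardized_hinge"]


def hinge_loss(score: float, y: int) -> float:
    """Hinge loss max(0, 1 - score*y) for a single prediction.

    Parameters
    ----------
    score : real decision value w.x
    y : binary label, must be -1 or +1
    """
    if y not in (-1, 1):
        raise ConfigError(f"binary label must be -1 or +1, got {y!r}")
    return max(0.0, 1.0 - float(score) * y)


def hinge_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Regularized hinge objective sum_n max(0, 1 - y_n w.x_n) + alpha ||w||^2."""
    margins = X @ w * y
    return float(np.sum(np.maximum(0.0, 1.0 - margins)) + alpha * np.dot(w, w))


@njit(cache=True)
def _dcd_epochs(X, y, box, alpha, max_iter, tol):  # pragma: no cover - numba
    n, d = X.shape
    w = np.zeros(d)
    dual = np.zeros(n)
    qd = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += X[i, j] * X[i, j]
        qd[i] = s
    w_best = w.copy()
    best = np.inf
    trace = np.empty(max_iter)
    n_epochs = 0
    for epoch in range(max_iter):
        for i in range(n):
            if qd[i] <= 0.0:
                continue
            g = 0.0
            for j in range(d):
                g += w[j] * X[i, j]
            g = y[i] * g - 1.0
            a_new = dual[i] - g / qd[i]
            if a_new < 0.0:
                a_new = 0.0
            elif a_new > box:
                a_new = box
            delta = a_new - dual[i]
            if delta != 0.0:
                dual[i] = a_new
                for j in range(d):
                    w[j] += delta * y[i] * X[i, j]
        # SVM-scale primal/dual objectives of the current iterate
        hinge_sum = 0.0
        for i in range(n):
            m = 0.0
            for j in range(d):
                m += w[j] * X[i, j]
            h = 1.0 - y[i] * m
            if h > 0.0:
                hinge_sum += h
        reg = 0.0
        for j in range(d):
            reg += w[j] * w[j]
        p_svm = 0.5 * reg + box * hinge_sum
        dual_sum = 0.0
        for i in range(n):
            dual_sum += dual[i]
        d_svm = dual_sum - 0.5 * reg
        obj = hinge_sum + alpha * reg  # user-scale primal
        if obj < best:
            best = obj
            w_best[:] = w
        trace[epoch] = best
        n_epochs = epoch + 1
        if p_svm - d_svm <= tol * max(1.0, p_svm):
            break
    return w_best, trace[:n_epochs]


def fit_binary_hinge(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a binary L2-hinge linear classifier.

    Parameters
    ----------
    X : (n, d) feature matrix (append a constant column yourself if you
        want a bias term; it will be regularized with the weights).
    y : (n,) labels in {-1, +1}.
    alpha : regularization strength, must be > 0.
    max_iter : epoch cap of the coordinate-descent solver.
    tol : relative duality-gap stopping tolerance (the gap bounds the
        objective suboptimality of the returned iterate).
    seed : accepted for interface stability; the solver is deterministic
        and does not consume randomness.

    Returns
    -------
    w : (d,) weight vector of the best iterate.
    trace : per-epoch primal objective of the retained best iterate;
        non-increasing.
    """
    if alpha <= 0:
        raise ConfigError(f"alpha must be positive, got {alpha}")
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ConfigError(f"X {X.shape} and y {y.shape} are misaligned")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ConfigError("labels must be -1/+1")
    if not np.all(np.isfinite(X)):
        raise NumericError("non-finite feature values")
    box = 1.0 / (2.0 * alpha)
    w, trace = _dcd_epochs(X, y, box, float(alpha), int(max_iter), float(tol))
    if not np.all(np.isfinite(w)):
        raise NumericError("hinge solver produced non-finite weights")
    return w, trace


def fit_standardized_hinge(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> np.ndarray:
    """Binary hinge fit on z-scored features, folded back to raw space.

    Columns are standardized with statistics of ``X`` itself, a constant-1
    bias column is appended, :func:`fit_binary_hinge` is run, and the
    affine transform is folded back so the returned ``(d+1,)`` vector
    (weights, then bias) scores *raw* features directly.  Standardizing
    first keeps the coordinate-descent solver well conditioned on feature
    tables with large offsets or very different column scales; the fit is
    deterministic in its inputs.
    """
    X = np.asarray(X, dtype=np.float64)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xa = np.hstack([(X - mean) / scale, np.ones((X.shape[0], 1))])
    w, _ = fit_binary_hinge(Xa, y, alpha=alpha, max_iter=max_iter, tol=tol)
    out = np.empty_like(w)
    out[:-1] = w[:-1] / scale
    out[-1] = w[-1] - np.dot(w[:-1], mean / scale)
    return out
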