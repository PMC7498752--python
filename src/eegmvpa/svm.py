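"""Batched soft-margin linear SVM for many small two-class problems.

Time-resolved decoding trains an enormous number of tiny classifiers: one
per timepoint, fold, repeat and condition pair, each on a handful of
pseudo-trials.  Fitting them one at a time through a generic SVM interface
is dominated by per-call overhead, so this module solves the standard
C-SVM dual (hinge loss, bias term, fixed C) for a whole batch of problems
simultaneously with a vectorized SMO sweep.  All problems in a batch must
share the same label vector, which is always the case here because
pseudo-trial construction yields a fixed number of training exemplars per
condition.

The solver targets the same optimum as libsvm; agreement with
``sklearn.svm.SVC(kernel="linear")`` is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_linear_svm_batch", "decision_function", "BatchedLinearSVM"]


def fit_linear_svm_batch(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-8,
    max_sweeps: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit B independent linear C-SVMs sharing one label vector.

    Parameters
    ----------
    X:
        Training samples, shape ``(B, n, d)`` — B problems, n samples each.
    y:
        Labels in {-1, +1}, shape ``(n,)``, shared across the batch.
    C:
        Box constraint of the soft margin.

    Returns
    -------
    (weights, bias):
        ``weights`` of shape ``(B, d)`` and ``bias`` of shape ``(B,)`` such
        that the decision value of sample x is ``w @ x + b``.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must be (batch, n_samples, n_features)")
    B, n, d = X.shape
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (n,):
        raise ValueError("y length must match n_samples")
    if not set(np.unique(y)) <= {-1.0, 1.0} or len(np.unique(y)) != 2:
        raise ValueError("y must contain both labels -1 and +1")

    K = X @ X.transpose(0, 2, 1)  # (B, n, n) linear Gram matrices
    alpha = np.zeros((B, n))
    g = np.zeros((B, n))  # decision values without bias at training points

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for _ in range(max_sweeps):
        max_step = 0.0
        for i, j in pairs:
            s = y[i] * y[j]
            eta = K[:, i, i] + K[:, j, j] - 2.0 * K[:, i, j]
            workable = eta > 1e-12
            # unconstrained optimum along the pair direction (Platt's update)
            delta = y[j] * ((g[:, i] - y[i]) - (g[:, j] - y[j]))
            aj_new = alpha[:, j] + np.where(workable, delta / np.where(workable, eta, 1.0), 0.0)
            if s < 0:
                lo = np.maximum(0.0, alpha[:, j] - alpha[:, i])
                hi = np.minimum(C, C + alpha[:, j] - alpha[:, i])
            else:
                lo = np.maximum(0.0, alpha[:, i] + alpha[:, j] - C)
                hi = np.minimum(C, alpha[:, i] + alpha[:, j])
            aj_new = np.clip(aj_new, lo, hi)
            d_j = np.where(workable, aj_new - alpha[:, j], 0.0)
            step = np.abs(d_j).max(initial=0.0)
            if step > max_step:
                max_step = step
            if step == 0.0:
                continue
            d_i = -s * d_j
            alpha[:, j] += d_j
            alpha[:, i] += d_i
            g += (d_i * y[i])[:, None] * K[:, :, i] + (d_j * y[j])[:, None] * K[:, :, j]
        if max_step < tol:
            break

    weights = np.einsum("bn,n,bnd->bd", alpha, y, X)
    bias = _bias_from_kkt(alpha, g, y, C)
    return weights, bias


def _bias_from_kkt(
    alpha: np.ndarray, g: np.ndarray, y: np.ndarray, C: float
) -> np.ndarray:
    """Bias as the midpoint of the KKT-feasible interval (libsvm's rho rule)."""
    eps = 1e-9 * max(C, 1.0)
    resid = y[None, :] - g  # candidate bias from each training point
    at_lower = alpha <= eps
    at_upper = alpha >= C - eps
    free = ~at_lower & ~at_upper
    pos = y[None, :] > 0
    # points that bound b from above / below under the KKT conditions
    upper_set = (pos & ~at_upper) | (~pos & ~at_lower)
    lower_set = (pos & ~at_lower) | (~pos & ~at_upper)
    b_up = np.where(upper_set, resid, np.inf).min(axis=1)
    b_lo = np.where(lower_set, resid, -np.inf).max(axis=1)
    free_mean = np.where(free, resid, 0.0).sum(axis=1)
    n_free = free.sum(axis=1)
    has_free = n_free > 0
    bias = np.where(
        has_free,
        free_mean / np.maximum(n_free, 1),
        0.5 * (b_up + b_lo),
    )
    return np.where(np.isfinite(bias), bias, 0.0)


def decision_function(
    weights: np.ndarray, bias: np.ndarray, X_test: np.ndarray
) -> np.ndarray:
    """Decision values for a batch: ``(B, m)`` from test samples ``(B, m, d)``."""
    return np.einsum("bmd,bd->bm", np.asarray(X_test, dtype=np.float64), weights) + bias[:, None]


class BatchedLinearSVM:
    """Thin object wrapper around the batched solver (train/predict contract).

    Predictions are +1 for non-negative decision values.
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self.weights: np.ndarray | None = None
        self.bias: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BatchedLinearSVM":
        self.weights, self.bias = fit_linear_svm_batch(X, y, C=self.C)
        return self

    def decision_function(self, X_test: np.ndarray) -> np.ndarray:
        if self.weights is None or self.bias is None:
            raise RuntimeError("fit must be called before prediction")
        return decision_function(self.weights, self.bias, X_test)

    def predict(self, X_test: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X_test) >= 0, 1.0, -1.0)
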