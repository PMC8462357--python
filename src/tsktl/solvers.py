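"""Closed-form consequent solvers for the classic and transfer TSK systems.

The classic ridge-style fit minimizes

    J_FS(p)  = 1/2 p^T p + lambda1/2 ||p^T X_s - y||^2

over the stacked consequent vector p (length K(d+1)); its unique minimizer
is p0 = (I + lambda1 X_s X_s^T)^{-1} (lambda1 X_s y).

The transfer objective adds a joint-distribution (MMD) penalty over the
pooled source+target design matrix X and a knowledge term tying p to the
historical consequents p0:

    J_TL(p) = J_FS(p) + lambda2 tr(p^T X M X^T p) + lambda3 ||p0 - p||^2

Setting the gradient to zero gives the normal equations solved by
:func:`fit_tsk_tl`:

    ((1 + 2 lambda3) I + lambda1 X_s X_s^T + lambda2 X (M + M^T) X^T) p
        = lambda1 X_s y + 2 lambda3 p0.

All systems are symmetric positive definite for nonnegative lambdas and are
solved by Cholesky factorization, never by explicit inversion.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "fit_tsk_fs",
    "tsk_fs_objective",
    "tsk_tl_objective",
    "tsk_tl_gradient",
    "fit_tsk_tl",
    "decision_values",
    "predict_labels",
]


def _check_design(Xg, y=None) -> np.ndarray:
    Xg = np.asarray(Xg, dtype=float)
    if Xg.ndim != 2:
        raise ValueError("design matrix must be 2-D (K(d+1) x N)")
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if y.size != Xg.shape[1]:
            raise ValueError(
                f"label count {y.size} does not match design columns {Xg.shape[1]}"
            )
        return Xg, y
    return Xg


def fit_tsk_fs(Xg_source, y, lambda1: float) -> np.ndarray:
    """Classic TSK-FS consequents p0 = (I + l1 X X^T)^{-1} (l1 X y)."""
    Xg, y = _check_design(Xg_source, y)
    if lambda1 < 0:
        raise ValueError("lambda1 must be nonnegative")
    p = Xg.shape[0]
    if lambda1 == 0:
        return np.zeros(p)
    A = lambda1 * (Xg @ Xg.T)
    A[np.diag_indices(p)] += 1.0
    return cho_solve(cho_factor(A, lower=True), lambda1 * (Xg @ y))


def tsk_fs_objective(p, Xg_source, y, lambda1: float) -> float:
    """J_FS(p) = 1/2 p^T p + lambda1/2 ||p^T X - y||^2."""
    Xg, y = _check_design(Xg_source, y)
    p = np.asarray(p, dtype=float).ravel()
    resid = p @ Xg - y
    return 0.5 * float(p @ p) + 0.5 * lambda1 * float(resid @ resid)


def tsk_tl_objective(p, Xg_source, y, Xg_all, M, p0, lambda1, lambda2, lambda3) -> float:
    """Transfer objective J_TL(p); used for diagnostics and as optimizer oracle."""
    p = np.asarray(p, dtype=float).ravel()
    p0 = np.asarray(p0, dtype=float).ravel()
    Xg_all = _check_design(Xg_all)
    M = np.asarray(M, dtype=float)
    if M.shape != (Xg_all.shape[1], Xg_all.shape[1]):
        raise ValueError("M must be (n+m) x (n+m) matching the pooled design")
    base = tsk_fs_objective(p, Xg_source, y, lambda1)
    proj = p @ Xg_all
    mmd = float(proj @ M @ proj)
    diff = p0 - p
    return base + lambda2 * mmd + lambda3 * float(diff @ diff)


def tsk_tl_gradient(p, Xg_source, y, Xg_all, M, p0, lambda1, lambda2, lambda3) -> np.ndarray:
    """Analytic gradient of :func:`tsk_tl_objective` with respect to p."""
    p = np.asarray(p, dtype=float).ravel()
    p0 = np.asarray(p0, dtype=float).ravel()
    Xg_s, y = _check_design(Xg_source, y)
    Xg_all = _check_design(Xg_all)
    M = np.asarray(M, dtype=float)
    grad = p + lambda1 * (Xg_s @ (p @ Xg_s - y))
    grad += lambda2 * (Xg_all @ ((M + M.T) @ (Xg_all.T @ p)))
    grad += 2.0 * lambda3 * (p - p0)
    return grad


def fit_tsk_tl(
    Xg_source,
    y,
    Xg_all,
    M,
    p0,
    lambda1: float,
    lambda2: float,
    lambda3: float,
    literal_form: bool = False,
) -> np.ndarray:
    """Transfer consequents: the unique stationary point of J_TL.

    Solves ((1+2*l3) I + l1 Xs Xs^T + l2 X (M+M^T) X^T) p = l1 Xs y + 2*l3 p0
    by Cholesky factorization.  With ``literal_form=True`` a compatibility
    variant is returned instead, solving

        (X (M+M^T)/2 X^T + l1 Xs Xs^T + l3 I) p = l1 Xs y + l3 p0,

    a historical form that drops the l2 weight, the unit ridge term and the
    factor 2 on the knowledge term; it is *not* the minimizer of J_TL and is
    provided only for cross-implementation comparison.
    """
    Xg_s, y = _check_design(Xg_source, y)
    Xg_all = _check_design(Xg_all)
    p0 = np.asarray(p0, dtype=float).ravel()
    M = np.asarray(M, dtype=float)
    if min(lambda1, lambda2, lambda3) < 0:
        raise ValueError("regularization weights must be nonnegative")
    k = Xg_s.shape[0]
    if Xg_all.shape[0] != k or p0.size != k:
        raise ValueError("design matrices and p0 disagree on K(d+1)")
    Msym = 0.5 * (M + M.T)

    if literal_form:
        A = Xg_all @ Msym @ Xg_all.T + lambda1 * (Xg_s @ Xg_s.T)
        A[np.diag_indices(k)] += lambda3
        rhs = lambda1 * (Xg_s @ y) + lambda3 * p0
        try:
            return np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(A, rhs, rcond=None)[0]

    A = lambda1 * (Xg_s @ Xg_s.T) + 2.0 * lambda2 * (Xg_all @ Msym @ Xg_all.T)
    A[np.diag_indices(k)] += 1.0 + 2.0 * lambda3
    rhs = lambda1 * (Xg_s @ y) + 2.0 * lambda3 * p0
    return cho_solve(cho_factor(A, lower=True), rhs)


def decision_values(p, Xg) -> np.ndarray:
    """Decision values p^T x_g per design column (the TSK defuzzified output)."""
    Xg = _check_design(Xg)
    p = np.asarray(p, dtype=float).ravel()
    if p.size != Xg.shape[0]:
        raise ValueError("consequent length does not match design rows")
    return p @ Xg


def predict_labels(p, Xg) -> np.ndarray:
    """Signed predictions in {+1, -1}; an exact zero decision value maps to +1."""
    return np.where(decision_values(p, Xg) >= 0.0, 1.0, -1.0)
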