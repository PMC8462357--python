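"""Fuzzy-rule antecedent learning and firing-strength design matrices.

A TSK (Takagi-Sugeno-Kang) fuzzy classifier is a rule base

    R^k : IF x_1 is A_1^k and ... and x_d is A_d^k
          THEN f^k(x) = p_0^k + p_1^k x_1 + ... + p_d^k x_d

whose output is the normalized-firing-strength-weighted average of the rule
outputs f^k.  This module learns the IF-part: fuzzy c-means places one rule
per cluster, each Gaussian fuzzy set A_i^k is parameterized by a center
c_i^k and a squared-width delta_i^k, and the defuzzified output is rewritten
as a linear regression on the "fuzzy design matrix" whose column for sample
x stacks, over rules k, the block  mu~^k(x) * (1, x^T)^T.

All user-facing feature matrices are samples x features; design matrices are
stored one column per sample so that decision values are ``p_g @ X_g``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "MembershipPartition",
    "AntecedentModel",
    "DegenerateClusterError",
    "fcm_partition",
    "estimate_antecedent",
    "gaussian_membership",
    "firing_strengths",
    "build_design",
]

#: squared widths below this are clamped to it; guards division blow-up on
#: degenerate (near-singleton) clusters.
WIDTH_FLOOR = 1e-8


class DegenerateClusterError(ValueError):
    """A cluster received (numerically) zero total membership."""


def _as_feature_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"feature matrix must be 2-D (N x d), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite entries")
    return X


@dataclass(frozen=True)
class MembershipPartition:
    """Fuzzy c-means partition: row-stochastic memberships u (N x K)."""

    u: np.ndarray
    fuzzifier: float
    seed: int
    iterations_run: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.u.shape[1]


@dataclass(frozen=True)
class AntecedentModel:
    """Gaussian rule antecedents: centers c_i^k and squared widths delta_i^k.

    ``widths`` holds the delta that sits under the 2 in the membership
    exponent exp(-(x_i - c_i^k)^2 / (2 delta_i^k)) -- a variance-like
    quantity, not a standard deviation.  ``h`` is the scale factor applied
    when the widths were estimated.
    """

    centers: np.ndarray  # (K, d)
    widths: np.ndarray  # (K, d), strictly positive
    h: float = 1.0

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        w = np.atleast_2d(np.asarray(self.widths, dtype=float))
        if c.shape != w.shape:
            raise ValueError("centers and widths must share shape (K, d)")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite centers")
        if np.any(w <= 0):
            raise ValueError("widths must be strictly positive")
        if self.h <= 0:
            raise ValueError("scale parameter h must be positive")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "widths", w)

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    def to_dict(self) -> dict:
        return {
            "K": int(self.n_rules),
            "d": int(self.n_features),
            "h": float(self.h),
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AntecedentModel":
        return cls(
            centers=np.asarray(doc["centers"], dtype=float),
            widths=np.asarray(doc["widths"], dtype=float),
            h=float(doc["h"]),
        )


def fcm_partition(
    X,
    n_clusters: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> MembershipPartition:
    """Fuzzy c-means soft partition of the rows of ``X``.

    Memberships u_jk minimize sum_jk u_jk^fuzzifier ||x_j - v_k||^2 subject
    to row-stochasticity.  Centers are initialized by drawing ``n_clusters``
    distinct data rows with the given seed, so a fixed seed is
    bit-reproducible.  Iteration stops when the largest center displacement
    falls below ``tol`` or after ``max_iter`` sweeps.
    """
    X = _as_feature_matrix(X)
    n, _ = X.shape
    K = int(n_clusters)
    if K < 1:
        raise ValueError("n_clusters must be >= 1")
    if K > n:
        raise ValueError(f"n_clusters={K} exceeds the sample count {n}")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    if tol <= 0:
        raise ValueError("tol must be positive")

    if K == 1:
        u = np.ones((n, 1))
        return MembershipPartition(u, fuzzifier, seed, 0, True)

    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=K, replace=False)].copy()
    expo = 2.0 / (fuzzifier - 1.0)
    u = np.empty((n, K))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # squared distances (n, K)
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0
        if np.any(zero):
            # a sample sitting exactly on a center belongs there crisply
            u[:] = 0.0
            hit = zero.any(axis=1)
            u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
            rest = ~hit
            if np.any(rest):
                ratio = d2[rest][:, :, None] / d2[rest][:, None, :]
                u[rest] = 1.0 / (ratio ** (1.0 / (fuzzifier - 1.0))).sum(axis=2)
        else:
            inv = d2 ** (-expo / 2.0)
            u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** fuzzifier
        new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break
    return MembershipPartition(u, fuzzifier, seed, it, converged)


def estimate_antecedent(X, partition: MembershipPartition, h: float = 1.0) -> AntecedentModel:
    """Membership-weighted centers and (h-scaled) squared widths per rule.

    Uses the raw memberships u_jk (not u^fuzzifier):

        c_i^k   = sum_j u_jk x_ji / sum_j u_jk
        delta_i^k = h * sum_j u_jk (x_ji - c_i^k)^2 / sum_j u_jk

    Widths below ``WIDTH_FLOOR`` are clamped to it.
    """
    X = _as_feature_matrix(X)
    u = np.asarray(partition.u, dtype=float)
    if u.shape[0] != X.shape[0]:
        raise ValueError("partition and feature matrix disagree on sample count")
    if h <= 0:
        raise ValueError("h must be positive")
    totals = u.sum(axis=0)
    dead = np.flatnonzero(totals <= 1e-12)
    if dead.size:
        raise DegenerateClusterError(
            f"cluster(s) {dead.tolist()} have ~zero total membership"
        )
    centers = (u.T @ X) / totals[:, None]
    sq = (X[:, None, :] - centers[None, :, :]) ** 2  # (N, K, d)
    widths = h * np.einsum("jk,jki->ki", u, sq) / totals[:, None]
    widths = np.maximum(widths, WIDTH_FLOOR)
    return AntecedentModel(centers=centers, widths=widths, h=float(h))


def _log_memberships(ant: AntecedentModel, X: np.ndarray) -> np.ndarray:
    """Log Gaussian memberships, shape (N, K, d)."""
    diff = X[:, None, :] - ant.centers[None, :, :]
    return -(diff**2) / (2.0 * ant.widths[None, :, :])


def gaussian_membership(ant: AntecedentModel, X) -> np.ndarray:
    """Per-sample, per-rule, per-dimension memberships in (0, 1], (N, K, d).

    mu_{A_i^k}(x_i) = exp(-(x_i - c_i^k)^2 / (2 delta_i^k)).
    """
    X = _as_feature_matrix(X)
    if X.shape[1] != ant.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model d={ant.n_features}"
        )
    return np.exp(_log_memberships(ant, X))


def firing_strengths(ant: AntecedentModel, X) -> np.ndarray:
    """Normalized firing strengths mu~^k(x), shape (N, K), rows sum to 1.

    The raw firing strength of rule k is the product over input dimensions
    of the Gaussian memberships; normalization is carried out in log space
    so samples far from every rule center still receive well-defined
    relative weights.  Any residual non-finite row falls back to uniform
    1/K with a warning.
    """
    X = _as_feature_matrix(X)
    if X.shape[1] != ant.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model d={ant.n_features}"
        )
    log_mu = _log_memberships(ant, X).sum(axis=2)  # (N, K)
    norm = np.exp(log_mu - logsumexp(log_mu, axis=1, keepdims=True))
    bad = ~np.isfinite(norm).all(axis=1)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} sample(s) had no computable firing strength; "
            "falling back to uniform rule weights",
            RuntimeWarning,
            stacklevel=2,
        )
        norm[bad] = 1.0 / ant.n_rules
    return norm


def build_design(ant: AntecedentModel, X) -> np.ndarray:
    """Fuzzy design matrix X_g, shape (K(d+1), N): one column per sample.

    The column for sample x concatenates over rules k the block
    mu~^k(x) * (1, x_1, ..., x_d)^T, so the TSK output becomes the linear
    form p_g^T x_g.
    """
    X = _as_feature_matrix(X)
    mu = firing_strengths(ant, X)  # (N, K)
    xe = np.hstack([np.ones((X.shape[0], 1)), X])  # (N, d+1)
    # (N, K, d+1) -> (N, K(d+1)) -> transpose to column-per-sample
    blocks = mu[:, :, None] * xe[:, None, :]
    return blocks.reshape(X.shape[0], -1).T
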