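"""Joint-distribution adaptation: pseudo-labels, MMD matrices, diagnostics.

The transfer penalty measures the projected maximum mean discrepancy (MMD)
between source and target samples under the fitted consequent projection p:
the marginal term compares the two domain means of p^T x_g, and one
conditional term per class compares the class-conditional means, with target
class assignments supplied by a pseudo-labeller trained on the source.  Each
term is a quadratic form tr(p^T X M_c X^T p) where M_c is the outer product
of one signed indicator vector over the pooled (source-then-target) sample
axis, so every M_c is symmetric PSD and annihilates constant vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "MMDSpec",
    "TransferDiagnostics",
    "default_pseudo_labeller",
    "pseudo_label",
    "build_mmd_matrix",
    "transfer_diagnostics",
]


def _check_pm1(labels, name: str) -> np.ndarray:
    labels = np.asarray(labels, dtype=float).ravel()
    if labels.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isin(labels, (-1.0, 1.0))):
        raise ValueError(f"{name} must contain only +1/-1")
    return labels


def default_pseudo_labeller():
    """Linear-kernel SVM with unit cost — the default target pseudo-labeller."""
    return SVC(kernel="linear", C=1.0)


def pseudo_label(source_features, source_labels, target_features, base=None) -> np.ndarray:
    """Target pseudo-labels from a base classifier trained on the source.

    ``base`` is any estimator with ``fit``/``predict`` (default: linear SVM).
    Raw features, not the fuzzy design space, are used by convention; pass
    design columns transposed if design-space labelling is wanted.
    """
    y = _check_pm1(source_labels, "source labels")
    Xs = np.asarray(source_features, dtype=float)
    Xt = np.asarray(target_features, dtype=float)
    if base is None:
        base = default_pseudo_labeller()
    if np.unique(y).size == 1:
        # no contrary evidence: every target sample inherits the one class
        return np.full(Xt.shape[0], y[0])
    try:
        base.fit(Xs, y)
        pred = np.asarray(base.predict(Xt), dtype=float).ravel()
    except Exception as exc:  # pragma: no cover - propagated with context
        raise RuntimeError(f"pseudo-labelling base classifier failed: {exc}") from exc
    return pred


@dataclass(frozen=True)
class MMDSpec:
    """Assembled MMD matrices over the pooled source+target sample axis.

    ``M0`` is the marginal matrix (entries 1/n^2, 1/m^2, -1/(nm)); ``Mc``
    maps each class label to its conditional matrix built from true source
    labels and target pseudo-labels; ``M = M0 + sum_c Mc``, symmetrized.
    Classes empty on either side contribute a zero matrix and are excluded
    from ``classes_used``.
    """

    n_source: int
    n_target: int
    M0: np.ndarray
    Mc: dict
    M: np.ndarray
    classes_used: tuple = ()

    @property
    def n_total(self) -> int:
        return self.n_source + self.n_target


def build_mmd_matrix(labels_source, pseudo_target) -> MMDSpec:
    """Marginal + per-class conditional MMD matrices for pooled samples.

    Pooled index order is all n source samples then all m target samples.
    Each matrix is the outer product v v^T of a signed indicator: for the
    marginal term v = (1/n,...,1/n, -1/m,...,-1/m); for class c, v has
    1/n^(c) on source members of c, -1/m^(c) on (pseudo-)target members of
    c, zero elsewhere.  A class absent from either side yields a zero
    matrix with a warning.
    """
    ys = _check_pm1(labels_source, "source labels")
    yt = _check_pm1(pseudo_target, "target pseudo-labels")
    n, m = ys.size, yt.size
    # entries written by case (not as outer products) so each value is the
    # exact quotient 1/n^2, 1/m^2, -1/(nm) etc. without extra rounding
    M0 = np.empty((n + m, n + m))
    M0[:n, :n] = 1.0 / n**2
    M0[n:, n:] = 1.0 / m**2
    M0[:n, n:] = M0[n:, :n] = -1.0 / (n * m)
    M = M0.copy()
    Mc = {}
    used = []
    for c in (1.0, -1.0):
        src_idx = np.flatnonzero(ys == c)
        tgt_idx = n + np.flatnonzero(yt == c)
        nc, mc = src_idx.size, tgt_idx.size
        if nc == 0 or mc == 0:
            warnings.warn(
                f"class {int(c):+d} empty on one side (n^(c)={nc}, m^(c)={mc}); "
                "its conditional MMD term is zero",
                RuntimeWarning,
                stacklevel=2,
            )
            Mc[c] = np.zeros((n + m, n + m))
            continue
        Mk = np.zeros((n + m, n + m))
        Mk[np.ix_(src_idx, src_idx)] = 1.0 / (nc * nc)
        Mk[np.ix_(tgt_idx, tgt_idx)] = 1.0 / (mc * mc)
        Mk[np.ix_(src_idx, tgt_idx)] = Mk[np.ix_(tgt_idx, src_idx)] = -1.0 / (nc * mc)
        Mc[c] = Mk
        M += Mk
        used.append(c)
    M = 0.5 * (M + M.T)  # defensive; exactly symmetric by construction
    return MMDSpec(n_source=n, n_target=m, M0=M0, Mc=Mc, M=M, classes_used=tuple(used))


@dataclass(frozen=True)
class TransferDiagnostics:
    """Projected distribution distances at a fitted consequent vector.

    marginal      D(Ps,Pt): squared gap of domain means of p^T x_g
    conditional   per-class D^(c)(Qs,Qt)
    joint         D(Js,Jt) = marginal + sum_c conditional
    knowledge     ||p0 - p||^2
    total_transfer joint + lambda3 * knowledge
    """

    marginal: float
    conditional_per_class: dict
    joint: float
    knowledge: float
    total_transfer: float

    def to_dict(self) -> dict:
        return {
            "marginal": self.marginal,
            "conditional_per_class": {
                f"{int(c):+d}": v for c, v in self.conditional_per_class.items()
            },
            "joint": self.joint,
            "knowledge": self.knowledge,
            "total_transfer": self.total_transfer,
        }


def transfer_diagnostics(
    p,
    Xg_source,
    Xg_target,
    labels_source,
    pseudo_target,
    p0,
    lambda3: float = 1.0,
    mmd: MMDSpec | None = None,
) -> TransferDiagnostics:
    """Mean-difference distribution distances, cross-checked against trace form.

    Each distance is computed directly from empirical means of the projected
    samples; when ``mmd`` is given (or rebuilt here) the joint distance is
    verified against tr(p^T X M X^T p) to 1e-8, a consistency guard on the
    assembled matrices.
    """
    p = np.asarray(p, dtype=float).ravel()
    p0 = np.asarray(p0, dtype=float).ravel()
    Xs = np.asarray(Xg_source, dtype=float)
    Xt = np.asarray(Xg_target, dtype=float)
    ys = _check_pm1(labels_source, "source labels")
    yt = _check_pm1(pseudo_target, "target pseudo-labels")
    proj_s = p @ Xs
    proj_t = p @ Xt
    marginal = float((proj_s.mean() - proj_t.mean()) ** 2)
    conditional = {}
    for c in (1.0, -1.0):
        sc = proj_s[ys == c]
        tc = proj_t[yt == c]
        if sc.size == 0 or tc.size == 0:
            warnings.warn(
                f"class {int(c):+d} empty on one side; conditional distance set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            conditional[c] = 0.0
        else:
            conditional[c] = float((sc.mean() - tc.mean()) ** 2)
    joint = marginal + sum(conditional.values())
    if mmd is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mmd = build_mmd_matrix(ys, yt)
    proj_all = np.concatenate([proj_s, proj_t])
    trace_form = float(proj_all @ mmd.M @ proj_all)
    if abs(trace_form - joint) > 1e-8 * max(1.0, abs(joint)):
        raise AssertionError(
            f"trace identity violated: mean-difference {joint} vs trace {trace_form}"
        )
    diff = p0 - p
    knowledge = float(diff @ diff)
    return TransferDiagnostics(
        marginal=marginal,
        conditional_per_class=conditional,
        joint=joint,
        knowledge=knowledge,
        total_transfer=joint + lambda3 * knowledge,
    )
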