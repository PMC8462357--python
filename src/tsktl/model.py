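"""Model/Results objects for the classic and transfer TSK fuzzy classifiers.

Two model classes in the statsmodels mould:

``TSKClassifier``
    the classic TSK-FS: fuzzy c-means antecedents on the training features,
    ridge-regularized closed-form consequents fitted to the ±1 labels.

``TSKTransferClassifier``
    the transfer variant (TSK-TL) for a labelled source domain plus an
    unlabelled target domain: it augments the classic objective with a
    projected-MMD joint-distribution penalty (marginal + per-class
    conditional, the target side classed by pseudo-labels) and a knowledge
    term shrinking toward the classic source-only consequents.

Both expose ``fit(...) -> Results`` where the Results object carries the
consequent estimates, diagnostics, prediction methods and a ``summary()``
table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import solvers
from .adaptation import build_mmd_matrix, pseudo_label, transfer_diagnostics
from .antecedent import (
    AntecedentModel,
    build_design,
    estimate_antecedent,
    fcm_partition,
)

__all__ = ["TSKClassifier", "TSKResults", "TSKTransferClassifier", "TSKTransferResults"]


def _zscore_params(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


class _TSKBase:
    """Shared antecedent plumbing."""

    def __init__(self, n_rules, h, fuzzifier, normalize, seed, fcm_tol, fcm_max_iter):
        if n_rules < 1:
            raise ValueError("n_rules must be >= 1")
        self.n_rules = int(n_rules)
        self.h = float(h)
        self.fuzzifier = float(fuzzifier)
        self.normalize = bool(normalize)
        self.seed = int(seed)
        self.fcm_tol = float(fcm_tol)
        self.fcm_max_iter = int(fcm_max_iter)
        self._norm_mu = None
        self._norm_sd = None

    def _maybe_normalize(self, X, fit: bool):
        X = np.asarray(X, dtype=float)
        if not self.normalize:
            return X
        if fit:
            self._norm_mu, self._norm_sd = _zscore_params(X)
        return (X - self._norm_mu) / self._norm_sd

    def _learn_antecedent(self, X) -> AntecedentModel:
        part = fcm_partition(
            X,
            self.n_rules,
            fuzzifier=self.fuzzifier,
            tol=self.fcm_tol,
            max_iter=self.fcm_max_iter,
            seed=self.seed,
        )
        return estimate_antecedent(X, part, h=self.h)


class TSKClassifier(_TSKBase):
    """Classic TSK fuzzy-system binary classifier.

    Parameters
    ----------
    X : array-like, (N, d)
        Training features.
    y : array-like, (N,)
        Labels in {+1, -1} (+1 "healthy", -1 "epileptic" in the EEG setting).
    n_rules : int
        Number of fuzzy rules K (one per fuzzy c-means cluster).
    h : float
        Scale factor on the estimated squared widths.
    fuzzifier : float
        Fuzzy c-means exponent (> 1).
    normalize : bool
        Z-score features before clustering/design construction.
    """

    def __init__(self, X, y, n_rules=5, h=1.0, fuzzifier=2.0, normalize=False,
                 seed=0, fcm_tol=1e-6, fcm_max_iter=300):
        super().__init__(n_rules, h, fuzzifier, normalize, seed, fcm_tol, fcm_max_iter)
        self.exog = np.asarray(X, dtype=float)
        self.endog = np.asarray(y, dtype=float).ravel()
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("X and y disagree on sample count")
        if not np.all(np.isin(self.endog, (-1.0, 1.0))):
            raise ValueError("labels must be +1/-1")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label", **kwargs):
        y = df[label_col].to_numpy()
        X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        return cls(X, y, **kwargs)

    def fit(self, lambda1: float = 1.0) -> "TSKResults":
        Xn = self._maybe_normalize(self.exog, fit=True)
        ant = self._learn_antecedent(Xn)
        Xg = build_design(ant, Xn)
        p = solvers.fit_tsk_fs(Xg, self.endog, lambda1)
        return TSKResults(self, ant, p, lambda1)


@dataclass
class _ResultsCommon:
    def _design_for(self, X):
        Xn = self.model._maybe_normalize(np.asarray(X, dtype=float), fit=False)
        return build_design(self.antecedent, Xn)

    def decision_function(self, X) -> np.ndarray:
        """Real-valued TSK outputs p_g^T x_g for new samples."""
        return solvers.decision_values(self.params, self._design_for(X))

    def predict(self, X) -> np.ndarray:
        """Hard ±1 predictions (sign of the decision value; 0 maps to +1)."""
        return solvers.predict_labels(self.params, self._design_for(X))

    def score(self, X, y_true) -> float:
        """Accuracy: fraction of correct ±1 predictions."""
        y_true = np.asarray(y_true, dtype=float).ravel()
        return float((self.predict(X) == y_true).mean())


@dataclass
class TSKResults(_ResultsCommon):
    """Fit results of the classic TSK-FS."""

    model: TSKClassifier
    antecedent: AntecedentModel
    params: np.ndarray
    lambda1: float

    def __init__(self, model, antecedent, params, lambda1):
        self.model = model
        self.antecedent = antecedent
        self.params = np.asarray(params, dtype=float)
        self.lambda1 = float(lambda1)

    @property
    def objective(self) -> float:
        Xg = self._design_for(self.model.exog)
        return solvers.tsk_fs_objective(self.params, Xg, self.model.endog, self.lambda1)

    def summary(self) -> str:
        lines = [
            "TSK fuzzy-system classifier (classic)",
            "=" * 48,
            f"rules (K):            {self.antecedent.n_rules}",
            f"features (d):         {self.antecedent.n_features}",
            f"scale h:              {self.antecedent.h:g}",
            f"lambda1:              {self.lambda1:g}",
            f"training samples:     {self.model.endog.size}",
            f"objective J_FS:       {self.objective:.6g}",
            f"training accuracy:    {self.score(self.model.exog, self.model.endog):.4f}",
            "",
            _consequent_table(self.antecedent, self.params),
        ]
        return "\n".join(lines)


class TSKTransferClassifier(_TSKBase):
    """TSK transfer-learning classifier (TSK-TL) for source→target shift.

    The antecedent space is shared between domains: by default fuzzy
    c-means runs on the pooled source+target features (``antecedent_data=
    "pooled"``, unsupervised and transductive); ``"source"`` restricts it
    to the source.  Pseudo-labels for the target's conditional MMD terms
    come from ``pseudo_labeller`` (default: linear SVM, unit cost) trained
    on raw source features (``pseudo_space="raw"``; ``"design"`` uses the
    fuzzy design space instead).
    """

    def __init__(self, X_source, y_source, X_target, n_rules=5, h=1.0,
                 fuzzifier=2.0, normalize=False, seed=0,
                 antecedent_data="pooled", pseudo_labeller=None,
                 pseudo_space="raw", fcm_tol=1e-6, fcm_max_iter=300):
        super().__init__(n_rules, h, fuzzifier, normalize, seed, fcm_tol, fcm_max_iter)
        if antecedent_data not in ("pooled", "source"):
            raise ValueError("antecedent_data must be 'pooled' or 'source'")
        if pseudo_space not in ("raw", "design"):
            raise ValueError("pseudo_space must be 'raw' or 'design'")
        self.exog = np.asarray(X_source, dtype=float)
        self.endog = np.asarray(y_source, dtype=float).ravel()
        self.exog_target = np.asarray(X_target, dtype=float)
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("source X and y disagree on sample count")
        if self.exog.shape[1] != self.exog_target.shape[1]:
            raise ValueError("source and target feature dimensions differ")
        if not np.all(np.isin(self.endog, (-1.0, 1.0))):
            raise ValueError("labels must be +1/-1")
        self.antecedent_data = antecedent_data
        self.pseudo_labeller = pseudo_labeller
        self.pseudo_space = pseudo_space

    @classmethod
    def from_dataframes(cls, source: pd.DataFrame, target: pd.DataFrame,
                        label_col: str = "label", **kwargs):
        y = source[label_col].to_numpy()
        Xs = source.drop(columns=[label_col]).to_numpy(dtype=float)
        Xt = target.drop(columns=[label_col], errors="ignore").to_numpy(dtype=float)
        return cls(Xs, y, Xt, **kwargs)

    def fit(self, lambda1: float = 1.0, lambda2: float = 1.0, lambda3: float = 1.0,
            refine_iterations: int = 1, literal_form: bool = False) -> "TSKTransferResults":
        if refine_iterations < 1:
            raise ValueError("refine_iterations must be >= 1")
        pooled = np.vstack([self.exog, self.exog_target])
        if self.normalize:
            self._norm_mu, self._norm_sd = _zscore_params(pooled)
        Xs = self._maybe_normalize(self.exog, fit=False)
        Xt = self._maybe_normalize(self.exog_target, fit=False)
        ant_X = np.vstack([Xs, Xt]) if self.antecedent_data == "pooled" else Xs
        ant = self._learn_antecedent(ant_X)
        Xg_s = build_design(ant, Xs)
        Xg_t = build_design(ant, Xt)
        Xg_all = np.hstack([Xg_s, Xg_t])

        p0 = solvers.fit_tsk_fs(Xg_s, self.endog, lambda1)

        if self.pseudo_space == "raw":
            pseudo = pseudo_label(Xs, self.endog, Xt, base=self.pseudo_labeller)
        else:
            pseudo = pseudo_label(Xg_s.T, self.endog, Xg_t.T, base=self.pseudo_labeller)

        p = p0
        mmd = None
        for it in range(refine_iterations):
            mmd = build_mmd_matrix(self.endog, pseudo)
            p = solvers.fit_tsk_tl(
                Xg_s, self.endog, Xg_all, mmd.M, p0,
                lambda1, lambda2, lambda3, literal_form=literal_form,
            )
            if it + 1 < refine_iterations:
                # iterated variant: re-label the target with the current fit
                pseudo = solvers.predict_labels(p, Xg_t)
        # reported pseudo-labels are the ones that built the final M
        return TSKTransferResults(
            self, ant, p, p0, lambda1, lambda2, lambda3,
            pseudo_labels=pseudo, mmd=mmd, literal_form=literal_form,
            design_source=Xg_s, design_target=Xg_t,
        )


class TSKTransferResults(_ResultsCommon):
    """Fit results of the transfer TSK classifier."""

    def __init__(self, model, antecedent, params, params_historical,
                 lambda1, lambda2, lambda3, pseudo_labels, mmd,
                 literal_form, design_source, design_target):
        self.model = model
        self.antecedent = antecedent
        self.params = np.asarray(params, dtype=float)
        self.params_historical = np.asarray(params_historical, dtype=float)
        self.lambda1 = float(lambda1)
        self.lambda2 = float(lambda2)
        self.lambda3 = float(lambda3)
        self.pseudo_labels = np.asarray(pseudo_labels, dtype=float)
        self.mmd = mmd
        self.literal_form = bool(literal_form)
        self._Xg_s = design_source
        self._Xg_t = design_target

    @property
    def objective(self) -> float:
        Xg_all = np.hstack([self._Xg_s, self._Xg_t])
        return solvers.tsk_tl_objective(
            self.params, self._Xg_s, self.model.endog, Xg_all, self.mmd.M,
            self.params_historical, self.lambda1, self.lambda2, self.lambda3,
        )

    @property
    def diagnostics(self):
        """Projected distribution distances at the fitted consequents."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return transfer_diagnostics(
                self.params, self._Xg_s, self._Xg_t, self.model.endog,
                self.pseudo_labels, self.params_historical,
                lambda3=self.lambda3, mmd=None,
            )

    def predict_target(self) -> np.ndarray:
        """Hard ±1 predictions on the (training-time) target domain."""
        return solvers.predict_labels(self.params, self._Xg_t)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "TSK transfer-learning fuzzy classifier (TSK-TL)",
            "=" * 48,
            f"rules (K):            {self.antecedent.n_rules}",
            f"features (d):         {self.antecedent.n_features}",
            f"scale h:              {self.antecedent.h:g}",
            f"lambda1/2/3:          {self.lambda1:g} / {self.lambda2:g} / {self.lambda3:g}",
            f"source samples (n):   {self.model.endog.size}",
            f"target samples (m):   {self.model.exog_target.shape[0]}",
            f"solver form:          {'literal (compatibility)' if self.literal_form else 'stationary point'}",
            f"objective J_TL:       {self.objective:.6g}",
            f"marginal distance:    {d.marginal:.6g}",
            f"joint distance:       {d.joint:.6g}",
            f"knowledge distance:   {d.knowledge:.6g}",
            f"source accuracy:      {self.score(self.model.exog, self.model.endog):.4f}",
            "",
            _consequent_table(self.antecedent, self.params),
        ]
        return "\n".join(lines)


def _consequent_table(ant: AntecedentModel, params: np.ndarray) -> str:
    """Per-rule consequent coefficients as a compact table."""
    d = ant.n_features
    rows = []
    header = "rule  " + "  ".join(f"p_{i:<2d}" for i in range(d + 1))
    rows.append(header)
    rows.append("-" * len(header))
    blocks = params.reshape(ant.n_rules, d + 1)
    for k, blk in enumerate(blocks, 1):
        rows.append(f"R{k:<4d}" + "  ".join(f"{v: .3f}" for v in blk))
    return "\n".join(rows)
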