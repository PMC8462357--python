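"""Benchmark harness: repeated trials, grid search, Friedman + Holm ranks.

The nonparametric comparison follows the standard protocol for comparing k
classifiers over N datasets: per-dataset ranks (1 = most accurate, ties get
the average of the tied positions), Friedman's chi-square

    chi2_F = 12 N / (k (k+1)) * sum_j R_j^2  -  3 N (k+1)

on k-1 degrees of freedom (with the Iman-Davenport F refinement also
reported), and Holm's step-down post hoc comparing every method to a
control at Z = (R_method - R_control) / SE, SE = sqrt(k (k+1) / (6 N)),
with thresholds alpha/i from the largest Z down.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import TSKClassifier, TSKTransferClassifier

__all__ = [
    "AccuracyTable",
    "RankAnalysis",
    "run_trials",
    "grid_search",
    "rank_table",
    "friedman_test",
    "holm_posthoc",
]


@dataclass
class AccuracyTable:
    """Mean (and optional SD) accuracy of k methods over N datasets.

    ``mean``/``sd`` are DataFrames indexed by dataset with one column per
    method; accuracies live in [0, 1].
    """

    mean: pd.DataFrame
    sd: pd.DataFrame | None = None

    def __post_init__(self):
        if self.mean.shape[1] < 2 or self.mean.shape[0] < 2:
            raise ValueError("need at least 2 methods and 2 datasets")
        vals = self.mean.to_numpy(dtype=float)
        # NaN cells are allowed here (failed trials); rank_table refuses them
        ok = vals[~np.isnan(vals)]
        if (ok < 0).any() or (ok > 1).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def methods(self):
        return list(self.mean.columns)

    @property
    def datasets(self):
        return list(self.mean.index)

    def to_csv(self, path):
        """Methods as rows, datasets as columns."""
        self.mean.T.to_csv(path)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path, index_col=0)
        return cls(mean=df.T)


@dataclass
class RankAnalysis:
    """Per-dataset ranks, average ranks, Friedman statistics, Holm ladder."""

    ranks: pd.DataFrame  # datasets x methods, 1 = best
    avg_ranks: pd.Series  # per method
    n_methods: int
    n_datasets: int
    friedman_chi2: float | None = None
    friedman_p: float | None = None
    iman_davenport_f: float | None = None
    iman_davenport_p: float | None = None
    holm_ladder: pd.DataFrame | None = None

    @property
    def se(self) -> float:
        k, N = self.n_methods, self.n_datasets
        return float(np.sqrt(k * (k + 1) / (6.0 * N)))


def rank_table(acc: AccuracyTable) -> RankAnalysis:
    """Per-dataset descending-accuracy ranks with average-rank tie handling."""
    vals = acc.mean.to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = [
            f"({acc.mean.index[i]}, {acc.mean.columns[j]})"
            for i, j in zip(*np.where(np.isnan(vals)))
        ]
        raise ValueError(f"missing accuracy cells: {', '.join(bad)}")
    # rankdata ranks ascending; negate so the most accurate method gets rank 1
    ranks = np.vstack([stats.rankdata(-row, method="average") for row in vals])
    rdf = pd.DataFrame(ranks, index=acc.mean.index, columns=acc.mean.columns)
    return RankAnalysis(
        ranks=rdf,
        avg_ranks=rdf.mean(axis=0),
        n_methods=rdf.shape[1],
        n_datasets=rdf.shape[0],
    )


def friedman_test(ra: RankAnalysis) -> RankAnalysis:
    """Friedman chi-square (+ Iman-Davenport F) from the computed ranks."""
    k, N = ra.n_methods, ra.n_datasets
    if N < 2:
        raise ValueError("Friedman test needs at least 2 datasets")
    R = ra.avg_ranks.to_numpy()
    chi2 = 12.0 * N / (k * (k + 1)) * float((R**2).sum()) - 3.0 * N * (k + 1)
    p_chi2 = float(stats.chi2.sf(chi2, k - 1))
    denom = N * (k - 1) - chi2
    if denom > 0:
        f_stat = (N - 1) * chi2 / denom
        p_f = float(stats.f.sf(f_stat, k - 1, (k - 1) * (N - 1)))
    else:  # chi2 at (or beyond) its maximum: F diverges, p -> 0
        f_stat, p_f = float("inf"), 0.0
    ra.friedman_chi2 = float(chi2)
    ra.friedman_p = p_chi2
    ra.iman_davenport_f = float(f_stat)
    ra.iman_davenport_p = p_f
    return ra


def holm_posthoc(ra: RankAnalysis, control: str | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Holm step-down ladder of every method against the control.

    ``control`` defaults to the method with the best (lowest) average rank.
    Rows are ordered by descending Z (i = k-1 down to 1); ``reject`` applies
    Holm's rule: step down from the largest Z, stopping at the first
    non-significant comparison.
    """
    if control is None:
        control = ra.avg_ranks.idxmin()
    if control not in ra.avg_ranks.index:
        raise ValueError(f"control method {control!r} not in the table")
    se = ra.se
    r0 = float(ra.avg_ranks[control])
    rows = []
    for method, r in ra.avg_ranks.items():
        if method == control:
            continue
        z = (float(r) - r0) / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append({"method": method, "z": z, "p": p})
    ladder = pd.DataFrame(rows).sort_values("z", ascending=False, kind="stable")
    ladder["i"] = np.arange(len(ladder), 0, -1)
    ladder["threshold"] = alpha / ladder["i"]
    reject, still = [], True
    for _, row in ladder.iterrows():
        still = still and (row["p"] <= row["threshold"])
        reject.append(still)
    ladder["reject"] = reject
    ladder = ladder.set_index("i")[["method", "z", "p", "threshold", "reject"]]
    ra.holm_ladder = ladder
    return ladder


def run_trials(tasks: dict, methods: dict, repeats: int = 10, seed: int = 0) -> AccuracyTable:
    """Repeated-trial accuracy table.

    ``tasks`` maps dataset name -> task payload (whatever the methods
    consume; typically a ShiftScenario or a (source, target, y_true)
    triple).  ``methods`` maps method name -> callable
    ``(task, seed) -> accuracy in [0, 1]``.  Each repeat receives its own
    derived seed; a crashing method leaves NaN cells and the exception is
    recorded on the returned table as ``failures``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    names = list(tasks)
    mean = pd.DataFrame(index=names, columns=list(methods), dtype=float)
    sd = pd.DataFrame(index=names, columns=list(methods), dtype=float)
    failures = {}
    ss = np.random.SeedSequence(seed)
    trial_seeds = [int(s) for s in ss.generate_state(repeats)]
    trial_seeds = [s % (2**31 - 1) for s in trial_seeds]
    for dname, task in tasks.items():
        for mname, fn in methods.items():
            accs = []
            for r, rs in enumerate(trial_seeds):
                try:
                    accs.append(float(fn(task, rs)))
                except Exception as exc:
                    failures[(dname, mname, r)] = repr(exc)
            if accs:
                mean.loc[dname, mname] = float(np.mean(accs))
                sd.loc[dname, mname] = float(np.std(accs, ddof=0))
    if failures:
        warnings.warn(f"{len(failures)} trial(s) failed: {failures}", RuntimeWarning)
    table = AccuracyTable(mean=mean, sd=sd)
    table.failures = failures
    table.seeds = trial_seeds
    return table


def grid_search(
    X_source,
    y_source,
    X_target,
    y_target_true=None,
    rule_grid=(5, 10, 15, 20, 25, 30),
    lambda1_grid=tuple(10.0**e for e in range(-5, 6)),
    lambda2_grid=(0.0,),
    lambda3_grid=(0.0,),
    selection: str = "oracle",
    transfer: bool = True,
    seed: int = 0,
    cv_folds: int = 5,
    **model_kwargs,
):
    """Exhaustive hyperparameter search for the classic or transfer model.

    selection='oracle' scores each cell by true-target accuracy (requires
    ``y_target_true``; the customary benchmark protocol, optimistic by
    construction).  selection='source_cv' scores by k-fold source
    cross-validation accuracy, never touching target labels.  Returns
    ``(best_params_dict, best_results, log)`` where ``log`` is a DataFrame
    with one row per visited cell.
    """
    if selection not in ("oracle", "source_cv"):
        raise ValueError("selection must be 'oracle' or 'source_cv'")
    if selection == "oracle" and y_target_true is None:
        raise ValueError("oracle selection needs y_target_true")
    y_source = np.asarray(y_source, dtype=float).ravel()
    if not transfer:
        lambda2_grid, lambda3_grid = (0.0,), (0.0,)
    cells = list(itertools.product(rule_grid, lambda1_grid, lambda2_grid, lambda3_grid))
    if not cells:
        raise ValueError("empty hyperparameter grid")
    rows, best = [], None
    for K, l1, l2, l3 in cells:
        try:
            if transfer:
                mod = TSKTransferClassifier(X_source, y_source, X_target,
                                            n_rules=K, seed=seed, **model_kwargs)
                res = mod.fit(lambda1=l1, lambda2=l2, lambda3=l3)
            else:
                mod = TSKClassifier(X_source, y_source, n_rules=K, seed=seed, **model_kwargs)
                res = mod.fit(lambda1=l1)
            score = _selection_score(res, X_source, y_source, X_target,
                                     y_target_true, selection, seed, cv_folds,
                                     transfer, K, l1, l2, l3, model_kwargs)
        except Exception as exc:
            rows.append({"K": K, "lambda1": l1, "lambda2": l2, "lambda3": l3,
                         "score": np.nan, "error": repr(exc)})
            continue
        rows.append({"K": K, "lambda1": l1, "lambda2": l2, "lambda3": l3,
                     "score": score, "error": ""})
        if best is None or score > best[0]:
            best = (score, {"K": K, "lambda1": l1, "lambda2": l2, "lambda3": l3}, res)
    log = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("every grid cell failed")
    return best[1], best[2], log


def _selection_score(res, Xs, ys, Xt, yt_true, selection, seed, cv_folds,
                     transfer, K, l1, l2, l3, model_kwargs):
    if selection == "oracle":
        if transfer:
            yt_true = np.asarray(yt_true, dtype=float).ravel()
            return float((res.predict_target() == yt_true).mean())
        return res.score(Xt, yt_true)
    # source_cv: refit per fold on source only
    from sklearn.model_selection import StratifiedKFold

    Xs = np.asarray(Xs, dtype=float)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(Xs, ys):
        if np.unique(ys[tr]).size < 2 or min(np.bincount((ys[tr] > 0).astype(int))) < 1:
            continue
        try:
            if transfer:
                m = TSKTransferClassifier(Xs[tr], ys[tr], Xs[te],
                                          n_rules=min(K, len(tr)), seed=seed, **model_kwargs)
                r = m.fit(lambda1=l1, lambda2=l2, lambda3=l3)
                accs.append(float((r.predict_target() == ys[te]).mean()))
            else:
                m = TSKClassifier(Xs[tr], ys[tr], n_rules=min(K, len(tr)), seed=seed,
                                  **model_kwargs)
                accs.append(m.fit(lambda1=l1).score(Xs[te], ys[te]))
        except Exception:
            continue
    if not accs:
        raise RuntimeError("source_cv selection: every fold failed")
    return float(np.mean(accs))
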