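"""Linguistic rule export: render a fitted TSK model as IF-THEN rules.

Each fuzzy set gets an ordered linguistic label per input dimension by
sorting the rule centers in that dimension from low to high.  With exactly
five rules the conventional label set {Low, A little low, Medium,
A little high, High} is used; any other rule count falls back to the
generic "level j of K".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RuleReport", "export_rules", "FIVE_LEVEL_LABELS"]

FIVE_LEVEL_LABELS = ("Low", "A little low", "Medium", "A little high", "High")


@dataclass(frozen=True)
class RuleReport:
    """One entry per rule: linguistic labels, parameters, rendered text."""

    labels: list  # per rule: list of d linguistic labels
    centers: np.ndarray  # (K, d)
    widths: np.ndarray  # (K, d)
    consequents: np.ndarray  # (K, d+1)
    text: list  # per rule: rendered IF/THEN string

    def __str__(self) -> str:
        return "\n\n".join(self.text)

    def to_dict(self) -> dict:
        return {
            "rules": [
                {
                    "labels": self.labels[k],
                    "centers": self.centers[k].tolist(),
                    "widths": self.widths[k].tolist(),
                    "consequent": self.consequents[k].tolist(),
                    "text": self.text[k],
                }
                for k in range(len(self.labels))
            ]
        }


def _level_labels(K: int):
    if K == 5:
        return FIVE_LEVEL_LABELS
    return tuple(f"level {j + 1} of {K}" for j in range(K))


def export_rules(results) -> RuleReport:
    """Linguistic rule base of a fitted classifier (any Results object).

    Label assignment is per dimension: rules sorted by ascending center
    value receive the ordered level labels; equal centers are tie-broken by
    rule index (lower rule index gets the lower level).
    """
    ant = results.antecedent
    K, d = ant.n_rules, ant.n_features
    params = np.asarray(results.params, dtype=float).reshape(K, d + 1)
    level = _level_labels(K)
    labels = [[None] * d for _ in range(K)]
    for i in range(d):
        order = np.argsort(ant.centers[:, i], kind="stable")  # ties -> rule index
        for pos, k in enumerate(order):
            labels[k][i] = level[pos]
    text = []
    for k in range(K):
        conds = " and ".join(
            f"x{i + 1} is {labels[k][i]} "
            f"(c={ant.centers[k, i]:.4g}, delta={ant.widths[k, i]:.4g})"
            for i in range(d)
        )
        terms = " ".join(
            f"{params[k, i + 1]:+.4g}*x{i + 1}" for i in range(d)
        )
        text.append(
            f"Rule R{k + 1}: IF {conds}\n"
            f"  THEN f{k + 1}(x) = {params[k, 0]:.4g} {terms}"
        )
    return RuleReport(
        labels=labels,
        centers=ant.centers.copy(),
        widths=ant.widths.copy(),
        consequents=params,
        text=text,
    )
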