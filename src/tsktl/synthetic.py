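"""Synthetic source/target classification problems with distribution shift.

The generator emulates post-feature-extraction EEG vectors: low-dimensional
(default d=6) class-conditional Gaussian clusters, one labelled source
domain and one unlabelled target domain whose clusters are translated by a
controllable marginal shift (applied to every target sample) plus per-class
conditional shifts.  True target labels are returned separately and are
never consumed by any fitting routine — they exist for oracle evaluation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["ShiftScenario", "LabeledDomain", "generate_shift_pair", "generate_fixture_suite"]


@dataclass(frozen=True)
class LabeledDomain:
    """Feature matrix with ±1 labels for one domain."""

    features: np.ndarray  # (N, d)
    labels: np.ndarray  # (N,), values in {+1, -1}
    role: str = "source"  # source | target
    pseudo: bool = False  # labels are pseudo-labels, not ground truth

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("label count must equal sample count")
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must be +1/-1")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)


def _shift_vector(value, d: int, direction: np.ndarray) -> np.ndarray:
    """A scalar shift is a magnitude along ``direction``; arrays pass through."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return float(arr) * direction
    if arr.shape != (d,):
        raise ValueError(f"shift vector must have length {d}")
    return arr


@dataclass(frozen=True)
class ShiftScenario:
    """Parameters of one source→target drift scenario.

    separation is the Euclidean distance between the two source class means
    (placed symmetrically along the first axis).  marginal_shift translates
    every target sample; conditional_shift adds an extra per-class
    translation with opposite directions for the two classes, creating a
    class-conditional (not just covariate) drift.  Scalars are magnitudes
    along fixed unit directions: the all-ones diagonal for the marginal
    shift, the second axis (±) for the conditional shifts.
    """

    d: int = 6
    n_source: int = 200
    n_target: int = 200
    class_balance: float = 0.5
    separation: float = 3.0
    marginal_shift: float | np.ndarray = 0.0
    conditional_shift: float | np.ndarray = 0.0
    noise_sd: float = 1.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_source < 4 or self.n_target < 4:
            raise ValueError("need at least 4 samples per domain")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie strictly in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.d < 1:
            raise ValueError("d must be >= 1")


def _sample_domain(rng, scenario: ShiftScenario, n: int, mean_pos, mean_neg):
    n_pos = int(round(n * scenario.class_balance))
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("scenario leaves one class with zero samples")
    X = np.vstack([
        mean_pos + scenario.noise_sd * rng.standard_normal((n_pos, scenario.d)),
        mean_neg + scenario.noise_sd * rng.standard_normal((n_neg, scenario.d)),
    ])
    y = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    if scenario.label_noise > 0:
        flip = rng.random(n) < scenario.label_noise
        y = np.where(flip, -y, y)
    perm = rng.permutation(n)
    return X[perm], y[perm]


def generate_shift_pair(scenario: ShiftScenario):
    """Draw one (source, target) pair; returns (source, target, true_target_labels).

    +1 plays the "healthy" class, -1 the "epileptic" class.  The target
    domain's true labels are hidden ground truth: they are returned as the
    third value (and mirrored in ``target.labels`` for convenience, with
    ``target.pseudo`` flagging that fitting code must never consume them) —
    only oracle evaluation and accuracy scoring may read them.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    e1 = np.zeros(s.d)
    e1[0] = 1.0
    diag = np.ones(s.d) / np.sqrt(s.d)
    e2 = np.zeros(s.d)
    e2[min(1, s.d - 1)] = 1.0

    mean_pos = +0.5 * s.separation * e1
    mean_neg = -0.5 * s.separation * e1
    Xs, ys = _sample_domain(rng, s, s.n_source, mean_pos, mean_neg)

    marg = _shift_vector(s.marginal_shift, s.d, diag)
    cond = _shift_vector(s.conditional_shift, s.d, e2)
    Xt, yt = _sample_domain(rng, s, s.n_target, mean_pos + marg + cond, mean_neg + marg - cond)

    source = LabeledDomain(Xs, ys, role="source")
    target = LabeledDomain(Xt, yt, role="target", pseudo=True)
    return source, target, yt.copy()


def generate_fixture_suite(seed: int = 0, out_dir=None) -> dict:
    """Small named instances used as worked examples across the package.

    Returns a dict name → instance description; with ``out_dir`` each
    fixture's arrays are written as CSV plus a JSON manifest.
    """
    rng = np.random.default_rng(seed)
    fixtures = {}

    fixtures["antecedent-2pt"] = {
        "params": {"h": 1.0},
        "X": np.array([[0.0], [2.0]]),
        "expected_center": 1.0,
        "expected_width": 1.0,
    }
    fixtures["mmd-1-1"] = {
        "params": {"labels_source": [1], "pseudo_target": [1]},
        "expected_M0": np.array([[1.0, -1.0], [-1.0, 1.0]]),
        "expected_Mc": np.array([[1.0, -1.0], [-1.0, 1.0]]),
    }
    X = rng.standard_normal((8, 2))
    fixtures["oracle-8x2"] = {
        "params": {"seed": int(seed), "K": 2},
        "X": X,
        "y": np.where(X[:, 0] > 0, 1.0, -1.0),
    }
    sep = ShiftScenario(d=2, n_source=12, n_target=12, separation=6.0, seed=seed)
    src, tgt, yt = generate_shift_pair(sep)
    fixtures["separable-12-12"] = {
        "params": {"scenario": asdict(sep) | {"marginal_shift": 0.0, "conditional_shift": 0.0}},
        "source_X": src.features,
        "source_y": src.labels,
        "target_X": tgt.features,
        "target_y_true": yt,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for name, fx in fixtures.items():
            files = {}
            for key, val in fx.items():
                if key == "params":
                    continue
                arr = np.atleast_2d(np.asarray(val, dtype=float))
                fname = f"{name}.{key}.csv"
                np.savetxt(out / fname, arr, delimiter=",")
                files[key] = fname
            manifest[name] = {"seed": int(seed), "params": _jsonable(fx["params"]), "files": files}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return fixtures


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
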