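"""File I/O: feature/label CSVs, model JSON documents, Bonn-format segments."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .antecedent import AntecedentModel

__all__ = [
    "read_features",
    "read_labels",
    "save_model",
    "load_model",
    "read_bonn_segments",
]

MODEL_FORMAT = "tsktl-model"
MODEL_VERSION = 1

#: group -> class label: healthy volunteers (A, B) are +1, epileptic (C, D, E) -1
BONN_GROUP_LABELS = {"A": 1.0, "B": 1.0, "C": -1.0, "D": -1.0, "E": -1.0}


def read_features(path, delimiter: str = ",", header: bool | None = None) -> np.ndarray:
    """Numeric feature matrix (samples x features) from delimited text.

    ``header=None`` sniffs: if the first row contains any non-numeric token
    it is treated as a header.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if header is None:
        tokens = [t.strip() for t in first.strip().split(delimiter)]
        header = not all(_is_number(t) for t in tokens if t)
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None)
    X = df.to_numpy(dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def read_labels(path, delimiter: str = ",", header: bool | None = None) -> np.ndarray:
    """±1 label vector from a one-column delimited file."""
    y = read_features(path, delimiter=delimiter, header=header).ravel()
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError(f"label file {path} must contain only +1/-1")
    return y


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def save_model(results, path) -> None:
    """Serialize a fitted classifier (Results object) to a JSON document."""
    ant: AntecedentModel = results.antecedent
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "provenance": "transfer" if hasattr(results, "params_historical") else "classic",
        "antecedent": ant.to_dict(),
        "consequent": np.asarray(results.params, dtype=float).tolist(),
        "hyperparams": {
            "lambda1": results.lambda1,
            "lambda2": getattr(results, "lambda2", None),
            "lambda3": getattr(results, "lambda3", None),
            "K": ant.n_rules,
            "h": ant.h,
            "fuzzifier": results.model.fuzzifier,
            "seed": results.model.seed,
        },
        "normalize": {
            "enabled": results.model.normalize,
            "mean": None if results.model._norm_mu is None else results.model._norm_mu.tolist(),
            "sd": None if results.model._norm_sd is None else results.model._norm_sd.tolist(),
        },
    }
    if hasattr(results, "params_historical"):
        doc["consequent_historical"] = results.params_historical.tolist()
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


class LoadedModel:
    """A deserialized classifier: enough state to score new samples."""

    def __init__(self, doc: dict):
        if doc.get("format") != MODEL_FORMAT:
            raise ValueError("not a recognised model document")
        self.provenance = doc["provenance"]
        self.antecedent = AntecedentModel.from_dict(doc["antecedent"])
        self.params = np.asarray(doc["consequent"], dtype=float)
        self.hyperparams = doc["hyperparams"]
        norm = doc.get("normalize") or {"enabled": False}
        self._norm_mu = None if norm.get("mean") is None else np.asarray(norm["mean"])
        self._norm_sd = None if norm.get("sd") is None else np.asarray(norm["sd"])
        self._normalize = bool(norm.get("enabled"))

    def _prep(self, X):
        X = np.asarray(X, dtype=float)
        if self._normalize:
            X = (X - self._norm_mu) / self._norm_sd
        return X

    def decision_function(self, X) -> np.ndarray:
        from .antecedent import build_design
        from .solvers import decision_values

        return decision_values(self.params, build_design(self.antecedent, self._prep(X)))

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0, 1.0, -1.0)


def load_model(path) -> LoadedModel:
    return LoadedModel(json.loads(Path(path).read_text()))


def read_bonn_segments(path, groups=("A", "B", "C", "D", "E")):
    """Read Bonn-style plain-text EEG segments.

    Expects one subdirectory per requested group (A-E) under ``path``, each
    holding plain-text files with one numeric sample per line.  Returns
    ``(segments, labels, group_of_row)`` with one row per segment; all
    segments must share one length.  Healthy groups (A, B) map to +1,
    epileptic groups (C, D, E) to -1.
    """
    root = Path(path)
    segments, labels, group_names = [], [], []
    seg_len = None
    for g in groups:
        if g not in BONN_GROUP_LABELS:
            raise ValueError(f"unknown group {g!r}; expected letters A-E")
        gdir = root / g
        if not gdir.is_dir():
            raise FileNotFoundError(f"missing group directory: {gdir}")
        for fname in sorted(gdir.iterdir()):
            if fname.is_dir():
                continue
            vals = []
            with open(fname) as fh:
                for lineno, line in enumerate(fh, 1):
                    tok = line.strip()
                    if not tok:
                        continue
                    try:
                        vals.append(float(tok))
                    except ValueError:
                        raise ValueError(
                            f"non-numeric value in {fname} at line {lineno}: {tok!r}"
                        ) from None
            if seg_len is None:
                seg_len = len(vals)
            elif len(vals) != seg_len:
                raise ValueError(
                    f"ragged segment length in {fname}: {len(vals)} != {seg_len}"
                )
            segments.append(vals)
            labels.append(BONN_GROUP_LABELS[g])
            group_names.append(g)
    if not segments:
        raise FileNotFoundError(f"no segment files found under {root}")
    return np.asarray(segments, dtype=float), np.asarray(labels), group_names
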