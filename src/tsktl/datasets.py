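"""Packaged reference data.

``load_benchmark_tables`` returns the published mean-accuracy tables of the
eight-classifier Bonn-EEG transfer benchmark (ten source→target dataset
pairings, three feature-extraction views: WPD, STFT, KPCA).  These tables
are reference inputs for the rank/Friedman/Holm analysis; the package does
not regenerate them (doing so would require the external EEG corpus and the
original feature-extraction settings).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import AccuracyTable

__all__ = ["load_benchmark_tables", "BENCHMARK_VIEWS"]

BENCHMARK_VIEWS = ("wpd", "stft", "kpca")


def load_benchmark_tables() -> dict:
    """View name -> AccuracyTable (10 datasets x 8 methods)."""
    tables = {}
    base = resources.files("tsktl").joinpath("data/benchmarks")
    for view in BENCHMARK_VIEWS:
        with resources.as_file(base.joinpath(f"{view}.csv")) as path:
            df = pd.read_csv(path, index_col=0)  # methods x datasets on disk
        tables[view] = AccuracyTable(mean=df.T)
    return tables
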