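"""CSV / JSON readers and writers shared across the toolkit.

RR series travel as small CSV files: either one column (``interval_ms``,
beat times reconstructed by cumulative sum) or two (``interval_ms``,
``beat_time_s``). ECG comes as a two-column CSV (``time_s``, ``mv``).
Feature tables, rankings and evaluation results are written as CSV /
JSON with deterministic column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DataError, ECGSignal, RRSeries
from .evaluation import EvalResult

__all__ = [
    "read_rr_csv",
    "write_rr_csv",
    "read_ecg_csv",
    "write_feature_table",
    "write_eval_result",
    "write_ranking",
]


def read_rr_csv(path) -> RRSeries:
    """Read an RR series from CSV (1- or 2-column dialect, header required)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] not in (1, 2):
        raise DataError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    for col in df.columns:
        bad = df[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise DataError(
                f"{path}: non-numeric or non-finite value in column {col!r} "
                f"at data row {bad.index[0] + 1}"
            )
    intervals = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(intervals <= 0):
        raise DataError(f"{path}: RR intervals must be positive")
    beat_times = df.iloc[:, 1].to_numpy(dtype=float) if df.shape[1] == 2 else None
    return RRSeries(intervals, beat_times=beat_times)


def write_rr_csv(rr: RRSeries, path) -> None:
    """Write an RR series as a two-column CSV (interval_ms, beat_time_s)."""
    pd.DataFrame(
        {"interval_ms": rr.intervals, "beat_time_s": rr.beat_times}
    ).to_csv(path, index=False)


def read_ecg_csv(path, fs: float | None = None) -> ECGSignal:
    """Read a two-column (time_s, mv) ECG CSV.

    The sampling rate is inferred from the median time step unless
    given explicitly; a non-uniform grid (tolerance 1%) is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise DataError(f"{path}: expected 2 columns (time_s, mv)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise DataError(f"{path}: time column must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise DataError(f"{path}: time grid is not uniform")
    return ECGSignal(v, fs=fs if fs is not None else 1.0 / med, start_time=float(t[0]))


def write_feature_table(table: pd.DataFrame, path, labels=None) -> None:
    """Write a feature table (optionally with a trailing label column).

    Column names must be unique; order is preserved exactly as given.
    """
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise DataError(f"duplicate feature names: {dupes}")
    out = table.copy()
    if labels is not None:
        out["label"] = np.asarray(labels)
    out.to_csv(path, index=False)


def write_eval_result(result: EvalResult, path) -> None:
    """Serialize an evaluation result (per-split records + summary) to JSON."""
    payload = {
        "summary": result.summary(),
        "per_split": {
            "accuracy": result.accuracies.tolist(),
            "f1": result.f1_scores.tolist(),
            "selected": [sel.tolist() for sel in result.selected],
        },
        "feature_names": list(result.feature_names),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_ranking(ranking: pd.DataFrame, path) -> None:
    """Write a (feature, freq) ranking table as CSV."""
    ranking.to_csv(path, index=False)
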