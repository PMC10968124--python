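"""CSV dataset ingestion and run-report emission.

Datasets are plain CSV: a header row, one numeric column per feature, one
categorical label column, comma-separated, '.' decimal, UTF-8.  Rows with
missing values are dropped with a counted warning; a non-numeric feature cell
is a hard parse error reported with its row/column coordinates.

Reports are written twice: a structured JSON file (configuration echo,
per-run records, summary, traces) and a flat per-run CSV table.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import RunReport
from .fitness import Dataset

__all__ = [
    "read_csv_dataset",
    "write_dataset_csv",
    "write_run_report",
    "read_run_report",
]


def read_csv_dataset(path, label_column: str) -> Dataset:
    """Load a tabular classification dataset from CSV."""
    frame = pd.read_csv(path)
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found in {path} "
                         f"(columns: {list(frame.columns)})")
    labels = frame[label_column]
    feats = frame.drop(columns=[label_column])
    for col in feats.columns:
        converted = pd.to_numeric(feats[col], errors="coerce")
        bad = converted.isna() & feats[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric feature value {feats[col][row]!r} "
                f"at row {row}, column {col!r}")
        feats[col] = converted
    missing = feats.isna().any(axis=1) | labels.isna()
    if missing.any():
        warnings.warn(f"dropped {int(missing.sum())} row(s) with missing values",
                      stacklevel=2)
        feats, labels = feats[~missing], labels[~missing]
    return Dataset(features=feats.to_numpy(dtype=float),
                   labels=labels.to_numpy(),
                   feature_names=list(feats.columns))


def write_dataset_csv(dataset: Dataset, path, label_column: str = "label") -> None:
    """Write a dataset in the same CSV dialect the reader consumes."""
    frame = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    frame[label_column] = dataset.labels
    frame.to_csv(path, index=False)


def write_run_report(report: RunReport, out_dir, stem: str = "report") -> tuple[Path, Path]:
    """Emit the JSON report and the per-run CSV table; returns their paths."""
    if not report.runs:
        raise ValueError("refusing to write a report with no runs")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    payload = {
        "config": report.config,
        "runs": report.runs,
        "summary": {
            "mean_fitness": report.summary.mean_fitness,
            "mean_accuracy": report.summary.mean_accuracy,
            "mean_subset_ratio": report.summary.mean_subset_ratio,
            "n_runs": report.summary.n_runs,
        },
        "traces": [res.trace.tolist() for res in report.results],
    }
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                         encoding="utf-8")

    table = pd.DataFrame(report.runs)
    table["best_features"] = table["best_features"].map(";".join)
    csv_path = out_dir / f"{stem}_runs.csv"
    table.to_csv(csv_path, index=False)
    return json_path, csv_path


def read_run_report(json_path) -> dict:
    """Load the structured JSON report back as a plain dictionary."""
    return json.loads(Path(json_path).read_text(encoding="utf-8"))
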