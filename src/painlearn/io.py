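"""Readers and writers for the pipeline's delimited formats.

Behaviour tables (subject, group, run, trial, choice, win, loss, optional
onset columns), parcel time-series matrices (label column + volumes),
clinical score tables (subject x named scores), FSL-style 3-column EV
files, and JSON run manifests.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ChoiceDataset, InvalidDataError, LatentTrace
from .network import ParcelTimeSeries

__all__ = [
    "read_behaviour",
    "write_behaviour",
    "read_timeseries",
    "write_timeseries",
    "read_clinical",
    "write_ev_files",
    "write_manifest",
]

_REQUIRED = ["subject", "run", "trial", "choice", "win", "loss"]


def read_behaviour(path) -> list[ChoiceDataset]:
    """Read a behaviour CSV/TSV with strict coding validation.

    choice must be 1-4, win 0/1, loss 0/-1; offending row numbers (1-based,
    excluding the header) are listed in the error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise InvalidDataError(f"{path}: missing columns {missing}")
    problems = []
    for col, valid in (("choice", {1, 2, 3, 4}), ("win", {0, 1}), ("loss", {0, -1})):
        bad = ~df[col].isin(list(valid))
        if bad.any():
            rows = (df.index[bad] + 1).tolist()[:10]
            problems.append(f"{col} outside {sorted(valid)} at rows {rows}")
    if problems:
        raise InvalidDataError(f"{path}: " + "; ".join(problems))
    datasets = []
    for sid, sub in df.groupby("subject", sort=True):
        group = str(sub["group"].iloc[0]) if "group" in sub.columns else ""
        datasets.append(ChoiceDataset.from_dataframe(sub, subject_id=str(sid),
                                                     group_label=group))
    return datasets


def write_behaviour(datasets: list[ChoiceDataset], path) -> None:
    pd.concat([ds.to_dataframe() for ds in datasets], ignore_index=True).to_csv(
        path, index=False)


def read_timeseries(path, subject_id: str = "", condition: str = "task") -> ParcelTimeSeries:
    """Delimited matrix: first column parcel label, remaining columns volumes."""
    df = pd.read_csv(path, sep=None, engine="python")
    labels = df.iloc[:, 0].astype(str).tolist()
    data = df.iloc[:, 1:].to_numpy(dtype=float)
    return ParcelTimeSeries(subject_id or Path(path).stem, labels, data, condition)


def write_timeseries(ts: ParcelTimeSeries, path) -> None:
    df = pd.DataFrame(ts.data)
    df.insert(0, "parcel", ts.labels)
    df.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    """Clinical table: subject column + named score columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "subject" not in df.columns:
        raise InvalidDataError(f"{path}: missing 'subject' column")
    return df.set_index("subject")


def write_ev_files(
    regressors: dict[int, dict[str, np.ndarray]],
    out_dir,
    subject_id: str,
) -> list[Path]:
    """FSL 3-column EV text files (onset duration value, whitespace-
    delimited, no header), one file per regressor per run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for run_id, tables in regressors.items():
        for name, table in tables.items():
            p = out_dir / f"{subject_id}_run{run_id}_{name}.txt"
            np.savetxt(p, table, fmt="%.6f")
            written.append(p)
    return written


def write_manifest(out_dir, config: dict, seed: int) -> Path:
    """JSON run manifest: config hash, seed, package versions."""
    import painlearn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "painlearn": painlearn.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": config,
    }
    p = out_dir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return p
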