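"""Plain-text readers and writers for ECG traces, RRI series, manifests
and metric tables.

ECG traces are one-column numeric text with a YAML sidecar (``<name>.meta.yaml``)
recording the sampling frequency and units.  RRI files hold one interval per
line, in seconds by default (milliseconds via ``ms=True``).  Cohort
manifests are CSV with the header
``subject_id,path,group,age,menopause,pr,ki67``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ECGRecord, RRISeries

__all__ = [
    "write_ecg",
    "read_ecg",
    "write_rri",
    "read_rri",
    "write_manifest",
    "read_manifest",
    "write_metric_csv",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["subject_id", "path", "group", "age", "menopause", "pr", "ki67"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_ecg(record: ECGRecord, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, record.samples, fmt="%.6f")
    meta = {"fs": float(record.fs), "units": "mV"}
    if record.subject_id:
        meta["subject_id"] = record.subject_id
    _sidecar(path).write_text(yaml.safe_dump(meta))
    return path


def read_ecg(path: str | Path, fs: float | None = None) -> ECGRecord:
    """Read a one-column ECG file; ``fs`` overrides the sidecar metadata."""
    path = Path(path)
    subject_id = None
    sidecar = _sidecar(path)
    if fs is None:
        if not sidecar.exists():
            raise ValueError(
                f"no sampling frequency: pass fs or provide sidecar {sidecar.name}"
            )
        meta = yaml.safe_load(sidecar.read_text())
        fs = float(meta["fs"])
        subject_id = meta.get("subject_id")
    samples = np.loadtxt(path, dtype=float)
    return ECGRecord(samples, fs=fs, subject_id=subject_id)


def write_rri(rri: RRISeries, path: str | Path, ms: bool = False) -> Path:
    path = Path(path)
    scale = 1000.0 if ms else 1.0
    np.savetxt(path, rri.intervals * scale, fmt="%.6f")
    return path


def read_rri(path: str | Path, ms: bool = False) -> RRISeries:
    intervals = np.atleast_1d(np.loadtxt(path, dtype=float))
    if ms:
        intervals = intervals / 1000.0
    return RRISeries(intervals, provenance="raw")


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_metric_csv(metric_rows: list[dict], path: str | Path) -> Path:
    """Flat metric table: ``subject_id,condition,metric,value``."""
    path = Path(path)
    pd.DataFrame(metric_rows, columns=["subject_id", "condition", "metric", "value"]).to_csv(
        path, index=False
    )
    return path
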