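"""Core data containers shared across the pipeline.

The pipeline moves through a small set of typed stages: a uniformly sampled
voltage trace (:class:`ECGRecord`), detected R-wave fiducials
(:class:`RPeakSet`), the beat-to-beat interval series with quality-control
flags (:class:`RRISeries`), its smooth-trend/residual decomposition
(:class:`DetrendedRRI`), and per-subject metric maps joined into a cohort
table for the statistics layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ECGRecord",
    "RPeakSet",
    "RRISeries",
    "DetrendedRRI",
    "MetricSet",
    "CohortTable",
]


@dataclass
class ECGRecord:
    """A single-lead ECG voltage trace sampled uniformly at ``fs`` Hz.

    Parameters
    ----------
    samples
        Voltage samples in millivolts.
    fs
        Sampling frequency in Hz (study device: 400 Hz).
    subject_id
        Optional identifier carried through to outputs.
    """

    samples: np.ndarray
    fs: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("ECG samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class RPeakSet:
    """Confirmed R-peak apex positions as 0-based sample indices."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("R-peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.indices / self.fs

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class RRISeries:
    """Ordered beat-to-beat intervals (seconds) with per-interval QC flags.

    ``valid`` marks intervals retained by quality control;
    ``bounds_reject`` marks physiologically implausible intervals
    (outside [0.3, 2.0] s by default) and ``cluster_flag`` marks intervals
    flagged by the adjacent-relative-change rule or sitting next to a removed
    cluster.  ``provenance`` is ``"raw"`` or ``"cleaned"``.
    """

    intervals: np.ndarray
    provenance: str = "raw"
    valid: np.ndarray | None = None
    bounds_reject: np.ndarray | None = None
    cluster_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        n = self.intervals.size
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        if self.bounds_reject is None:
            self.bounds_reject = np.zeros(n, dtype=bool)
        if self.cluster_flag is None:
            self.cluster_flag = np.zeros(n, dtype=bool)
        for name in ("valid", "bounds_reject", "cluster_flag"):
            arr = np.asarray(getattr(self, name), dtype=bool)
            if arr.size != n:
                raise ValueError(f"flag array {name!r} length mismatch")
            setattr(self, name, arr)
        if self.provenance not in ("raw", "cleaned"):
            raise ValueError("provenance must be 'raw' or 'cleaned'")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def beat_times(self) -> np.ndarray:
        """Cumulative time of each beat (end of each interval), seconds."""
        return np.cumsum(self.intervals)

    @property
    def duration(self) -> float:
        return float(np.sum(self.intervals))


@dataclass
class DetrendedRRI:
    """Smoothness-priors decomposition of a cleaned RRI series.

    ``trend + residual`` reconstructs the input elementwise.  ``lam`` is the
    regularisation strength (enters the solve as lam**2) and ``diff_order``
    the order of the penalised difference operator.
    """

    residual: np.ndarray
    trend: np.ndarray
    lam: float
    diff_order: int
    mean_rr: float

    def __post_init__(self) -> None:
        self.residual = np.asarray(self.residual, dtype=float)
        self.trend = np.asarray(self.trend, dtype=float)
        if self.residual.shape != self.trend.shape:
            raise ValueError("residual and trend must have equal length")

    def series(self, mean_restored: bool = False) -> np.ndarray:
        """The stationary series used for downstream metrics.

        By default the zero-mean residual is returned (the package's
        detrended-condition convention); with ``mean_restored`` the mean RR
        is added back, which leaves every metric except the angle/radius
        based SI and AI unchanged.
        """
        if mean_restored:
            return self.residual + self.mean_rr
        return self.residual.copy()


# Named metric -> value map for one subject under one preprocessing condition.
MetricSet = dict[str, float]

#: canonical metric ordering used by reports and CSV output
METRIC_NAMES: tuple[str, ...] = (
    "sdnn",
    "rmssd",
    "lf",
    "hf",
    "lf_hf",
    "apen",
    "sampen",
    "sd1",
    "sd2",
    "sd1_sd2",
    "pi",
    "gi",
    "si",
    "ai",
    "gdr",
    "gde",
)

CONDITIONS: tuple[str, ...] = ("raw", "detrended")

COVARIATE_NAMES: tuple[str, ...] = ("age", "menopause", "pr", "ki67")


@dataclass
class CohortTable:
    """Per-subject metric sets joined with group label and covariates.

    ``data`` is a wide DataFrame with one row per subject: ``subject_id``,
    ``group`` (1 = positive, 0 = negative), covariate columns
    (``age``, ``menopause``, ``pr``, ``ki67``) and one column per
    (metric, condition) pair named ``"<metric>_<condition>"``.
    """

    data: pd.DataFrame
    covariates: tuple[str, ...] = COVARIATE_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "group" not in self.data.columns:
            raise ValueError("cohort table requires a 'group' column")
        if self.data["subject_id"].duplicated().any():
            raise ValueError("duplicated subject ids in cohort table")
        groups = set(self.data["group"].unique())
        if not groups.issuperset({0, 1}):
            raise ValueError("both groups must be non-empty (labels 0 and 1)")

    def metric_columns(self) -> list[str]:
        reserved = {"subject_id", "group", *self.covariates}
        return [c for c in self.data.columns if c not in reserved]

    def values(self, metric: str, condition: str) -> np.ndarray:
        return self.data[f"{metric}_{condition}"].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.data["group"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.data)
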