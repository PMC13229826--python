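"""Poincare-plot graphical metrics: ellipse, asymmetry, and grid occupancy.

The Poincare plot scatters each interval against its successor,
``(x_i, y_i) = (RR_i, RR_{i+1})``.  The identity line y = x splits it into an
acceleration region (y < x: the next beat comes sooner) and a deceleration
region (y > x).  Three metric families are computed:

* **Ellipse** — SD1 (dispersion perpendicular to the identity line,
  beat-to-beat variability) and SD2 (dispersion along it, longer-term
  variability), from the variance decomposition
  ``SD1^2 = Var(dRR)/2`` and ``SD2^2 = 2 Var(RR) - Var(dRR)/2``.

* **Heart-rate asymmetry** — Porta (PI: point counts), Guzik (GI: vertical
  distances to the identity line), Slope (SI: phase angles from the x-axis,
  referenced to 45 degrees) and Area (AI: circular-sector areas
  ``r^2 theta / 2``) indices.  Each is the acceleration share of its
  functional, in percent, reported as the absolute deviation |X - 50| from
  the symmetry baseline: 0 means perfect acceleration/deceleration balance.
  Points exactly on the identity line are excluded from numerator and
  denominator (Porta's convention).

* **Grid occupancy** — the plot's square bounding box is divided into an
  n x n grid; GDR is the fraction of occupied cells and GDE the Shannon
  entropy (nats) of the cell-occupancy distribution.  Both are averaged over
  all integer resolutions n in [100, 200] so that no single arbitrary grid
  choice drives the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PoincarePoints",
    "EllipseMetrics",
    "AsymmetryMetrics",
    "GridMetrics",
    "poincare_points",
    "ellipse_metrics",
    "asymmetry_metrics",
    "grid_metrics_at",
    "grid_metrics",
]


def _as_array(rri, min_len: int) -> np.ndarray:
    x = np.asarray(getattr(rri, "intervals", rri), dtype=float)
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} intervals, got {x.size}")
    return x


@dataclass
class PoincarePoints:
    """Successive-interval pairs with acceleration/deceleration bookkeeping."""

    x: np.ndarray
    y: np.ndarray

    @property
    def accel(self) -> np.ndarray:
        """Mask of accelerating points (next interval shorter)."""
        return self.y < self.x

    @property
    def decel(self) -> np.ndarray:
        return self.y > self.x

    @property
    def online(self) -> np.ndarray:
        return self.y == self.x

    @property
    def n_accel(self) -> int:
        return int(np.sum(self.accel))

    @property
    def n_decel(self) -> int:
        return int(np.sum(self.decel))

    def __len__(self) -> int:
        return int(self.x.size)


@dataclass
class EllipseMetrics:
    sd1: float  # ms
    sd2: float  # ms
    ratio: float  # sd1/sd2, nan when sd2 == 0
    sd2_clipped: bool = False


@dataclass
class AsymmetryMetrics:
    """|X - 50| asymmetry indices; nan + flag when undefined."""

    pi: float
    gi: float
    si: float
    ai: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"pi": self.pi, "gi": self.gi, "si": self.si, "ai": self.ai}


@dataclass
class GridMetrics:
    gdr: float  # mean occupied-cell fraction over the resolution range
    gde: float  # mean occupancy entropy (nats)
    n_range: tuple[int, int]
    gdr_trace: np.ndarray  # per-resolution values, index aligned with n_values
    gde_trace: np.ndarray
    n_values: np.ndarray
    degenerate: bool = False


def poincare_points(rri) -> PoincarePoints:
    """Lag-1 Poincare scatter of an interval series."""
    x = _as_array(rri, min_len=2)
    return PoincarePoints(x[:-1].copy(), x[1:].copy())


def ellipse_metrics(rri) -> EllipseMetrics:
    """SD1/SD2 ellipse descriptors, in ms.

    Sample variances (ddof 1) give the exact identities
    ``SD1^2 + SD2^2 = 2 SDNN^2`` and ``SD1 = SDSD / sqrt(2)``.  A negative
    SD2 radicand (possible for strongly alternating rhythms) is clipped to 0
    and flagged.
    """
    x = _as_array(rri, min_len=3)
    var_d = float(np.var(np.diff(x), ddof=1))
    var_x = float(np.var(x, ddof=1))
    sd1 = math.sqrt(var_d / 2.0) * 1000.0
    radicand = 2.0 * var_x - var_d / 2.0
    clipped = radicand < 0
    sd2 = math.sqrt(max(radicand, 0.0)) * 1000.0
    ratio = sd1 / sd2 if sd2 > 0 else math.nan
    return EllipseMetrics(sd1=sd1, sd2=sd2, ratio=ratio, sd2_clipped=clipped)


def asymmetry_metrics(rri, gi_mode: str = "linear") -> AsymmetryMetrics:
    """Porta, Guzik, Slope and Area indices as |X - 50| deviations.

    With A the accelerating points and O all off-line points:

    * PI uses point counts |A| / |O|;
    * GI uses vertical distances d = |y - x| to the identity line;
    * SI uses phase angles theta = |45 deg - atan2(y, x)|;
    * AI uses circular-sector areas S = r^2 theta_rad / 2 with
      r = sqrt(x^2 + y^2).

    All four are ``|100 * (sum over A) / (sum over O) - 50|``.  A series with
    every point on the identity line has no off-line information and returns
    flagged nans.

    ``gi_mode`` selects the GI weighting: ``"linear"`` distances (default)
    or the classic ``"squared"`` Guzik variant.  The distance is measured
    parallel to the y-axis; a perpendicular measure would differ by a
    constant factor that cancels in the ratio.
    """
    if gi_mode not in ("linear", "squared"):
        raise ValueError("gi_mode must be 'linear' or 'squared'")
    pts = poincare_points(_as_array(rri, min_len=2))
    off = ~pts.online
    if not np.any(off):
        return AsymmetryMetrics(math.nan, math.nan, math.nan, math.nan, degenerate=True)
    x, y = pts.x[off], pts.y[off]
    accel = y < x

    def index(weights: np.ndarray) -> float:
        total = float(np.sum(weights))
        if total == 0:
            return math.nan
        return abs(100.0 * float(np.sum(weights[accel])) / total - 50.0)

    counts = np.ones(x.size)
    dists = np.abs(y - x)
    if gi_mode == "squared":
        dists = dists**2
    theta = np.abs(np.deg2rad(45.0) - np.arctan2(y, x))
    areas = (x**2 + y**2) * theta / 2.0

    return AsymmetryMetrics(
        pi=index(counts),
        gi=index(dists),
        si=index(np.rad2deg(theta)),
        ai=index(areas),
    )


def grid_metrics_at(rri, n: int) -> tuple[float, float]:
    """Occupancy ratio and entropy for a single n x n grid resolution.

    The grid covers the square bounding box of the combined coordinate
    range, with half-open cells (points on the top/right edge fall in the
    last cell).  A zero coordinate range returns the single-cell convention
    ``(1/n^2, 0)``.
    """
    if n < 1:
        raise ValueError("grid resolution n must be >= 1")
    pts = poincare_points(_as_array(rri, min_len=2))
    lo = min(pts.x.min(), pts.y.min())
    hi = max(pts.x.max(), pts.y.max())
    side = hi - lo
    if side == 0:
        return 1.0 / n**2, 0.0
    ix = np.clip((pts.x - lo) / side * n, 0, n - 1).astype(np.int64)
    iy = np.clip((pts.y - lo) / side * n, 0, n - 1).astype(np.int64)
    _, counts = np.unique(ix * n + iy, return_counts=True)
    gdr = counts.size / n**2
    p = counts / counts.sum()
    gde = float(-np.sum(p * np.log(p)))
    return float(gdr), gde


def grid_metrics(rri, n_min: int = 100, n_max: int = 200) -> GridMetrics:
    """Multi-resolution grid metrics averaged over n in [n_min, n_max].

    Arithmetic (equal-weight) mean over every integer resolution; the
    per-resolution traces are retained for sensitivity reporting.
    """
    if n_min < 1 or n_max < n_min:
        raise ValueError("need 1 <= n_min <= n_max")
    x = _as_array(rri, min_len=2)
    n_values = np.arange(n_min, n_max + 1)
    gdr_trace = np.empty(n_values.size)
    gde_trace = np.empty(n_values.size)
    degenerate = float(np.ptp(x)) == 0.0
    for i, n in enumerate(n_values):
        gdr_trace[i], gde_trace[i] = grid_metrics_at(x, int(n))
    return GridMetrics(
        gdr=float(np.mean(gdr_trace)),
        gde=float(np.mean(gde_trace)),
        n_range=(n_min, n_max),
        gdr_trace=gdr_trace,
        gde_trace=gde_trace,
        n_values=n_values,
        degenerate=degenerate,
    )
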