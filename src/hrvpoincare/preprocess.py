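"""RR-interval extraction, quality control and smoothness-priors detrending.

Quality control applies two rules in order: intervals outside physiologically
plausible resting bounds ([0.3, 2.0] s) are unconditionally discarded, then
any interval whose relative change against the last accepted interval exceeds
20% is discarded as part of an abnormal cluster (ectopic beats produce a
premature/compensatory pair that trips this rule twice).  Immediate
neighbours of a removed cluster are flagged in the QC report but kept;
``neighbor_margin`` widens removal to them when requested.  A recording
losing more than half of its intervals is rejected as unusable.

Detrending solves the smoothness-priors problem

    trend = argmin ||z - tau||^2 + lambda^2 ||D_d tau||^2
          = (I + lambda^2 D_d' D_d)^{-1} z

with a second-order difference operator and lambda = 500 by default; the
residual z - trend is the stationary component.  Straight lines lie in the
null space of D_2, so linear drifts pass through to the trend exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .core import DetrendedRRI, RPeakSet, RRISeries

__all__ = ["QCReport", "extract_rri", "qc_filter", "smoothness_priors_detrend"]


@dataclass
class QCReport:
    """Removal bookkeeping from :func:`qc_filter`.

    Positions index the *input* series.  ``neighbor_flagged`` lists kept
    intervals adjacent to a removed cluster.
    """

    n_input: int
    bounds_removed: np.ndarray
    cluster_removed: np.ndarray
    neighbor_flagged: np.ndarray

    @property
    def n_removed(self) -> int:
        return int(self.bounds_removed.size + self.cluster_removed.size)

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_rows(self) -> list[dict]:
        rows = [{"index": int(i), "rule": "bounds"} for i in self.bounds_removed]
        rows += [{"index": int(i), "rule": "relative_change"} for i in self.cluster_removed]
        rows += [{"index": int(i), "rule": "neighbor_flag"} for i in self.neighbor_flagged]
        return sorted(rows, key=lambda r: r["index"])


def extract_rri(rpeaks: RPeakSet) -> RRISeries:
    """Intervals between consecutive confirmed R-peak apices, in seconds."""
    if len(rpeaks) < 2:
        raise ValueError("need at least 2 R peaks to form an interval series")
    intervals = np.diff(rpeaks.indices) / rpeaks.fs
    return RRISeries(intervals, provenance="raw")


def qc_filter(
    rri: RRISeries,
    low: float = 0.3,
    high: float = 2.0,
    rel_change: float = 0.20,
    max_removed_fraction: float = 0.5,
    neighbor_margin: int = 0,
) -> tuple[RRISeries, QCReport]:
    """Remove implausible intervals and abnormal-change clusters.

    Bounds rejection runs first; the relative-change rule is then evaluated
    on the spliced series, comparing each interval with the last accepted
    one (denominator = the earlier, accepted interval).  ``neighbor_margin``
    additionally removes that many kept neighbours on each side of every
    removed cluster (default 0: neighbours are only flagged).

    Raises ``ValueError`` when more than ``max_removed_fraction`` of the
    input is removed, signalling an unusable recording.
    """
    x = rri.intervals
    n = x.size
    if n == 0:
        raise ValueError("empty RRI series")

    in_bounds = (x >= low) & (x <= high)
    bounds_removed = np.flatnonzero(~in_bounds)
    surviving = np.flatnonzero(in_bounds)  # input positions of the spliced series

    removed_mask = np.zeros(surviving.size, dtype=bool)
    last_accepted = None
    for j, pos in enumerate(surviving):
        v = x[pos]
        if last_accepted is None:
            last_accepted = v
            continue
        if abs(v - last_accepted) / last_accepted > rel_change:
            removed_mask[j] = True
        else:
            last_accepted = v

    if neighbor_margin > 0 and removed_mask.any():
        widened = removed_mask.copy()
        hits = np.flatnonzero(removed_mask)
        for h in hits:
            widened[max(h - neighbor_margin, 0) : h + neighbor_margin + 1] = True
        removed_mask = widened

    cluster_removed = surviving[removed_mask]
    keep_positions = surviving[~removed_mask]

    # neighbours of removed clusters, among kept intervals
    removed_set = set(bounds_removed.tolist()) | set(cluster_removed.tolist())
    neighbor = [
        int(p)
        for p in keep_positions
        if (p - 1 in removed_set) or (p + 1 in removed_set)
    ]

    report = QCReport(
        n_input=n,
        bounds_removed=bounds_removed,
        cluster_removed=cluster_removed,
        neighbor_flagged=np.asarray(neighbor, dtype=int),
    )
    if report.removed_fraction > max_removed_fraction:
        raise ValueError(
            f"unusable recording: QC removed {report.n_removed}/{n} intervals "
            f"({100 * report.removed_fraction:.0f}% > "
            f"{100 * max_removed_fraction:.0f}%)"
        )

    valid = np.zeros(n, dtype=bool)
    valid[keep_positions] = True
    bounds_flag = np.zeros(n, dtype=bool)
    bounds_flag[bounds_removed] = True
    cluster_flag = np.zeros(n, dtype=bool)
    cluster_flag[cluster_removed] = True
    cluster_flag[report.neighbor_flagged] = True

    cleaned = RRISeries(
        x[keep_positions],
        provenance="cleaned",
        valid=np.ones(keep_positions.size, dtype=bool),
    )
    # annotate the input-aligned flags on the report for provenance
    report.input_flags = {  # type: ignore[attr-defined]
        "valid": valid,
        "bounds_reject": bounds_flag,
        "cluster_flag": cluster_flag,
    }
    return cleaned, report


def _difference_operator(n: int, order: int) -> sparse.spmatrix:
    d = sparse.identity(n, format="csc")
    for _ in range(order):
        rows = d.shape[0] - 1
        diff = sparse.diags([-np.ones(rows), np.ones(rows)], [0, 1],
                            shape=(rows, d.shape[0]), format="csc")
        d = diff @ d
    return d


def smoothness_priors_detrend(
    rri: RRISeries, lam: float = 500.0, order: int = 2
) -> DetrendedRRI:
    """Split a cleaned RRI series into a smooth trend and a residual.

    The regulariser enters as ``lam**2`` so ``lam`` plays the role of the
    smoothing strength; ``order=2`` penalises curvature.  The sparse system
    is solved exactly (N is a few hundred, so cost is negligible).
    """
    z = rri.intervals
    n = z.size
    if n < order + 2:
        raise ValueError(f"series of length {n} too short for difference order {order}")
    d = _difference_operator(n, order)
    a = sparse.identity(n, format="csc") + (lam**2) * (d.T @ d)
    trend = spsolve(a.tocsc(), z)
    residual = z - trend
    return DetrendedRRI(
        residual=residual,
        trend=trend,
        lam=lam,
        diff_order=order,
        mean_rr=float(np.mean(z)),
    )
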