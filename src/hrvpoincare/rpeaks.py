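"""Adaptive R-peak detection (Pan-Tompkins style).

The chain is: 5-15 Hz zero-phase Butterworth bandpass -> five-point
differencing -> squaring -> 150 ms moving-window integration -> adaptive
dual-threshold peak picking with minimum-interval, T-wave and refractory
rules -> apex refinement as the local maximum of the bandpassed signal
within +/-150 ms of each candidate.

Thresholds adapt as exponential running estimates of signal- and noise-peak
levels (weights 1/8 and 7/8), with a half-threshold search-back when no beat
is found within 1.66x the running RR estimate.  Because every threshold is
derived from the signal itself, detection is invariant to global amplitude
scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .core import ECGRecord, RPeakSet

__all__ = ["DetectorConfig", "bandpass", "feature_transform", "detect_rpeaks"]

# classic five-point derivative kernel: y[n] = (2x[n] + x[n-1] - x[n-3] - 2x[n-4]) / 8,
# antisymmetric about its centre, applied here with the 2-sample delay removed
_DERIV_KERNEL = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable constants of the detection chain (times in seconds)."""

    band: tuple[float, float] = (5.0, 15.0)
    order: int = 3
    integration_window: float = 0.150
    min_peak_interval: float = 0.2
    twave_window: float = 0.36
    refractory: float = 0.2
    refine_window: float = 0.150
    # adaptive-threshold machinery
    signal_weight: float = 0.125  # 1/8 update of the running peak levels
    threshold_frac: float = 0.25  # threshold = noise + frac * (signal - noise)
    searchback_factor: float = 1.66
    searchback_thresh_frac: float = 0.5
    twave_slope_frac: float = 0.5

    def validate(self, fs: float) -> None:
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < low < high")
        if hi >= fs / 2:
            raise ValueError(
                f"band high edge {hi} Hz violates the Nyquist limit {fs / 2} Hz "
                f"at fs={fs} Hz"
            )
        for name in ("integration_window", "min_peak_interval", "twave_window",
                     "refractory", "refine_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def bandpass(ecg: ECGRecord, band: tuple[float, float] = (5.0, 15.0), order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth bandpass of the ECG trace.

    Forward-backward filtering keeps the output aligned with the input so the
    integrated energy signal and the refinement stage share a time base.
    """
    lo, hi = band
    if hi >= ecg.fs / 2:
        raise ValueError(
            f"band high edge {hi} Hz violates the Nyquist limit {ecg.fs / 2} Hz "
            f"at fs={ecg.fs} Hz"
        )
    sos = sps.butter(order, band, btype="bandpass", fs=ecg.fs, output="sos")
    return sps.sosfiltfilt(sos, ecg.samples)


def feature_transform(filtered: np.ndarray, fs: float, integration_window: float = 0.150) -> np.ndarray:
    """Five-point derivative, squaring, and moving-window integration.

    The derivative is scaled by ``fs`` (units of mV/s), squared, then averaged
    over ``round(integration_window * fs)`` samples.  Output is non-negative
    and time-aligned with the input (the kernel's 2-sample group delay is
    compensated and the integration window is centred).
    """
    x = np.asarray(filtered, dtype=float)
    win = int(round(integration_window * fs))
    if x.size <= win:
        raise ValueError("signal shorter than the integration window")
    padded = np.pad(x, 2, mode="edge")  # replicate edges: constant input -> 0
    deriv = np.convolve(padded, _DERIV_KERNEL * fs, mode="valid")
    return uniform_filter1d(deriv**2, size=max(win, 1), mode="nearest")


def _max_slope(filtered: np.ndarray, idx: int, half: int) -> float:
    lo = max(idx - half, 0)
    hi = min(idx + half + 1, filtered.size - 1)
    if hi <= lo:
        return 0.0
    return float(np.max(np.abs(np.diff(filtered[lo : hi + 1]))))


def detect_rpeaks(ecg: ECGRecord, cfg: DetectorConfig | None = None) -> RPeakSet:
    """Detect R-peak apices in a raw ECG trace.

    Returns an empty :class:`RPeakSet` with a warning (not an exception) when
    no peaks survive the rules.
    """
    cfg = cfg or DetectorConfig()
    cfg.validate(ecg.fs)
    fs = ecg.fs
    if ecg.duration < 2.0:
        raise ValueError("need at least 2 s of signal for detection")

    filt = bandpass(ecg, cfg.band, cfg.order)
    integ = feature_transform(filt, fs, cfg.integration_window)

    dist = max(int(round(cfg.min_peak_interval * fs)), 1)
    candidates, _ = sps.find_peaks(integ, distance=dist)
    if candidates.size == 0:
        warnings.warn("no candidate peaks found in the integrated signal")
        return RPeakSet(np.empty(0, dtype=np.int64), fs)

    init = integ[: int(2 * fs)]
    spk = float(np.max(init)) / 3.0  # running signal-peak level
    npk = float(np.mean(init)) / 2.0  # running noise-peak level
    w = cfg.signal_weight

    twave_win = int(round(cfg.twave_window * fs))
    slope_half = int(round(0.075 * fs))
    searchback = cfg.searchback_factor

    accepted: list[int] = []
    rejected: list[int] = []  # noise-classified candidates, for search-back
    rr_recent: list[float] = []

    def threshold() -> float:
        return npk + cfg.threshold_frac * (spk - npk)

    def is_twave(idx: int) -> bool:
        if not accepted or idx - accepted[-1] >= twave_win:
            return False
        return _max_slope(filt, idx, slope_half) < cfg.twave_slope_frac * _max_slope(
            filt, accepted[-1], slope_half
        )

    def accept(idx: int, from_searchback: bool = False) -> None:
        nonlocal spk
        weight = 2 * w if from_searchback else w
        spk = weight * integ[idx] + (1 - weight) * spk
        if accepted:
            rr_recent.append((idx - accepted[-1]) / fs)
            del rr_recent[:-8]
        accepted.append(idx)

    for idx in candidates:
        # search-back: expected beat missed -> rescan noise peaks at half threshold
        if accepted and rr_recent:
            rr_avg = float(np.mean(rr_recent))
            if (idx - accepted[-1]) / fs > searchback * rr_avg:
                half_thr = cfg.searchback_thresh_frac * threshold()
                window = [j for j in rejected if accepted[-1] < j < idx]
                window = [j for j in window if integ[j] > half_thr and not is_twave(j)]
                if window:
                    best = max(window, key=lambda j: integ[j])
                    if (best - accepted[-1]) / fs >= cfg.min_peak_interval:
                        accept(best, from_searchback=True)
        if integ[idx] > threshold() and not is_twave(idx):
            accept(idx)
        else:
            npk = w * integ[idx] + (1 - w) * npk
            rejected.append(idx)

    if not accepted:
        warnings.warn("no peaks passed the adaptive threshold")
        return RPeakSet(np.empty(0, dtype=np.int64), fs)

    # apex refinement on the bandpassed trace
    refine_half = int(round(cfg.refine_window * fs))
    refined = []
    for idx in accepted:
        lo = max(idx - refine_half, 0)
        hi = min(idx + refine_half + 1, filt.size)
        refined.append(lo + int(np.argmax(np.abs(filt[lo:hi]))))
    refined = np.unique(np.asarray(refined, dtype=np.int64))

    # refractory: merge peaks closer than 0.2 s, keeping the larger apex
    refractory = int(round(cfg.refractory * fs))
    kept: list[int] = []
    for idx in refined:
        if kept and idx - kept[-1] < refractory:
            if np.abs(filt[idx]) > np.abs(filt[kept[-1]]):
                kept[-1] = int(idx)
        else:
            kept.append(int(idx))
    return RPeakSet(np.asarray(kept, dtype=np.int64), fs)
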