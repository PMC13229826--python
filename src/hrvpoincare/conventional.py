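"""Time-domain, frequency-domain and entropy HRV metrics.

Frequency-domain analysis resamples the tachogram onto a uniform 4 Hz grid
(cubic spline over cumulative beat times by default), then estimates the
power spectral density with Welch's method (256-point Hamming segments, 50%
overlap, 1024-point FFT) and integrates the LF (0.04-0.15 Hz) and HF
(0.15-0.40 Hz) bands with the trapezoidal rule.  The shared 0.15 Hz band
edge is assigned to HF (LF is half-open on the right).

Entropy uses the standard template-matching definitions with Chebyshev
distance, embedding dimension m = 2, and tolerance r = 0.2 x the series'
standard deviation: ApEn includes self-matches, SampEn excludes them and
reports -ln(A/B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "SpectralConfig",
    "EntropyConfig",
    "sdnn",
    "rmssd",
    "resample_tachogram",
    "welch_band_powers",
    "apen",
    "sampen",
]


@dataclass(frozen=True)
class SpectralConfig:
    resample_rate: float = 4.0
    segment_length: int = 256
    overlap: float = 0.5
    window: str = "hamming"
    nfft: int = 1024
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.40)
    interpolation: str = "cubic"  # or "linear"

    def validate(self) -> None:
        nyq = self.resample_rate / 2
        if not 0 < self.lf_band[0] < self.lf_band[1] <= self.hf_band[0] < self.hf_band[1] < nyq:
            raise ValueError("bands must be disjoint and inside (0, resample_rate/2)")

    @property
    def min_duration(self) -> float:
        """Shortest usable record: two segment lengths of resampled signal."""
        return 2 * self.segment_length / self.resample_rate


@dataclass(frozen=True)
class EntropyConfig:
    m: int = 2
    r: float = 0.2  # tolerance as a fraction of the series SD

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if self.r <= 0:
            raise ValueError("tolerance fraction r must be positive")


def _as_array(rri, min_len: int = 2) -> np.ndarray:
    x = np.asarray(getattr(rri, "intervals", rri), dtype=float)
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} intervals, got {x.size}")
    return x


def sdnn(rri) -> float:
    """Sample standard deviation of the interval series, in ms."""
    x = _as_array(rri)
    return float(np.std(x, ddof=1) * 1000.0)


def rmssd(rri) -> float:
    """Root mean square of successive differences, in ms."""
    x = _as_array(rri)
    return float(np.sqrt(np.mean(np.diff(x) ** 2)) * 1000.0)


def resample_tachogram(
    rri, cfg: SpectralConfig | None = None, times: np.ndarray | None = None
) -> np.ndarray:
    """Interpolate the tachogram onto a uniform grid at ``cfg.resample_rate``.

    Beat times default to the cumulative interval sums (each beat carries
    its preceding interval as the tachogram value); pass ``times`` when the
    values are not themselves the intervals, e.g. a zero-mean detrended
    residual whose time base comes from the cleaned series.
    """
    cfg = cfg or SpectralConfig()
    x = _as_array(rri, min_len=4)
    t = np.cumsum(x) if times is None else np.asarray(times, dtype=float)
    if t.size != x.size:
        raise ValueError("times must align with the interval series")
    grid = np.arange(t[0], t[-1], 1.0 / cfg.resample_rate)
    if cfg.interpolation == "cubic":
        return CubicSpline(t, x)(grid)
    return interp1d(t, x, kind="linear")(grid)


def welch_band_powers(
    rri, cfg: SpectralConfig | None = None, times: np.ndarray | None = None
) -> dict[str, float]:
    """LF/HF band powers (ms^2) and their ratio from a Welch periodogram.

    Segments are mean-removed before windowing (trend handling is owned by
    the detrending stage).  Band powers are trapezoidal integrals of the
    one-sided PSD; the 0.15 Hz boundary bin belongs to HF.
    """
    cfg = cfg or SpectralConfig()
    cfg.validate()
    y = resample_tachogram(rri, cfg, times=times)
    if y.size < 2 * cfg.segment_length:
        raise ValueError(
            f"series too short for spectral analysis: need at least "
            f"{cfg.min_duration:.0f} s of resampled signal"
        )
    freqs, psd = sps.welch(
        y,
        fs=cfg.resample_rate,
        window=cfg.window,
        nperseg=cfg.segment_length,
        noverlap=int(cfg.segment_length * cfg.overlap),
        nfft=cfg.nfft,
        detrend="constant",
        scaling="density",
    )

    def band_power(lo: float, hi: float, include_hi: bool) -> float:
        if include_hi:
            mask = (freqs >= lo) & (freqs <= hi)
        else:
            mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]) * 1e6)  # s^2 -> ms^2

    lf = band_power(*cfg.lf_band, include_hi=False)
    hf = band_power(*cfg.hf_band, include_hi=True)
    ratio = lf / hf if hf > 0 else math.inf
    return {"lf": lf, "hf": hf, "lf_hf": ratio}


def _match_counts(templates: np.ndarray, r: float, include_self: bool) -> np.ndarray:
    """Per-template Chebyshev match counts within ``templates``."""
    dist = np.max(np.abs(templates[:, None, :] - templates[None, :, :]), axis=-1)
    counts = np.sum(dist <= r, axis=1).astype(float)
    if not include_self:
        counts -= 1.0
    return counts


def apen(series, cfg: EntropyConfig | None = None) -> float:
    """Approximate entropy: Phi_m(r) - Phi_{m+1}(r), self-matches included."""
    cfg = cfg or EntropyConfig()
    cfg.validate()
    x = _as_array(series, min_len=10 * cfg.m)
    r = cfg.r * np.std(x, ddof=1)

    def phi(m: int) -> float:
        templates = np.lib.stride_tricks.sliding_window_view(x, m)
        c = _match_counts(templates, r, include_self=True) / templates.shape[0]
        return float(np.mean(np.log(c)))

    return phi(cfg.m) - phi(cfg.m + 1)


def sampen(series, cfg: EntropyConfig | None = None) -> float:
    """Sample entropy: -ln(A/B) with self-matches excluded.

    A and B count template pairs over the same N - m templates at dimensions
    m + 1 and m respectively, so a perfectly regular series (every m-match
    extends to an (m+1)-match) gives exactly 0.  Returns ``inf`` when no
    pair matches at dimension m + 1; callers flag rather than fail on it.
    """
    cfg = cfg or EntropyConfig()
    cfg.validate()
    x = _as_array(series, min_len=10 * cfg.m)
    r = cfg.r * np.std(x, ddof=1)
    m = cfg.m
    n_templ = x.size - m  # shared template count at both dimensions
    tm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templ]
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    b = float(np.sum(_match_counts(tm, r, include_self=False)))
    a = float(np.sum(_match_counts(tm1, r, include_self=False)))
    if a == 0 or b == 0:
        return math.inf
    return float(-np.log(a / b))
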