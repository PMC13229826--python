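"""Synthetic RRI series, ECG traces and two-group cohorts.

Every downstream stage of the pipeline is testable against this module
without any recorded data.  The tachogram model is additive:

    RR_i = mean_rr + LF sinusoid + HF sinusoid + slow trend + skewed jitter

where the LF (default 0.10 Hz) and HF (default 0.25 Hz) oscillations emulate
baroreflex and respiratory modulation, the slow trend (default 0.01 Hz, below
the LF band) emulates the non-stationary drift the detrending stage is meant
to remove, and the jitter is a mean-reverting process whose successive-
difference innovations follow a two-sided exponential with unequal rates.

``asym_skew`` is the single heart-rate-asymmetry dial.  A positive value
(a) biases the jitter innovations so decelerations (positive successive
differences) become more frequent but smaller and accelerations rarer but
larger, and (b) skews the respiratory waveform by phase modulation,
``sin(phi + skew * sin(phi))``, producing the gradual-deceleration /
brisk-acceleration cycling seen in vagally mediated rhythms.  The frequency
bias moves the count-based Porta index; the waveform bias moves the
angle- and area-based slope/area indices of the detrended residual, while
the distance-based Guzik index stays near balance (the up- and down-distance
sums of any series telescope to its endpoint difference).

Cohort generation draws one tachogram per subject with group-specific
parameters plus covariates (age, menopausal status, PR status, Ki-67 status)
so that the full pipeline and the statistics layer can be run end to end.
``generate_metric_cohort`` additionally draws subject-level *metric values*
directly, with controllable standardized group shifts and covariate
confounding; it exists for calibrating the statistics layer with many
replicates where re-running the signal pipeline would add nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .core import ECGRecord, RRISeries

__all__ = [
    "RRIGenParams",
    "CohortGenParams",
    "CohortSubject",
    "ArtifactInjection",
    "generate_rri",
    "inject_artifacts",
    "synthesize_ecg",
    "generate_cohort",
    "generate_metric_cohort",
]

# mean-reversion coefficient of the jitter process; close to 1 so that the
# successive differences inherit the skew of the innovations
_JITTER_AR = 0.9


@dataclass(frozen=True)
class RRIGenParams:
    """Parameters of the additive tachogram model.

    Defaults target a resting 5-minute recording at a mean heart rate of
    ~73 bpm (mean RR 0.82 s, ~366 beats) with SDNN in the high-20s ms and
    RMSSD in the mid-teens ms, i.e. the order of magnitude of short resting
    recordings in middle-aged adults.
    """

    mean_rr: float = 0.82
    n_beats: int = 366
    lf_amp: float = 0.013
    lf_freq: float = 0.10
    hf_amp: float = 0.015
    hf_freq: float = 0.25
    trend_amp: float = 0.025
    trend_freq: float = 0.01
    jitter_sd: float = 0.012
    asym_skew: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.3 < self.mean_rr < 2.0:
            raise ValueError(f"mean_rr must lie in (0.3, 2.0) s, got {self.mean_rr}")
        if self.n_beats < 1:
            raise ValueError("n_beats must be positive")
        for name in ("lf_amp", "hf_amp", "trend_amp", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.asym_skew <= 1.0:
            raise ValueError("asym_skew must lie in [-1, 1]")
        if self.jitter_sd > 0 and abs(self.asym_skew) == 1.0:
            raise ValueError("asym_skew of +/-1 leaves no zero-mean jitter law")


@dataclass(frozen=True)
class CohortGenParams:
    """Two-group cohort with group effects and a Table-1-like covariate model.

    ``ai_effect`` shifts the positive group's ``asym_skew`` downward (the
    positive group shows *less* spatial asymmetry), ``complexity_effect``
    shrinks its jitter and trend amplitudes (less complex, more stereotyped
    rhythm).  Covariates are drawn per group and by default do not feed back
    into the signal (effects enter only through group); ``confound_strength``
    adds a covariate-driven component for ANCOVA testing.
    """

    n_pos: int = 142
    n_neg: int = 76
    ai_effect: float = 0.0
    complexity_effect: float = 0.0
    base: RRIGenParams = field(default_factory=lambda: RRIGenParams(asym_skew=0.6))
    age_mean_pos: float = 51.6
    age_sd_pos: float = 10.2
    age_mean_neg: float = 48.9
    age_sd_neg: float = 9.7
    menopause_prev: tuple[float, float] = (0.556, 0.329)  # (positive, negative)
    pr_prev: tuple[float, float] = (0.486, 0.632)
    ki67_prev: tuple[float, float] = (0.787, 0.526)
    confound_strength: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("each group needs at least 2 subjects")
        for name in ("menopause_prev", "pr_prev", "ki67_prev"):
            for p in getattr(self, name):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name} prevalence outside [0, 1]")


class CohortSubject(NamedTuple):
    subject_id: str
    rri: RRISeries
    group: int  # 1 = positive, 0 = negative
    covariates: dict


class ArtifactInjection(NamedTuple):
    rri: RRISeries
    positions: np.ndarray  # index of the premature interval of each pair


def _skewed_innovations(rng: np.random.Generator, n: int, sd: float, skew: float) -> np.ndarray:
    """Zero-mean two-sided exponential innovations with unequal rates.

    Positive side drawn with probability (1+skew)/2 and proportionally
    smaller scale, so the mean stays zero while positive jumps become more
    frequent and smaller as ``skew`` grows.
    """
    if sd == 0:
        return np.zeros(n)
    w_pos = (1.0 + skew) / 2.0
    w_neg = 1.0 - w_pos
    # zero mean requires w_pos * beta_pos == w_neg * beta_neg == c;
    # E[X^2] = 2 c^2 / (w_pos w_neg) fixes c for the target sd
    c = sd * np.sqrt(w_pos * w_neg / 2.0)
    signs = np.where(rng.random(n) < w_pos, 1.0, -1.0)
    scales = np.where(signs > 0, c / w_pos, c / w_neg)
    return signs * rng.exponential(1.0, size=n) * scales


def generate_rri(params: RRIGenParams) -> RRISeries:
    """Generate one synthetic tachogram under the additive model.

    Deterministic under a fixed seed.  Raises ``ValueError`` if the composed
    parameters could ever produce a non-positive interval.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    i = np.arange(params.n_beats)
    t = i * params.mean_rr  # nominal beat times for the oscillator phases
    rr = np.full(params.n_beats, params.mean_rr)
    rr += params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t)
    # respiratory component with waveform skew: phase modulation steepens the
    # accelerating flank and stretches the decelerating one for skew > 0
    phi = 2 * np.pi * params.hf_freq * t
    rr += params.hf_amp * np.sin(phi + params.asym_skew * np.sin(phi))
    rr += params.trend_amp * np.sin(2 * np.pi * params.trend_freq * t)

    if params.jitter_sd > 0:
        innov_sd = params.jitter_sd * np.sqrt(1.0 - _JITTER_AR**2)
        d = _skewed_innovations(rng, params.n_beats, innov_sd, params.asym_skew)
        jitter = np.empty(params.n_beats)
        acc = 0.0
        for k in range(params.n_beats):
            acc = _JITTER_AR * acc + d[k]
            jitter[k] = acc
        rr += jitter

    if np.any(rr <= 0):
        raise ValueError(
            "parameter combination produced a non-positive RR interval; "
            "reduce amplitudes or jitter_sd relative to mean_rr"
        )
    return RRISeries(rr, provenance="raw")


def inject_artifacts(rri: RRISeries, ectopic_rate: float, seed: int) -> ArtifactInjection:
    """Replace random beats with a premature/compensatory interval pair.

    Each eligible interval ``i`` is independently selected with probability
    ``ectopic_rate``; the pair ``(i, i+1)`` is rewritten to ``0.6 * RR_i`` and
    ``1.4 * RR_i``, mimicking an ectopic beat with compensatory pause.
    Overlapping selections are dropped greedily so pairs never share an
    interval.  Selected positions are returned so QC recall is measurable.
    """
    if not 0.0 <= ectopic_rate <= 0.2:
        raise ValueError("ectopic_rate must lie in [0, 0.2]")
    intervals = rri.intervals.copy()
    n = intervals.size
    rng = np.random.default_rng(seed)
    if ectopic_rate == 0 or n < 2:
        return ArtifactInjection(
            RRISeries(intervals, provenance=rri.provenance), np.empty(0, dtype=int)
        )
    candidates = np.flatnonzero(rng.random(n - 1) < ectopic_rate)
    positions: list[int] = []
    last = -2
    for idx in candidates:
        if idx - last < 2:  # would overlap the previous pair
            continue
        base = intervals[idx]
        intervals[idx] = 0.6 * base
        intervals[idx + 1] = 1.4 * base
        positions.append(int(idx))
        last = idx
    return ArtifactInjection(
        RRISeries(intervals, provenance=rri.provenance),
        np.asarray(positions, dtype=int),
    )


def _qrs_template(fs: float, width: float = 0.080) -> np.ndarray:
    """Narrow biphasic pulse (Ricker wavelet) ~``width`` seconds wide."""
    sigma = width / 6.0  # support ~ +/- 3 sigma
    t = np.arange(-3 * sigma, 3 * sigma + 1.0 / fs, 1.0 / fs)
    x = (t / sigma) ** 2
    return (1.0 - x) * np.exp(-x / 2.0)


def synthesize_ecg(
    rri: RRISeries,
    fs: float = 400.0,
    qrs_amp: float = 1.0,
    noise_sd: float = 0.0,
    wander_amp: float = 0.0,
    seed: int = 0,
    twave_amp: float = 0.0,
    wander_freq: float = 0.33,
) -> tuple[ECGRecord, np.ndarray]:
    """Render a template-based ECG trace from a tachogram.

    QRS complexes (biphasic, ~80 ms wide) are centred at cumulative beat
    times; an optional T-wave bump follows each R by 250 ms; a sub-0.5 Hz
    baseline-wander sinusoid and white noise are added on top.  Returns the
    trace and the true R-peak sample indices.
    """
    if fs < 100:
        raise ValueError("fs must be at least 100 Hz")
    if wander_freq >= 0.5:
        raise ValueError("baseline wander must stay below 0.5 Hz")
    rng = np.random.default_rng(seed)
    margin = 0.5  # seconds of padding before the first and after the last R
    r_times = margin + np.concatenate(([0.0], np.cumsum(rri.intervals)))
    n_samples = int(np.ceil((r_times[-1] + margin) * fs))
    x = np.zeros(n_samples)

    template = qrs_amp * _qrs_template(fs)
    half = template.size // 2
    r_indices = np.round(r_times * fs).astype(np.int64)
    for r in r_indices:
        lo, hi = r - half, r - half + template.size
        s_lo, s_hi = max(lo, 0), min(hi, n_samples)
        x[s_lo:s_hi] += template[s_lo - lo : template.size - (hi - s_hi)]

    if twave_amp > 0:
        t_sigma = 0.05
        t_rel = np.arange(-3 * t_sigma, 3 * t_sigma + 1.0 / fs, 1.0 / fs)
        t_shape = twave_amp * np.exp(-0.5 * (t_rel / t_sigma) ** 2)
        t_half = t_shape.size // 2
        for r in r_indices:
            c = r + int(round(0.25 * fs))
            lo, hi = c - t_half, c - t_half + t_shape.size
            s_lo, s_hi = max(lo, 0), min(hi, n_samples)
            if s_lo < s_hi:
                x[s_lo:s_hi] += t_shape[s_lo - lo : t_shape.size - (hi - s_hi)]

    t_axis = np.arange(n_samples) / fs
    if wander_amp > 0:
        x += wander_amp * np.sin(2 * np.pi * wander_freq * t_axis)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n_samples)

    record = ECGRecord(x, fs=fs, subject_id=None)
    return record, r_indices


def _group_params(
    base: RRIGenParams, group: int, params: CohortGenParams, covariates: dict, seed: int
) -> RRIGenParams:
    """Per-subject generator parameters given group label and covariates."""
    skew = base.asym_skew - (params.ai_effect if group == 1 else 0.0)
    ce = params.complexity_effect if group == 1 else 0.0
    # reduced complexity = shrunken broadband jitter plus a slightly longer
    # mean RR at fixed recording duration: fewer Poincare points directly
    # lowers grid occupancy and its log-count-dominated entropy
    jitter = base.jitter_sd * (1.0 - ce)
    trend = base.trend_amp
    mean_rr = base.mean_rr * (1.0 + 0.05 * ce)
    duration = base.n_beats * base.mean_rr
    if params.confound_strength != 0.0:
        # older / postmenopausal subjects get proportionally less variability
        age_z = (covariates["age"] - 50.0) / 10.0
        factor = max(0.2, 1.0 - params.confound_strength * 0.25 * age_z)
        jitter *= factor
        trend *= factor
    return replace(
        base,
        asym_skew=float(np.clip(skew, -0.99, 0.99)),
        jitter_sd=jitter,
        trend_amp=trend,
        mean_rr=mean_rr,
        n_beats=int(round(duration / mean_rr)),
        seed=seed,
    )


def generate_cohort(params: CohortGenParams) -> list[CohortSubject]:
    """Draw a full two-group cohort of tachograms with covariates.

    Positive-group subjects come first (ids ``P0001`` ...), then negative
    (``N0001`` ...).  Bit-identical under a fixed seed.
    """
    params.validate()
    root = np.random.SeedSequence(params.seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    subject_seeds = root.generate_state(params.n_pos + params.n_neg) >> 1  # keep < 2**31

    subjects: list[CohortSubject] = []
    k = 0
    for group, n, prefix in ((1, params.n_pos, "P"), (0, params.n_neg, "N")):
        age_mu = params.age_mean_pos if group == 1 else params.age_mean_neg
        age_sd = params.age_sd_pos if group == 1 else params.age_sd_neg
        idx = 0 if group == 1 else 1
        for j in range(n):
            covariates = {
                "age": float(np.round(cov_rng.normal(age_mu, age_sd), 1)),
                "menopause": int(cov_rng.random() < params.menopause_prev[idx]),
                "pr": int(cov_rng.random() < params.pr_prev[idx]),
                "ki67": int(cov_rng.random() < params.ki67_prev[idx]),
            }
            gp = _group_params(params.base, group, params, covariates, int(subject_seeds[k]))
            subjects.append(
                CohortSubject(f"{prefix}{j + 1:04d}", generate_rri(gp), group, covariates)
            )
            k += 1
    return subjects


def generate_metric_cohort(
    n_pos: int = 142,
    n_neg: int = 76,
    effects: dict[str, float] | None = None,
    confounded_metrics: dict[str, float] | None = None,
    metrics: tuple[str, ...] = ("ai_detrended", "gdr_raw", "gde_raw", "sdnn_raw"),
    seed: int = 0,
    heavy_tailed: bool = False,
    cov_params: CohortGenParams | None = None,
):
    """Draw subject-level metric values directly, on a standardized scale.

    Each metric column is unit-variance noise (normal, or Student-t with 3 df
    when ``heavy_tailed``) plus ``effects[metric]`` added to the positive
    group — i.e. ``effects`` are standardized group differences (Cohen's d).
    ``confounded_metrics[metric] = beta`` instead adds ``beta * menopause``
    with *no* direct group term, so any marginal group difference is driven
    entirely by the covariate's differing prevalence between groups: the
    scenario ANCOVA adjustment is supposed to absorb.

    Returns a wide :class:`pandas.DataFrame` suitable for
    :class:`~hrvpoincare.core.CohortTable`.
    """
    import pandas as pd

    effects = effects or {}
    confounded_metrics = confounded_metrics or {}
    cp = cov_params or CohortGenParams(n_pos=n_pos, n_neg=n_neg)
    rng = np.random.default_rng(seed)

    group = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    age = np.where(
        group == 1,
        rng.normal(cp.age_mean_pos, cp.age_sd_pos, group.size),
        rng.normal(cp.age_mean_neg, cp.age_sd_neg, group.size),
    )
    prev = {"menopause": cp.menopause_prev, "pr": cp.pr_prev, "ki67": cp.ki67_prev}
    covs = {
        name: np.where(
            group == 1,
            (rng.random(group.size) < p[0]).astype(int),
            (rng.random(group.size) < p[1]).astype(int),
        )
        for name, p in prev.items()
    }

    data = {
        "subject_id": [f"S{i + 1:04d}" for i in range(group.size)],
        "group": group,
        "age": np.round(age, 1),
        **covs,
    }
    for m in metrics:
        if heavy_tailed:
            noise = rng.standard_t(3, group.size) / np.sqrt(3.0)  # unit variance
        else:
            noise = rng.standard_normal(group.size)
        col = noise + effects.get(m, 0.0) * group
        if m in confounded_metrics:
            col = col + confounded_metrics[m] * covs["menopause"]
        data[m] = col
    return pd.DataFrame(data)
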