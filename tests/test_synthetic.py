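"""Generator behaviour: determinism, composition, artifact injection,
cohort structure."""

import numpy as np
import pytest

from hrvpoincare import (
    CohortGenParams,
    RRIGenParams,
    asymmetry_metrics,
    generate_cohort,
    generate_metric_cohort,
    generate_rri,
    inject_artifacts,
    smoothness_priors_detrend,
    synthesize_ecg,
    welch_band_powers,
)


def test_degenerate_constant_series():
    p = RRIGenParams(mean_rr=0.8, n_beats=10, lf_amp=0, hf_amp=0, trend_amp=0,
                     jitter_sd=0, seed=0)
    rri = generate_rri(p)
    assert np.array_equal(rri.intervals, np.full(10, 0.8))


def test_determinism_and_seed_sensitivity():
    a = generate_rri(RRIGenParams(seed=5)).intervals
    b = generate_rri(RRIGenParams(seed=5)).intervals
    c = generate_rri(RRIGenParams(seed=6)).intervals
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        RRIGenParams(mean_rr=0.2).validate()
    with pytest.raises(ValueError):
        RRIGenParams(asym_skew=1.5).validate()
    with pytest.raises(ValueError):
        # huge trend swings the composition non-positive
        generate_rri(RRIGenParams(mean_rr=0.4, trend_amp=0.5, seed=0))


def test_hf_dominated_series_has_hf_power():
    p = RRIGenParams(lf_amp=0.0, hf_amp=0.03, trend_amp=0.0, jitter_sd=0.001,
                     n_beats=400, seed=1)
    powers = welch_band_powers(generate_rri(p))
    assert powers["hf"] > 10 * powers["lf"]


def test_null_skew_raw_indices_small_at_n3000():
    # Monte-Carlo: at asym_skew 0 every |X-50| index concentrates near 0
    hits = 0
    n_seeds = 40
    for s in range(n_seeds):
        rri = generate_rri(RRIGenParams(n_beats=3000, asym_skew=0.0, seed=s))
        a = asymmetry_metrics(rri)
        if max(a.pi, a.gi, a.si, a.ai) < 2.0:
            hits += 1
    assert hits / n_seeds >= 0.95


def test_artifact_injection_identity_and_counts(tachogram):
    out = inject_artifacts(tachogram, 0.0, seed=1)
    assert np.array_equal(out.rri.intervals, tachogram.intervals)
    assert out.positions.size == 0

    base = generate_rri(RRIGenParams(n_beats=301, jitter_sd=0, seed=0))
    out = inject_artifacts(base, 0.05, seed=3)
    # ~15 pairs expected from binomial(300, 0.05), generous band
    assert 5 <= out.positions.size <= 30
    for pos in out.positions:
        assert out.rri.intervals[pos] == pytest.approx(0.6 * base.intervals[pos])
        assert out.rri.intervals[pos + 1] == pytest.approx(1.4 * base.intervals[pos])


def test_injected_pair_violates_adjacent_change_rule():
    base = np.full(6, 0.8)
    from hrvpoincare import RRISeries

    out = inject_artifacts(RRISeries(base), 0.2, seed=12)
    if out.positions.size:
        i = out.positions[0]
        prem, comp = out.rri.intervals[i], out.rri.intervals[i + 1]
        assert prem == pytest.approx(0.48)
        assert comp == pytest.approx(1.12)
        assert abs(prem - 0.8) / 0.8 > 0.20
        assert abs(comp - prem) / prem > 0.20


def test_ecg_truth_alignment_noiseless(clean_ecg):
    ecg, truth = clean_ecg
    half = int(0.05 * ecg.fs)
    for r in truth[1:-1]:
        w = ecg.samples[r - half : r + half + 1]
        assert abs(int(np.argmax(w)) - half) <= 2  # within 5 ms of centre


def test_ecg_beat_count_scales_with_duration():
    rri = generate_rri(RRIGenParams(mean_rr=0.82, n_beats=365, jitter_sd=0, seed=0))
    _, truth = synthesize_ecg(rri, fs=400.0)
    assert truth.size == 366  # n intervals -> n+1 beats


def test_cohort_defaults_match_design():
    params = CohortGenParams(seed=3)
    cohort = generate_cohort(params)
    assert len(cohort) == 218
    assert sum(s.group for s in cohort) == 142
    meno_pos = np.mean([s.covariates["menopause"] for s in cohort if s.group == 1])
    meno_neg = np.mean([s.covariates["menopause"] for s in cohort if s.group == 0])
    # binomial SE ~ 0.04 / 0.055
    assert meno_pos == pytest.approx(0.556, abs=0.13)
    assert meno_neg == pytest.approx(0.329, abs=0.17)
    assert meno_pos > meno_neg


def test_cohort_bit_identical_under_seed():
    a = generate_cohort(CohortGenParams(n_pos=4, n_neg=3, seed=9))
    b = generate_cohort(CohortGenParams(n_pos=4, n_neg=3, seed=9))
    for sa, sb in zip(a, b):
        assert sa.subject_id == sb.subject_id
        assert np.array_equal(sa.rri.intervals, sb.rri.intervals)
        assert sa.covariates == sb.covariates


def test_ai_effect_monotone_in_detrended_ai():
    """Larger ai_effect widens the mean group difference in detrended AI."""
    diffs = []
    for effect in (0.0, 0.2, 0.4):
        gaps = []
        for seed in range(6):
            cohort = generate_cohort(
                CohortGenParams(n_pos=8, n_neg=8, ai_effect=effect, seed=seed)
            )
            ai = {0: [], 1: []}
            for s in cohort:
                det = smoothness_priors_detrend(s.rri)
                ai[s.group].append(asymmetry_metrics(det.series()).ai)
            gaps.append(np.mean(ai[0]) - np.mean(ai[1]))
        diffs.append(np.mean(gaps))
    assert diffs[0] < diffs[1] < diffs[2]


def test_metric_cohort_effects_and_confounding():
    df = generate_metric_cohort(effects={"ai_detrended": 0.5}, seed=1)
    pos = df[df.group == 1]["ai_detrended"]
    neg = df[df.group == 0]["ai_detrended"]
    assert (pos.mean() - neg.mean()) == pytest.approx(0.5, abs=0.45)

    dfc = generate_metric_cohort(confounded_metrics={"gdr_raw": 1.5}, seed=2)
    r = np.corrcoef(dfc["gdr_raw"], dfc["menopause"])[0, 1]
    assert r > 0.2
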