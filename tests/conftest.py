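import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hrvpoincare import RRIGenParams, generate_rri, synthesize_ecg


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def tachogram():
    """Default 5-minute synthetic tachogram."""
    return generate_rri(RRIGenParams(seed=42))


@pytest.fixture
def skewed_tachogram():
    return generate_rri(RRIGenParams(seed=42, asym_skew=0.6))


@pytest.fixture
def clean_ecg(tachogram):
    """Noiseless ECG with T waves, plus its true R-peak indices."""
    return synthesize_ecg(tachogram, fs=400.0, qrs_amp=1.0, twave_amp=0.2, seed=7)


def random_rri(rng, n, base=0.85, spread=0.12):
    """Short positive interval series for oracle-equivalence tests."""
    return base + spread * (rng.random(n) - 0.5)


def match_counts(truth, detected, tol):
    """Greedy one-to-one matching of detected peaks to truth within tol samples."""
    truth = np.asarray(truth)
    detected = np.asarray(detected)
    used = np.zeros(detected.size, dtype=bool)
    hits = 0
    for t in truth:
        if detected.size == 0:
            break
        d = np.abs(detected - t)
        d[used] = tol + 1
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            hits += 1
    recall = hits / truth.size if truth.size else 0.0
    precision = hits / detected.size if detected.size else 0.0
    return recall, precision
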