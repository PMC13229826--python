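"""Independent brute-force reference implementations.

Every function here computes its quantity straight from the textbook
definition with explicit Python loops (or a direct enumeration), sharing no
code with the package's vectorised implementations.  They exist solely as
oracles for equivalence tests.
"""

from __future__ import annotations

import math


def mean(xs):
    return sum(xs) / len(xs)


def sample_var(xs):
    m = mean(xs)
    return sum((x - m) ** 2 for x in xs) / (len(xs) - 1)


def sdnn_ms(xs):
    return math.sqrt(sample_var(xs)) * 1000.0


def rmssd_ms(xs):
    diffs = [xs[i + 1] - xs[i] for i in range(len(xs) - 1)]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs)) * 1000.0


def sd1_sd2_ms(xs):
    diffs = [xs[i + 1] - xs[i] for i in range(len(xs) - 1)]
    vd = sample_var(diffs)
    vx = sample_var(xs)
    sd1 = math.sqrt(vd / 2.0) * 1000.0
    sd2 = math.sqrt(max(2.0 * vx - vd / 2.0, 0.0)) * 1000.0
    return sd1, sd2


def asymmetry_indices(xs):
    """(PI, GI, SI, AI) as |X - 50| deviations, or None when degenerate."""
    pts = [(xs[i], xs[i + 1]) for i in range(len(xs) - 1)]
    off = [(x, y) for x, y in pts if y != x]
    if not off:
        return None
    sums = {"pi": [0.0, 0.0], "gi": [0.0, 0.0], "si": [0.0, 0.0], "ai": [0.0, 0.0]}
    for x, y in off:
        accel = y < x
        d = abs(y - x)
        theta_deg = abs(45.0 - math.degrees(math.atan2(y, x)))
        area = (x * x + y * y) * math.radians(theta_deg) / 2.0
        for key, w in (("pi", 1.0), ("gi", d), ("si", theta_deg), ("ai", area)):
            sums[key][0] += w if accel else 0.0
            sums[key][1] += w
    return tuple(
        abs(100.0 * acc / tot - 50.0) for acc, tot in
        (sums["pi"], sums["gi"], sums["si"], sums["ai"])
    )


def grid_occupancy(xs, n):
    """(gdr, gde) by explicitly testing every cell against every point."""
    pts = [(xs[i], xs[i + 1]) for i in range(len(xs) - 1)]
    coords = [c for p in pts for c in p]
    lo, hi = min(coords), max(coords)
    if hi == lo:
        return 1.0 / n**2, 0.0
    w = (hi - lo) / n
    counts = []
    for i in range(n):
        for j in range(n):
            c = 0
            for x, y in pts:
                in_x = (lo + i * w <= x < lo + (i + 1) * w) or (i == n - 1 and x == hi)
                in_y = (lo + j * w <= y < lo + (j + 1) * w) or (j == n - 1 and y == hi)
                if in_x and in_y:
                    c += 1
            if c:
                counts.append(c)
    total = len(pts)
    gde = -sum((c / total) * math.log(c / total) for c in counts)
    return len(counts) / n**2, gde


def _chebyshev(a, b):
    return max(abs(u - v) for u, v in zip(a, b))


def apen(xs, m=2, r_frac=0.2):
    n = len(xs)
    r = r_frac * math.sqrt(sample_var(xs))

    def phi(mm):
        templates = [xs[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            c = sum(1 for b in templates if _chebyshev(a, b) <= r)
            total += math.log(c / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen(xs, m=2, r_frac=0.2):
    n = len(xs)
    r = r_frac * math.sqrt(sample_var(xs))
    tm = [xs[i : i + m] for i in range(n - m)]
    tm1 = [xs[i : i + m + 1] for i in range(n - m)]

    def pairs(templates):
        c = 0
        for i in range(len(templates)):
            for j in range(len(templates)):
                if i != j and _chebyshev(templates[i], templates[j]) <= r:
                    c += 1
        return c

    b, a = pairs(tm), pairs(tm1)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def auc_by_pairs(pos, neg):
    """AUC as the fraction of (positive, negative) pairs won, ties half."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def squared_partial_correlation(y, g, covariates):
    """r^2 between y and g after regressing both on the covariates."""
    import numpy as np

    z = np.column_stack([np.ones(len(y)), *covariates])
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    rg = g - z @ np.linalg.lstsq(z, g, rcond=None)[0]
    return float((ry @ rg) ** 2 / ((ry @ ry) * (rg @ rg)))


def two_sample_t_power(d, n1, n2, alpha=0.05):
    """Analytic power of the two-sided two-sample t-test via noncentral t."""
    from scipy import stats as sst

    df = n1 + n2 - 2
    ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sst.t.ppf(1 - alpha / 2, df)
    return float(1 - sst.nct.cdf(tcrit, df, ncp) + sst.nct.cdf(-tcrit, df, ncp))
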