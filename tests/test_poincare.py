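"""Poincare graphical metrics: hand examples, oracles, symmetry and
invariance properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from hrvpoincare import (
    asymmetry_metrics,
    ellipse_metrics,
    grid_metrics,
    grid_metrics_at,
    poincare_points,
    sdnn,
)

series_strategy = st.lists(
    st.floats(min_value=0.4, max_value=1.8, allow_nan=False), min_size=5, max_size=40
).map(np.asarray)


class TestEllipse:
    def test_alternating_series_degenerate_sd2(self):
        x = np.array([0.8, 0.9] * 10)
        m = ellipse_metrics(x)
        # exact alternation makes the SD2 radicand marginally negative
        # (ddof asymmetry between the two variances): clipped and flagged
        assert m.sd2 == 0.0 and m.sd2_clipped
        assert m.sd1 > 60.0
        assert math.isnan(m.ratio)
        # a whisper of drift restores a tiny positive major axis
        drifted = x + 1e-4 * np.arange(x.size)
        md = ellipse_metrics(drifted)
        assert md.ratio > 10.0

    def test_constant_series_flagged(self):
        m = ellipse_metrics(np.full(10, 0.8))
        assert m.sd1 == 0.0 and m.sd2 == 0.0
        assert math.isnan(m.ratio)

    @given(series_strategy)
    @settings(max_examples=50, deadline=None)
    def test_variance_identity(self, x):
        m = ellipse_metrics(x)
        if not m.sd2_clipped:
            lhs = m.sd1**2 + m.sd2**2
            rhs = 2 * sdnn(x) ** 2
            assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_sd1_equals_sdsd_over_sqrt2(self, rng):
        x = 0.8 + 0.05 * rng.standard_normal(100)
        sdsd = np.std(np.diff(x), ddof=1) * 1000
        assert ellipse_metrics(x).sd1 == pytest.approx(sdsd / math.sqrt(2), rel=1e-12)


class TestAsymmetry:
    def test_mirror_symmetric_exactly_zero(self):
        a = asymmetry_metrics([0.8, 0.9, 0.8, 0.9, 0.8])
        assert (a.pi, a.gi, a.si, a.ai) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_example(self):
        a = asymmetry_metrics([0.8, 1.0, 0.9, 0.7])
        assert a.pi == pytest.approx(abs(100 * 2 / 3 - 50), abs=1e-9)
        assert a.gi == pytest.approx(10.0, abs=1e-9)

    def test_constant_series_degenerate(self):
        a = asymmetry_metrics(np.full(10, 0.8))
        assert a.degenerate
        assert math.isnan(a.pi)

    def test_point_counts(self):
        pts = poincare_points([0.8, 1.0, 0.9, 0.7])
        assert len(pts) == 3
        assert pts.n_accel == 2 and pts.n_decel == 1

    def test_swap_symmetry(self, rng):
        # reversing the series maps each point (x, y) to (y, x)
        x = 0.8 + 0.1 * rng.random(60)
        a, b = asymmetry_metrics(x), asymmetry_metrics(x[::-1])
        for k in ("pi", "gi", "si", "ai"):
            assert getattr(a, k) == pytest.approx(getattr(b, k), abs=1e-9)

    def test_scale_invariance(self, rng):
        x = 0.8 + 0.1 * rng.random(80)
        a, b = asymmetry_metrics(x), asymmetry_metrics(2.5 * x)
        for k in ("pi", "gi", "si", "ai"):
            assert getattr(a, k) == pytest.approx(getattr(b, k), rel=1e-9, abs=1e-9)

    def test_oracle_equivalence(self, rng):
        for _ in range(10):
            x = 0.8 + 0.15 * (rng.random(30) - 0.5)
            a = asymmetry_metrics(x)
            ref = oracles.asymmetry_indices(list(x))
            for got, want in zip((a.pi, a.gi, a.si, a.ai), ref):
                assert got == pytest.approx(want, abs=1e-10)

    def test_gi_mode_squared_differs(self, rng):
        x = 0.8 + 0.1 * rng.random(100)
        lin = asymmetry_metrics(x, gi_mode="linear").gi
        sq = asymmetry_metrics(x, gi_mode="squared").gi
        assert lin != pytest.approx(sq, abs=1e-6)


class TestGrid:
    def test_identical_points_single_cell(self):
        gdr, gde = grid_metrics_at(np.full(10, 0.8), 7)
        assert gdr == pytest.approx(1 / 49)
        assert gde == 0.0

    def test_four_quadrants_equal_occupancy(self):
        # chain 0.2 -> 0.2 -> 0.8 -> 0.8 -> 0.2 puts one point in each
        # quadrant of the bounding box
        x = np.array([0.2, 0.2, 0.8, 0.8, 0.2])
        gdr, gde = grid_metrics_at(x, 2)
        assert gdr == 1.0
        assert gde == pytest.approx(math.log(4), abs=1e-12)

    def test_oracle_equivalence(self, rng):
        for n in (2, 5, 9):
            x = 0.8 + 0.2 * (rng.random(20) - 0.5)
            got = grid_metrics_at(x, n)
            want = oracles.grid_occupancy(list(x), n)
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_multiresolution_average_and_traces(self, tachogram):
        g = grid_metrics(tachogram)
        assert g.n_values.size == 101
        assert g.gdr == pytest.approx(float(np.mean(g.gdr_trace)), rel=1e-12)
        assert 0.010 <= g.gdr <= 0.025
        assert 5.4 <= g.gde <= math.log(len(tachogram) - 1)

    def test_entropy_bounded_by_log_points(self, rng):
        x = 0.8 + 0.1 * rng.random(40)
        n_points = x.size - 1
        for n in (3, 10, 50, 200):
            _, gde = grid_metrics_at(x, n)
            assert gde <= math.log(n_points) + 1e-12

    def test_saturation_occupancy_counts_distinct_points(self, rng):
        x = 0.8 + 0.1 * rng.random(30)
        pts = poincare_points(x)
        n = 2000  # far beyond saturation for 29 generic points
        gdr, _ = grid_metrics_at(x, n)
        n_distinct = len({(a, b) for a, b in zip(pts.x, pts.y)})
        assert gdr * n**2 == pytest.approx(n_distinct)

    def test_scale_invariance(self, tachogram):
        g1 = grid_metrics(tachogram.intervals, 100, 110)
        g2 = grid_metrics(2.0 * tachogram.intervals, 100, 110)
        assert g1.gdr == pytest.approx(g2.gdr, rel=1e-12)
        assert g1.gde == pytest.approx(g2.gde, rel=1e-12)

    def test_constant_series_convention(self):
        g = grid_metrics(np.full(10, 0.8), 100, 200)
        assert g.degenerate
        assert g.gde == 0.0
        assert g.gdr == pytest.approx(float(np.mean(1.0 / np.arange(100, 201) ** 2)))
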