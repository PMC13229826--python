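"""Statistics layer: normality gate, effect sizes, ANCOVA, ROC."""

import numpy as np
import pytest

import oracles
from hrvpoincare import (
    CohortTable,
    ancova,
    build_report,
    chi_square,
    compare_groups,
    cv_roc,
    generate_metric_cohort,
    roc_auc,
)


class TestCompareGroups:
    def test_identical_groups(self, rng):
        x = rng.standard_normal(30)
        values = np.concatenate([x, x])
        labels = np.array([1] * 30 + [0] * 30)
        res = compare_groups(values, labels)
        assert res.p > 0.99
        assert res.cohens_d == pytest.approx(0.0, abs=1e-12)
        assert res.d_ci_low <= 0.0 <= res.d_ci_high

    def test_normality_gate_branches(self, rng):
        normal = np.concatenate([rng.standard_normal(60), rng.standard_normal(60) + 1])
        labels = np.array([1] * 60 + [0] * 60)
        assert compare_groups(normal, labels).test == "t"
        skewed = np.concatenate(
            [rng.exponential(1.0, 60), rng.exponential(1.0, 60) * 2]
        )
        assert compare_groups(skewed, labels).test == "mann-whitney"

    def test_d_recovery_and_ci_coverage(self):
        """d-hat averages near truth and the 95% CI covers it ~95% of the time."""
        true_d, n1, n2, reps = 0.4, 142, 76, 300
        rng = np.random.default_rng(17)
        labels = np.array([1] * n1 + [0] * n2)
        ds, covered = [], 0
        for _ in range(reps):
            values = np.concatenate(
                [rng.standard_normal(n1) + true_d, rng.standard_normal(n2)]
            )
            res = compare_groups(values, labels)
            ds.append(res.cohens_d)
            covered += res.d_ci_low <= true_d <= res.d_ci_high
        assert np.mean(ds) == pytest.approx(true_d, abs=0.03)
        assert 0.91 <= covered / reps <= 0.985

    def test_zero_pooled_sd_flagged(self):
        values = np.array([1.0] * 6 + [1.0] * 6)
        labels = np.array([1] * 6 + [0] * 6)
        assert compare_groups(values, labels).d_flagged


class TestChiSquare:
    def test_perfect_independence(self):
        assert chi_square([[30, 30], [30, 30]]) == pytest.approx(1.0)

    def test_menopause_counts_significant(self):
        # yes/no split of two groups with very different prevalence
        assert chi_square([[79, 63], [25, 51]]) < 0.01

    def test_empty_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [10, 20]])


def _table_from_metric_df(df):
    return CohortTable(df)


class TestAncova:
    def test_null_calibration(self):
        rejections = 0
        reps = 300
        for seed in range(reps):
            df = generate_metric_cohort(
                n_pos=60, n_neg=40, metrics=("ai_detrended",), seed=seed
            )
            res = ancova(_table_from_metric_df(df), "ai", "detrended")
            rejections += res.p_adjusted < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)

    def test_group_effect_recovered(self):
        hits = 0
        reps = 150
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            df = generate_metric_cohort(
                n_pos=80, n_neg=60, metrics=("ai_detrended",), seed=seed
            )
            df["ai_detrended"] += 0.5 * df["group"] + 0.3 * (
                (df["age"] - df["age"].mean()) / df["age"].std()
            )
            res = ancova(_table_from_metric_df(df), "ai", "detrended")
            hits += res.p_adjusted < 0.05
        assert hits / reps > 0.7  # d=0.5 at n=140 with adjustment: high power

    def test_partial_eta_sq_is_squared_partial_correlation(self):
        df = generate_metric_cohort(
            effects={"ai_detrended": 0.4}, metrics=("ai_detrended",), seed=5
        )
        res = ancova(_table_from_metric_df(df), "ai", "detrended")
        want = oracles.squared_partial_correlation(
            df["ai_detrended"].to_numpy(float),
            df["group"].to_numpy(float),
            [df[c].to_numpy(float) for c in ("age", "menopause", "pr", "ki67")],
        )
        assert res.partial_eta_sq == pytest.approx(want, abs=1e-9)

    def test_collinear_covariates_named(self):
        df = generate_metric_cohort(metrics=("ai_detrended",), seed=2)
        df["age2"] = df["age"] * 2.0
        table = CohortTable(df, covariates=("age", "age2", "menopause"))
        with pytest.raises(ValueError, match="age"):
            ancova(table, "ai", "detrended")


class TestRoc:
    def test_perfect_separation(self):
        values = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert roc_auc(values, labels).auc == 1.0

    def test_interleaved_pairs(self):
        values = np.array([1.0, 3, 2, 4])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(values, labels, orientation="higher_in_positive").auc == 0.75

    def test_rank_auc_equals_pair_enumeration(self, rng):
        for _ in range(20):
            pos = rng.integers(0, 10, size=12).astype(float)  # ties included
            neg = rng.integers(0, 10, size=9).astype(float)
            values = np.concatenate([pos, neg])
            labels = np.array([1] * 12 + [0] * 9)
            got = roc_auc(values, labels, orientation="higher_in_positive").auc
            assert got == pytest.approx(oracles.auc_by_pairs(pos, neg), abs=1e-12)

    def test_auto_orientation_recorded(self, rng):
        values = np.concatenate([rng.standard_normal(30) - 2, rng.standard_normal(30)])
        labels = np.array([1] * 30 + [0] * 30)
        res = roc_auc(values, labels)
        assert res.orientation == "lower_in_positive"
        assert res.auc > 0.5

    def test_cv_perfect_separation(self):
        values = np.concatenate([np.linspace(2, 3, 40), np.linspace(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        res = cv_roc(values, labels, k=10, seed=0)
        assert res.cv_auc == 1.0
        assert res.cv_sensitivity == 1.0 and res.cv_specificity == 1.0

    def test_cv_deterministic_under_seed(self, rng):
        values = rng.standard_normal(100)
        labels = (rng.random(100) < 0.5).astype(int)
        a = cv_roc(values, labels, k=5, seed=3)
        b = cv_roc(values, labels, k=5, seed=3)
        assert a.cv_auc == b.cv_auc
        assert a.cv_sensitivity == b.cv_sensitivity


class TestBuildReport:
    def test_report_shapes_and_selection_rule(self):
        df = generate_metric_cohort(
            effects={"ai_detrended": 0.6},
            metrics=("ai_detrended", "sdnn_raw", "apen_raw", "gdr_raw"),
            seed=8,
        )
        report = build_report(CohortTable(df), seed=1)
        assert len(report.comparisons) == 4
        assert "ai" in set(report.ancova["metric"])
        # only sub-alpha metrics enter the ANCOVA table
        sig = set(
            report.comparisons.query("p < 0.05")[["metric", "condition"]]
            .apply(tuple, axis=1)
        )
        anc = set(report.ancova[["metric", "condition"]].apply(tuple, axis=1))
        assert anc == sig
        assert report.meta["multiple_testing_correction"].startswith("none")

    def test_no_signal_empty_ancova(self):
        df = generate_metric_cohort(metrics=("sdnn_raw",), seed=123)
        report = build_report(CohortTable(df), seed=1)
        if (report.comparisons["p"] >= 0.05).all():
            assert len(report.ancova) == 0
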