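"""Group-comparison statistics: normality-gated tests, effect sizes,
covariate-adjusted ANCOVA, and cross-validated ROC.

The comparison of each metric between the two groups follows a fixed
protocol: Shapiro-Wilk normality per group at alpha = 0.05; Student's t-test
when both groups pass, Mann-Whitney U otherwise; Cohen's d (pooled sample
SD) with a 95% CI from the large-sample standard error

    SE(d) = sqrt((n1 + n2) / (n1 n2) + d^2 / (2 (n1 + n2))).

ANCOVA fits ``metric ~ group + covariates`` by OLS; the adjusted p-value is
the t-test of the binary group coefficient (equivalent to a Type-III test
for a two-level factor) and partial eta^2 = SS_group / (SS_group + SS_resid).

ROC analysis uses the rank (Mann-Whitney) AUC with tie correction; the
cross-validated variant fits a univariable logistic score per stratified
fold, pools validation scores, and reports the pooled AUC plus sensitivity
and specificity at the Youden-optimal threshold.

No multiple-testing correction is applied anywhere (the metric panel is
geometrically inter-correlated, making family-wise corrections overly
conservative for an exploratory comparison); report metadata states this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core import CONDITIONS, METRIC_NAMES, CohortTable

__all__ = [
    "ComparisonResult",
    "AncovaResult",
    "RocResult",
    "StatsReport",
    "compare_groups",
    "chi_square",
    "ancova",
    "roc_auc",
    "cv_roc",
    "build_report",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    metric: str
    condition: str
    test: str  # "t" or "mann-whitney"
    p: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    summary_pos: str
    summary_neg: str
    d_flagged: bool = False  # zero pooled SD


@dataclass
class AncovaResult:
    metric: str
    condition: str
    p_unadjusted: float
    p_adjusted: float
    partial_eta_sq: float
    covariates: tuple[str, ...]


@dataclass
class RocResult:
    metric: str
    auc: float
    orientation: str  # "higher_in_positive" or "lower_in_positive"
    cv_auc: float | None = None
    cv_sensitivity: float | None = None
    cv_specificity: float | None = None
    folds: int | None = None
    seed: int | None = None


@dataclass
class StatsReport:
    comparisons: pd.DataFrame
    ancova: pd.DataFrame
    roc: list[RocResult]
    meta: dict = field(default_factory=dict)


def _summaries(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{np.mean(x):.3g} ± {np.std(x, ddof=1):.3g}"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.3g} ({q1:.3g}, {q3:.3g})"


def cohens_d_ci(d: float, n1: int, n2: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation confidence interval for Cohen's d."""
    se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    z = sst.norm.ppf(0.5 + level / 2)
    return d - z * se, d + z * se


def compare_groups(
    values: np.ndarray,
    labels: np.ndarray,
    metric: str = "",
    condition: str = "",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    ``labels`` are 1 for the positive group, 0 for the negative.  Cohen's d
    (positive minus negative, pooled SD) is computed regardless of which
    test the gate selects.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos, neg = values[labels == 1], values[labels == 0]
    if pos.size < 3 or neg.size < 3:
        raise ValueError("need at least 3 observations per group")

    normal = (sst.shapiro(pos).pvalue > alpha) and (sst.shapiro(neg).pvalue > alpha)
    if normal:
        test, p = "t", float(sst.ttest_ind(pos, neg, equal_var=True).pvalue)
    else:
        test, p = "mann-whitney", float(
            sst.mannwhitneyu(pos, neg, alternative="two-sided").pvalue
        )

    n1, n2 = pos.size, neg.size
    pooled_var = ((n1 - 1) * np.var(pos, ddof=1) + (n2 - 1) * np.var(neg, ddof=1)) / (
        n1 + n2 - 2
    )
    flagged = pooled_var == 0
    if flagged:
        d, lo, hi = math.nan, math.nan, math.nan
    else:
        d = float((np.mean(pos) - np.mean(neg)) / math.sqrt(pooled_var))
        lo, hi = cohens_d_ci(d, n1, n2)

    return ComparisonResult(
        metric=metric,
        condition=condition,
        test=test,
        p=p,
        cohens_d=d,
        d_ci_low=lo,
        d_ci_high=hi,
        summary_pos=_summaries(pos, normal),
        summary_neg=_summaries(neg, normal),
        d_flagged=bool(flagged),
    )


def chi_square(counts: np.ndarray, correction: bool = False) -> float:
    """Pearson chi-square p-value for a 2x2 contingency table.

    Continuity correction is off by default.  Raises on an empty margin.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("expected a 2x2 contingency table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has an empty margin")
    return float(sst.chi2_contingency(counts, correction=correction).pvalue)


def ancova(
    table: CohortTable,
    metric: str,
    condition: str,
    covariates: tuple[str, ...] | None = None,
    p_unadjusted: float = math.nan,
) -> AncovaResult:
    """Covariate-adjusted group comparison via OLS.

    Binary covariates are coded 0/1 and group enters as a 0/1 fixed factor;
    the adjusted p is the t-test of the group coefficient.  Partial eta^2 is
    the group sum of squares over group-plus-residual sums of squares,
    computed by comparing the full model with the model omitting group.
    """
    covariates = covariates or table.covariates
    col = f"{metric}_{condition}"
    df = table.data[["group", *covariates, col]].dropna()
    if len(df) < len(covariates) + 3:
        raise ValueError("too few complete cases for ANCOVA")

    design = sm.add_constant(df[["group", *covariates]].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify offending columns by leave-one-out rank
        offenders = [
            c
            for c in design.columns
            if c != "const"
            and np.linalg.matrix_rank(design.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"collinear covariates: {offenders}")

    y = df[col].astype(float)
    full = sm.OLS(y, design).fit()
    reduced = sm.OLS(y, design.drop(columns="group")).fit()
    ss_group = reduced.ssr - full.ssr
    partial_eta_sq = float(ss_group / (ss_group + full.ssr))
    return AncovaResult(
        metric=metric,
        condition=condition,
        p_unadjusted=p_unadjusted,
        p_adjusted=float(full.pvalues["group"]),
        partial_eta_sq=partial_eta_sq,
        covariates=tuple(covariates),
    )


def roc_auc(values: np.ndarray, labels: np.ndarray, orientation: str = "auto") -> RocResult:
    """Rank-based AUC with tie correction.

    ``orientation="auto"`` flips the score when the positive group tends to
    have lower values and records the direction used; pass
    ``"higher_in_positive"`` or ``"lower_in_positive"`` to fix it.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos, neg = values[labels == 1], values[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = sst.rankdata(values)  # midranks give the tie-corrected AUC
    auc = (np.sum(ranks[labels == 1]) - pos.size * (pos.size + 1) / 2) / (
        pos.size * neg.size
    )
    auc = float(auc)
    if orientation == "auto":
        orientation = "higher_in_positive" if auc >= 0.5 else "lower_in_positive"
    if orientation == "lower_in_positive":
        auc = 1.0 - auc
    return RocResult(metric="", auc=auc, orientation=orientation)


def _stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(labels.size), labels)]


def cv_roc(
    values: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    seed: int = 0,
    orientation: str = "auto",
) -> RocResult:
    """Stratified k-fold cross-validated ROC for a single metric.

    Per fold, a univariable logistic score is fit on the training subjects
    and applied to the held-out subjects.  The cross-validated AUC is the
    mean of the per-fold validation AUCs (a pooled-score AUC carries a
    pessimistic bias under weak signal, because fold-specific score shifts
    anti-correlate with the held-out labels).  The logistic model orients
    its own score toward the positive class, so fold AUCs are evaluated
    as-is — under permuted labels they must be free to fall below 0.5.
    Sensitivity and specificity are whole-cohort counts at the
    Youden-optimal threshold of the pooled validation scores.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels, dtype=int)
    if min(np.bincount(labels, minlength=2)) < k:
        raise ValueError("each fold needs both classes; reduce k")

    scores = np.empty(labels.size)
    fold_aucs = []
    for test_idx in _stratified_folds(labels, k, seed):
        train = np.ones(labels.size, dtype=bool)
        train[test_idx] = False
        model = LogisticRegression(max_iter=1000)
        model.fit(values[train], labels[train])
        scores[test_idx] = model.predict_proba(values[test_idx])[:, 1]
        fold_aucs.append(
            roc_auc(scores[test_idx], labels[test_idx],
                    orientation="higher_in_positive").auc
        )

    cv_auc_value = float(np.mean(fold_aucs))
    if orientation == "auto":
        orientation = "higher_in_positive" if cv_auc_value >= 0.5 else "lower_in_positive"

    # Youden-optimal operating point on the pooled validation scores
    s = scores
    thresholds = np.unique(s)
    best_j, best_sens, best_spec = -np.inf, math.nan, math.nan
    n_pos, n_neg = int(np.sum(labels == 1)), int(np.sum(labels == 0))
    for thr in thresholds:
        pred = s >= thr
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        if sens + spec - 1 > best_j:
            best_j, best_sens, best_spec = sens + spec - 1, sens, spec

    return RocResult(
        metric="",
        auc=cv_auc_value,
        orientation=orientation,
        cv_auc=cv_auc_value,
        cv_sensitivity=float(best_sens),
        cv_specificity=float(best_spec),
        folds=k,
        seed=seed,
    )


def build_report(
    table: CohortTable,
    headline_metric: tuple[str, str] = ("ai", "detrended"),
    comparator_metrics: tuple[tuple[str, str], ...] = (("sdnn", "raw"), ("apen", "raw")),
    alpha: float = ALPHA,
    cv_folds: int = 10,
    seed: int = 0,
) -> StatsReport:
    """Full statistics report: comparisons, gated ANCOVA, and ROC panels.

    Every available (metric, condition) pair is compared; metrics with an
    unadjusted p below ``alpha`` proceed to ANCOVA; ROC (apparent and
    cross-validated) is run for the headline metric and its comparators.
    """
    available = [
        (m, c)
        for c in CONDITIONS
        for m in METRIC_NAMES
        if f"{m}_{c}" in table.data.columns
    ]
    labels = table.labels

    comp_rows = []
    for m, c in available:
        res = compare_groups(table.values(m, c), labels, metric=m, condition=c, alpha=alpha)
        comp_rows.append(vars(res))
    comparisons = pd.DataFrame(comp_rows)

    anc_rows = []
    for _, row in comparisons.iterrows():
        if np.isfinite(row["p"]) and row["p"] < alpha:
            res = ancova(
                table, row["metric"], row["condition"], p_unadjusted=float(row["p"])
            )
            anc_rows.append(vars(res))
    anc_cols = ["metric", "condition", "p_unadjusted", "p_adjusted",
                "partial_eta_sq", "covariates"]
    ancova_df = pd.DataFrame(anc_rows, columns=anc_cols)

    roc_results = []
    for m, c in (headline_metric, *comparator_metrics):
        if f"{m}_{c}" not in table.data.columns:
            continue
        vals = table.values(m, c)
        apparent = roc_auc(vals, labels)
        result = RocResult(
            metric=f"{m}_{c}",
            auc=apparent.auc,
            orientation=apparent.orientation,
        )
        if int(np.bincount(labels, minlength=2).min()) >= cv_folds:
            cv = cv_roc(vals, labels, k=cv_folds, seed=seed,
                        orientation=apparent.orientation)
            result.cv_auc = cv.cv_auc
            result.cv_sensitivity = cv.cv_sensitivity
            result.cv_specificity = cv.cv_specificity
            result.folds = cv_folds
            result.seed = seed
        roc_results.append(result)

    return StatsReport(
        comparisons=comparisons,
        ancova=ancova_df,
        roc=roc_results,
        meta={
            "alpha": alpha,
            "multiple_testing_correction": "none (uncorrected p-values reported)",
            "cv_folds": cv_folds,
            "seed": seed,
        },
    )
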