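"""Per-stratum summaries, rank tests between grades, cross-dataset pooling.

Group comparison uses the two-sided Wilcoxon rank-sum (Mann-Whitney U)
test between independent severity groups: exact null distribution when both
groups have n <= 25 and no ties, normal approximation with tie and
continuity corrections otherwise.  Confidence intervals default to the
Student-t interval on the mean; a seeded percentile bootstrap is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from lesioncount.types import (
    GRADES,
    MEASURE_COLUMNS,
    SeverityGrade,
    ValidationError,
)

#: significance thresholds, most stringent first
_LABEL_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

EXACT_MAX_N = 25
BOOTSTRAP_RESAMPLES = 2000


@dataclass(frozen=True)
class StratumSummary:
    """Mean and 95% CI of one measure in one (dataset, grade) stratum."""

    dataset_id: str
    grade: SeverityGrade
    lesion: str
    n: int
    mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairwiseTestResult:
    """Two-sided rank-sum comparison of one measure between two grades."""

    dataset_id: str
    lesion: str
    grade_a: SeverityGrade
    grade_b: SeverityGrade
    statistic: float
    p_value: float
    label: str
    n_a: int
    n_b: int
    method: str


@dataclass(frozen=True)
class WeightedSummary:
    """Sample-size-weighted cross-dataset mean and pooled 95% CI."""

    grade: SeverityGrade
    lesion: str
    pooled_mean: float
    ci_low: float
    ci_high: float
    total_n: int
    weights: dict[str, float]


def significance_label(p: float) -> str:
    """Map a p-value to the figure labels ***, **, * or NS."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p-value {p} outside [0, 1]")
    for threshold, label in _LABEL_THRESHOLDS:
        if p < threshold:
            return label
    return "NS"


def _measure_values(table: pd.DataFrame, lesion: str) -> pd.Series:
    try:
        col = MEASURE_COLUMNS[lesion]
    except KeyError:
        raise ValidationError(
            f"unknown measure {lesion!r}; expected one of {sorted(MEASURE_COLUMNS)}"
        ) from None
    return table[col].astype(float)


def _stratum(table: pd.DataFrame, dataset_id: str | None, grade: SeverityGrade) -> pd.DataFrame:
    sel = table["grade"] == grade
    if dataset_id is not None:
        sel &= table["dataset_id"] == dataset_id
    return table.loc[sel]


def _mean_ci(
    values: np.ndarray,
    method: str = "t",
    seed: int | None = None,
) -> tuple[float, float, float]:
    mean = float(values.mean())
    n = len(values)
    if n < 2 or np.ptp(values) == 0:
        return mean, mean, mean
    if method == "t":
        half = sps.t.ppf(0.975, n - 1) * values.std(ddof=1) / np.sqrt(n)
        return mean, mean - float(half), mean + float(half)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(values, size=(BOOTSTRAP_RESAMPLES, n), replace=True).mean(axis=1)
        lo, hi = np.quantile(means, [0.025, 0.975])
        return mean, float(lo), float(hi)
    raise ValidationError(f"unknown CI method {method!r}")


def stratum_summary(
    table: pd.DataFrame,
    dataset_id: str | None,
    grade: SeverityGrade,
    lesion: str,
    ci_method: str = "t",
    seed: int | None = None,
) -> StratumSummary | None:
    """Mean and 95% CI of one measure in one stratum; None if empty.

    ``dataset_id=None`` pools all datasets.  A single observation yields a
    degenerate CI equal to the mean.
    """
    sub = _stratum(table, dataset_id, grade)
    values = _measure_values(sub, lesion).dropna().to_numpy()
    if len(values) == 0:
        return None
    mean, lo, hi = _mean_ci(values, method=ci_method, seed=seed)
    return StratumSummary(
        dataset_id=dataset_id if dataset_id is not None else "all",
        grade=grade,
        lesion=lesion,
        n=len(values),
        mean=mean,
        ci_low=lo,
        ci_high=hi,
    )


def wilcoxon_pairwise(
    table: pd.DataFrame,
    dataset_id: str | None,
    lesion: str,
    grade_a: SeverityGrade,
    grade_b: SeverityGrade,
) -> PairwiseTestResult | None:
    """Two-sided rank-sum test of one measure between two severity grades.

    Returns None when either stratum is empty (datasets lacking a grade).
    Two groups with a single shared constant value (e.g. all-zero hemorrhage
    counts at no-DR and mild) have no evidence either way: p = 1, NS.
    """
    x = _measure_values(_stratum(table, dataset_id, grade_a), lesion).dropna().to_numpy()
    y = _measure_values(_stratum(table, dataset_id, grade_b), lesion).dropna().to_numpy()
    if len(x) == 0 or len(y) == 0:
        return None
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        statistic, p, method = len(x) * len(y) / 2.0, 1.0, "degenerate"
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        statistic, p = float(res.statistic), float(min(res.pvalue, 1.0))
    return PairwiseTestResult(
        dataset_id=dataset_id if dataset_id is not None else "all",
        lesion=lesion,
        grade_a=grade_a,
        grade_b=grade_b,
        statistic=statistic,
        p_value=p,
        label=significance_label(p),
        n_a=len(x),
        n_b=len(y),
        method=method,
    )


def adjacent_grade_tests(
    table: pd.DataFrame,
    dataset_id: str | None,
    lesion: str,
    pairs: str = "adjacent",
) -> list[PairwiseTestResult]:
    """Rank-sum tests for adjacent grade pairs (default) or all pairs."""
    if pairs == "adjacent":
        grade_pairs = list(zip(GRADES[:-1], GRADES[1:]))
    elif pairs == "all":
        grade_pairs = [(a, b) for i, a in enumerate(GRADES) for b in GRADES[i + 1 :]]
    else:
        raise ValidationError(f"pairs must be 'adjacent' or 'all', got {pairs!r}")
    results = []
    for a, b in grade_pairs:
        res = wilcoxon_pairwise(table, dataset_id, lesion, a, b)
        if res is not None:
            results.append(res)
    return results


def weighted_mean_across_datasets(
    table: pd.DataFrame,
    grade: SeverityGrade,
    lesion: str,
    ci_method: str = "t",
    seed: int | None = None,
) -> WeightedSummary | None:
    """Pool one stratum across datasets with sample-size weights.

    pooled_mean = sum(w_i * mean_i) with w_i proportional to the dataset's
    stratum n — identical to the mean of the pooled records; the CI is
    computed on the pooled sample.  None if no dataset contributes.
    """
    sub = _stratum(table, None, grade)
    values = _measure_values(sub, lesion)
    present = values.notna()
    if not present.any():
        return None
    contributing = sub.loc[present]
    per_dataset_n = contributing.groupby("dataset_id")["image_id"].count()
    total = int(per_dataset_n.sum())
    weights = {str(ds): float(n) / total for ds, n in per_dataset_n.items()}
    pooled = values[present].to_numpy()
    mean, lo, hi = _mean_ci(pooled, method=ci_method, seed=seed)
    return WeightedSummary(
        grade=grade,
        lesion=lesion,
        pooled_mean=mean,
        ci_low=lo,
        ci_high=hi,
        total_n=total,
        weights=weights,
    )


def summarize_all(
    table: pd.DataFrame,
    ci_method: str = "t",
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy frame of per-(dataset, grade, measure) summaries."""
    rows = []
    for dataset_id in sorted(table["dataset_id"].unique()):
        for grade in GRADES:
            for lesion in MEASURE_COLUMNS:
                s = stratum_summary(table, dataset_id, grade, lesion, ci_method, seed)
                if s is not None:
                    rows.append(
                        {
                            "dataset_id": s.dataset_id,
                            "grade": s.grade.label,
                            "lesion": s.lesion,
                            "n": s.n,
                            "mean": s.mean,
                            "ci_low": s.ci_low,
                            "ci_high": s.ci_high,
                        }
                    )
    return pd.DataFrame(rows)


def weighted_summary_frame(
    table: pd.DataFrame,
    ci_method: str = "t",
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy frame of cross-dataset weighted summaries per (grade, measure)."""
    rows = []
    for grade in GRADES:
        for lesion in MEASURE_COLUMNS:
            w = weighted_mean_across_datasets(table, grade, lesion, ci_method, seed)
            if w is not None:
                rows.append(
                    {
                        "grade": w.grade.label,
                        "lesion": w.lesion,
                        "pooled_mean": w.pooled_mean,
                        "ci_low": w.ci_low,
                        "ci_high": w.ci_high,
                        "total_n": w.total_n,
                    }
                )
    return pd.DataFrame(rows)


def pairwise_frame(
    table: pd.DataFrame,
    pairs: str = "adjacent",
    per_dataset: bool = True,
) -> pd.DataFrame:
    """Tidy frame of rank-sum results, per dataset and pooled."""
    dataset_ids: list[str | None] = [None]
    if per_dataset:
        dataset_ids += sorted(table["dataset_id"].unique())
    rows = []
    for dataset_id in dataset_ids:
        for lesion in MEASURE_COLUMNS:
            for res in adjacent_grade_tests(table, dataset_id, lesion, pairs=pairs):
                rows.append(
                    {
                        "dataset_id": res.dataset_id,
                        "lesion": res.lesion,
                        "grade_a": res.grade_a.label,
                        "grade_b": res.grade_b.label,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "label": res.label,
                        "n_a": res.n_a,
                        "n_b": res.n_b,
                        "method": res.method,
                    }
                )
    return pd.DataFrame(rows)


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjustment (off by default in the pipeline)."""
    order = np.argsort(p_values)
    m = len(p_values)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_values[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()
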