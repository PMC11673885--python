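"""Outlier exclusion of count records with the 1.5*IQR rule.

Records whose MA or Hma count falls outside ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]``
of their stratum are excluded.  Stratification defaults to dataset x grade
(pooling grades would systematically delete severe cases, whose counts are
legitimately large); per-dataset and global modes are available for
sensitivity checks.  HE values never trigger exclusion.  Filtering is a
single pass: bounds are computed once on the input table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lesioncount.types import SeverityGrade, ValidationError, as_grade

logger = logging.getLogger(__name__)

#: lesions the exclusion rule inspects
FILTER_LESIONS = ("MA", "Hma")
_FILTER_COLUMNS = {"MA": "ma_count", "Hma": "hma_count"}

#: quantile conventions exposed in config; "linear" is numpy's default
#: (interpolation between closest ranks, a.k.a. type 7)
QUANTILE_METHODS = ("linear", "lower", "higher", "midpoint", "nearest")

#: minimum stratum size for meaningful quartiles
MIN_STRATUM_N = 4


@dataclass(frozen=True)
class IqrBounds:
    """Quartiles and exclusion bounds for one stratum/lesion.

    ``degenerate`` marks strata too small to filter (< 4 values): the
    stratum passes unfiltered.
    """

    q1: float
    q3: float
    lower: float
    upper: float
    n: int
    degenerate: bool = False

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    def outside(self, value: float) -> bool:
        if self.degenerate or value is None or np.isnan(value):
            return False
        return value < self.lower or value > self.upper


@dataclass
class StratumFilter:
    """Audit record of the rule applied to one (dataset, grade, lesion)."""

    dataset_id: str
    grade: SeverityGrade | None
    lesion: str
    bounds: IqrBounds
    excluded_image_ids: list[str]
    n_before: int
    n_after: int


@dataclass
class FilterReport:
    """Full audit of one filtering pass."""

    strata: list[StratumFilter] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (dataset_id, image_id)
    n_before: int = 0
    n_after: int = 0

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    @property
    def excluded_fraction(self) -> float:
        return self.n_excluded / self.n_before if self.n_before else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            rows.append(
                {
                    "dataset_id": s.dataset_id,
                    "grade": s.grade.label if s.grade is not None else "all",
                    "lesion": s.lesion,
                    "q1": s.bounds.q1,
                    "q3": s.bounds.q3,
                    "iqr": s.bounds.iqr,
                    "lower": s.bounds.lower,
                    "upper": s.bounds.upper,
                    "degenerate": s.bounds.degenerate,
                    "n_before": s.n_before,
                    "n_after": s.n_after,
                    "excluded_image_ids": ";".join(s.excluded_image_ids),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "dataset_id", "grade", "lesion", "q1", "q3", "iqr", "lower",
                "upper", "degenerate", "n_before", "n_after", "excluded_image_ids",
            ],
        )


def compute_iqr_bounds(values, quantile_method: str = "linear") -> IqrBounds:
    """Quartiles and 1.5*IQR exclusion bounds of a value list.

    Fewer than 4 non-missing values yields a degenerate (no-filter) sentinel
    with a logged warning instead of unstable quartiles.
    """
    if quantile_method not in QUANTILE_METHODS:
        raise ValidationError(
            f"unknown quantile method {quantile_method!r}; expected {QUANTILE_METHODS}"
        )
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(arr) < MIN_STRATUM_N:
        logger.warning(
            "stratum with %d non-missing values (< %d): passes unfiltered",
            len(arr), MIN_STRATUM_N,
        )
        return IqrBounds(
            q1=float("nan"), q3=float("nan"),
            lower=-np.inf, upper=np.inf, n=len(arr), degenerate=True,
        )
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=quantile_method)
    iqr = q3 - q1
    return IqrBounds(
        q1=float(q1), q3=float(q3),
        lower=float(q1 - 1.5 * iqr), upper=float(q3 + 1.5 * iqr),
        n=len(arr),
    )


def filter_outliers(
    table: pd.DataFrame,
    stratify: str = "dataset_grade",
    quantile_method: str = "linear",
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove records whose MA or Hma count violates its stratum's bounds.

    Returns the filtered table and an auditable :class:`FilterReport`;
    filtered rows plus excluded rows partition the input exactly.
    """
    if stratify not in ("dataset_grade", "dataset", "global"):
        raise ValidationError(f"unknown stratification mode {stratify!r}")
    report = FilterReport(n_before=len(table))
    if stratify == "dataset_grade":
        groups = table.groupby(["dataset_id", "grade"], sort=True, observed=True)
        keys = [(ds, gr) for (ds, gr) in groups.groups]
    elif stratify == "dataset":
        groups = table.groupby(["dataset_id"], sort=True, observed=True)
        keys = [(ds[0] if isinstance(ds, tuple) else ds, None) for ds in groups.groups]
    else:
        groups = None
        keys = [("all", None)]

    drop_mask = pd.Series(False, index=table.index)
    group_frames = (
        {k: groups.get_group(k) for k in groups.groups} if groups is not None else {"all": table}
    )
    for key, (dataset_id, grade) in zip(group_frames, keys):
        sub = group_frames[key]
        for lesion in FILTER_LESIONS:
            col = _FILTER_COLUMNS[lesion]
            bounds = compute_iqr_bounds(sub[col], quantile_method=quantile_method)
            values = sub[col].astype(float)
            violates = values.notna() & ((values < bounds.lower) | (values > bounds.upper))
            if bounds.degenerate:
                violates[:] = False
            excluded_ids = sub.loc[violates, "image_id"].tolist()
            report.strata.append(
                StratumFilter(
                    dataset_id=str(dataset_id),
                    grade=as_grade(grade) if grade is not None else None,
                    lesion=lesion,
                    bounds=bounds,
                    excluded_image_ids=excluded_ids,
                    n_before=len(sub),
                    n_after=len(sub) - int(violates.sum()),
                )
            )
            drop_mask.loc[sub.index[violates]] = True

    dropped = table.loc[drop_mask]
    report.excluded = list(
        dict.fromkeys(zip(dropped["dataset_id"], dropped["image_id"]))
    )
    filtered = table.loc[~drop_mask].reset_index(drop=True)
    report.n_after = len(filtered)
    return filtered, report
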