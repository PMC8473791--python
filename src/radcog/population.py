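"""Group-level descriptive statistics and the Mann-Whitney comparison.

These are the population analyses behind the bar/box plots: per-arm mean
with its standard error, box-plot five-number summaries with 1.5 x IQR
outliers, and two-sample Mann-Whitney U tests of each irradiated arm
against sham.  The tests are per-comparison; no multiplicity correction
is applied across stages or doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

# exact-enumeration budget for the Mann-Whitney null (number of label
# assignments C(nA+nB, nA) we are willing to enumerate)
_EXACT_BUDGET = 200_000


@dataclass(frozen=True)
class GroupSummary:
    ion: str
    dose_cgy: float
    n: int
    mean: float
    sem: float
    median: float
    q1: float
    q3: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def summarize_group(
    scores: Sequence[float], ion: str = "", dose_cgy: float = 0.0
) -> GroupSummary:
    """Mean/SEM, quartiles and 1.5xIQR box-plot outliers for one arm."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty group")
    n = arr.size
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    q1, median, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = tuple(float(v) for v in arr[(arr < lo) | (arr > hi)])
    return GroupSummary(ion, dose_cgy, n, mean, sem, median, q1, q3, outliers)


def summary_table(scores: pd.DataFrame, value_column: str = "atrc") -> pd.DataFrame:
    """GroupSummary rows per (ion, dose) from a long score table."""
    rows = []
    for (ion, dose), grp in scores.groupby(["ion", "dose_cgy"], sort=True):
        values = grp[value_column].dropna()
        if values.empty:
            continue
        s = summarize_group(values, ion, dose)
        rows.append(
            {
                "ion": s.ion,
                "dose_cgy": s.dose_cgy,
                "n": s.n,
                "mean": s.mean,
                "sem": s.sem,
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "n_outliers": len(s.outliers),
            }
        )
    return pd.DataFrame(rows)


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U for group A, p-value).

    U is computed by rank summation with midranks for ties.  With
    ``method="auto"`` the p-value is exact (full enumeration of label
    assignments) for small tie-free samples and otherwise uses the normal
    approximation with tie correction and continuity correction.  Two
    identical pooled samples give p = 1 by convention.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = (
            "exact"
            if not has_ties and comb(a.size + b.size, a.size) <= _EXACT_BUDGET
            else "asymptotic"
        )
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def group_comparisons(
    scores: pd.DataFrame,
    value_column: str = "atrc",
    reference_ion: str = "sham",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney of every non-reference (ion, dose) arm against sham."""
    ref = scores.loc[scores["ion"] == reference_ion, value_column].dropna()
    if ref.empty:
        raise ValueError(f"no {reference_ion} scores to compare against")
    rows = []
    for (ion, dose), grp in scores.groupby(["ion", "dose_cgy"], sort=True):
        if ion == reference_ion:
            continue
        values = grp[value_column].dropna()
        if values.empty:
            continue
        u, p = mann_whitney(values, ref)
        rows.append(
            {
                "ion": ion,
                "dose_cgy": dose,
                "n": len(values),
                "n_ref": len(ref),
                "U": u,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
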