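"""Impairment thresholds from the sham cohort's empirical CDF.

Step 1 of the subject-level analysis: the non-irradiated (sham) cohort
defines "normal" performance.  The impairment threshold for a stage/score
is set so that at least a fraction ``level`` (default 95%) of sham
subjects fall strictly below it; any subject scoring at or above the
threshold is labeled impaired.  Because the scores are lower-is-better,
this singles out the worst-performing (1 - level) tail.

The two phrasings of the rule — "the score at or below which 95% of sham
pass" and "scores at or above the threshold are impaired" — conflict at
the threshold value itself.  The default (``tie_rule="strict_below"``)
takes the smallest grid value with strictly-below sham mass >= level,
which guarantees that at most (1 - level) of sham are ever labeled
impaired and matches the ">= threshold => impaired" labeling contract.
The alternative inclusive reading is available as
``tie_rule="at_or_below"``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCORE_TYPES = ("ATRC", "MCL")


class EmpiricalCDF:
    """Right-continuous step function F(s) = fraction of scores <= s."""

    def __init__(self, scores: Sequence[float]):
        arr = np.asarray(list(scores), dtype=float)
        if arr.size == 0:
            raise ValueError("empirical CDF requires at least one score")
        if not np.all(np.isfinite(arr)):
            raise ValueError("scores must be finite")
        self._sorted = np.sort(arr)
        self.n = arr.size

    def __call__(self, s) -> np.ndarray | float:
        s = np.asarray(s, dtype=float)
        out = np.searchsorted(self._sorted, s, side="right") / self.n
        return float(out) if out.ndim == 0 else out

    def fraction_below(self, s) -> np.ndarray | float:
        """Fraction of scores strictly below s."""
        s = np.asarray(s, dtype=float)
        out = np.searchsorted(self._sorted, s, side="left") / self.n
        return float(out) if out.ndim == 0 else out

    @property
    def support(self) -> np.ndarray:
        return self._sorted


def empirical_cdf(scores: Sequence[float]) -> EmpiricalCDF:
    return EmpiricalCDF(scores)


@dataclass(frozen=True)
class ImpairmentRule:
    """Stage + score type + threshold; impaired <=> score >= threshold."""

    stage: str
    score_type: str
    level: float
    threshold: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ImpairmentRule":
        return cls(d["stage"], d["score_type"], float(d["level"]), float(d["threshold"]))


def _candidate_grid(scores: np.ndarray, grid: str) -> np.ndarray:
    if grid == "integer":
        lo, hi = int(np.floor(scores.min())), int(np.ceil(scores.max()))
        return np.arange(lo, hi + 2, dtype=float)
    if grid == "observed":
        uniq = np.unique(scores)
        # one value past the maximum so a degenerate sample still yields a
        # threshold that labels zero sham impaired
        return np.append(uniq, uniq[-1] + 1.0)
    raise ValueError(f"unknown grid {grid!r}")


def derive_threshold(
    sham_scores: Sequence[float],
    level: float = 0.95,
    stage: str = "SD",
    score_type: str = "ATRC",
    grid: str = "integer",
    tie_rule: str = "strict_below",
) -> ImpairmentRule:
    """Threshold from sham scores only; see module docstring for semantics."""
    if not 0.0 < level <= 1.0:
        raise ValueError(f"level must lie in (0, 1], got {level}")
    cdf = empirical_cdf(sham_scores)
    candidates = _candidate_grid(cdf.support, grid)
    if tie_rule == "strict_below":
        mass = cdf.fraction_below(candidates)
    elif tie_rule == "at_or_below":
        mass = cdf(candidates)
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    ok = np.nonzero(mass >= level - 1e-12)[0]
    threshold = float(candidates[ok[0]])
    return ImpairmentRule(stage=stage, score_type=score_type, level=level, threshold=threshold)


def label_impairment(score: float | None, rule: ImpairmentRule) -> bool | None:
    """True iff score >= threshold; a missing score yields no label."""
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return None
    return bool(score >= rule.threshold)


def percent_impaired(
    scores: pd.DataFrame, rule: ImpairmentRule, score_column: str | None = None
) -> pd.DataFrame:
    """Per-(ion, dose) impairment percentages.

    ``scores`` needs columns ion, dose_cgy and the score column (default:
    the rule's score type, lower-cased, i.e. ``atrc`` or ``mcl_s``).
    Subjects with a missing score carry no label and are excluded from both
    numerator and denominator; empty groups report percent as missing.
    """
    col = score_column or {"ATRC": "atrc", "MCL": "mcl_s"}[rule.score_type]
    rows = []
    for (ion, dose), grp in scores.groupby(["ion", "dose_cgy"], sort=True):
        labels = [label_impairment(v, rule) for v in grp[col]]
        labeled = [l for l in labels if l is not None]
        n = len(labeled)
        n_imp = sum(labeled)
        rows.append(
            {
                "ion": ion,
                "dose_cgy": dose,
                "n": n,
                "n_impaired": n_imp,
                "percent_impaired": 100.0 * n_imp / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def label_table(
    scores: pd.DataFrame, rule: ImpairmentRule, score_column: str | None = None
) -> pd.DataFrame:
    """Subject-level labels under a rule; unlabelable subjects are dropped."""
    col = score_column or {"ATRC": "atrc", "MCL": "mcl_s"}[rule.score_type]
    out = scores.copy()
    out["impaired"] = [label_impairment(v, rule) for v in out[col]]
    out = out[out["impaired"].notna()].copy()
    out["impaired"] = out["impaired"].astype(int)
    return out
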