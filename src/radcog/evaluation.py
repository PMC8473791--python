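"""Leave-one-out cross-validation and the classification metric suite.

All curve metrics operate on pooled out-of-fold impairment scores: LOOCV
tests each subject once on a model trained on everyone else, and the N
held-out scores form a single ranking from which the ROC and PR curves
are built.  Hard metrics (accuracy, precision, recall, F1, MCC) come from
the confusion counts at a score cutoff (default 0.5, i.e. a subject is
called impaired when its score is at least 0.5).

Zero-denominator conventions: precision, recall and F1 are 0 when their
denominators vanish, and MCC is 0 when any confusion-matrix marginal is
zero — the value a random guess would earn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classifiers import class_weights


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels, scores, cutoff: float = 0.5) -> ConfusionCounts:
    """Confusion counts calling positive iff score >= cutoff."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("cannot build a confusion matrix from no samples")
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    pred = s >= cutoff
    pos = y == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def basic_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, F1 and MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    accuracy = (tp + tn) / c.total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "mcc": mcc,
    }


@dataclass(frozen=True)
class Curve:
    """An operating-characteristic curve with its generating cutoffs."""

    x: tuple[float, ...]
    y: tuple[float, ...]
    cutoffs: tuple[float, ...]
    auc: float
    baseline: float | None = None


def _ranked_counts(labels, scores):
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.size == 0:
        raise ValueError("labels and scores must be equal-length and non-empty")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # collapse tied scores: cumulative counts at each distinct cutoff
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.r_[distinct, y_sorted.size - 1]
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(1 - y_sorted)[idx]
    return s_sorted[idx], tps, fps, int(y.sum()), int((1 - y).sum())


def roc_curve(labels, scores) -> Curve:
    """ROC curve over all distinct cutoffs; AUC by the trapezoidal rule.

    With tied scores the curve steps diagonally through the tie block, so
    the trapezoidal area equals pairwise concordance with ties counted 1/2.
    """
    cuts, tps, fps, n_pos, n_neg = _ranked_counts(labels, scores)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return Curve(
        x=tuple(fpr), y=tuple(tpr), cutoffs=(math.inf, *cuts), auc=auc
    )


def pr_curve(labels, scores) -> Curve:
    """Precision-recall curve; AUC by step-wise summation over achievable
    operating points (no interpolation between PR pairs).  The no-skill
    baseline is the positive-class fraction."""
    cuts, tps, fps, n_pos, n_neg = _ranked_counts(labels, scores)
    if n_pos == 0:
        raise ValueError("PR curve requires at least one positive")
    recall = tps / n_pos
    precision = tps / (tps + fps)
    auc = float(np.sum(np.diff(np.r_[0.0, recall]) * precision))
    return Curve(
        x=tuple(recall),
        y=tuple(precision),
        cutoffs=tuple(cuts),
        auc=auc,
        baseline=n_pos / (n_pos + n_neg),
    )


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    auc_roc: float
    auc_pr: float
    pr_baseline: float

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
            "pr_baseline": self.pr_baseline,
        }


def metrics_report(labels, scores, cutoff: float = 0.5) -> MetricsReport:
    counts = confusion(labels, scores, cutoff)
    basics = basic_metrics(counts)
    roc = roc_curve(labels, scores)
    pr = pr_curve(labels, scores)
    return MetricsReport(
        counts=counts,
        auc_roc=roc.auc,
        auc_pr=pr.auc,
        pr_baseline=pr.baseline,
        **basics,
    )


@dataclass
class LOOCVResult:
    """Pooled out-of-fold scores plus bookkeeping about skipped folds."""

    scores: np.ndarray  # NaN where the fold was skipped or failed
    labels: np.ndarray
    skipped_folds: list[int] = field(default_factory=list)
    failed_folds: list[int] = field(default_factory=list)

    @property
    def evaluated(self) -> np.ndarray:
        return ~np.isnan(self.scores)


def loocv_scores(
    X,
    y,
    classifier_factory: Callable[[int], object],
    seed: int = 0,
) -> LOOCVResult:
    """Leave-one-out driver: N folds, each sample tested exactly once.

    ``classifier_factory(fold_seed)`` must return a fresh classifier with
    ``fit(X, y, class_weight)`` / ``predict_score(X)``.  Class weights are
    recomputed on every training fold.  A fold whose training set lacks a
    class is skipped; a fold whose classifier raises is recorded as failed
    and the run continues.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("LOOCV needs both classes present overall")
    out = np.full(n, np.nan)
    skipped: list[int] = []
    failed: list[int] = []
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        y_tr = y[mask]
        if len(np.unique(y_tr)) < 2:
            skipped.append(i)
            continue
        weights = class_weights(y_tr)
        fold_seed = (seed * 100_003 + i) % (2**31 - 1)
        clf = classifier_factory(fold_seed)
        try:
            clf.fit(X[mask], y_tr, class_weight=weights)
            out[i] = float(clf.predict_score(X[i : i + 1])[0])
        except Exception:
            failed.append(i)
    return LOOCVResult(scores=out, labels=y, skipped_folds=skipped, failed_folds=failed)


def bootstrap_auc_ci(
    labels,
    scores,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the ROC AUC of a score vector.

    Resamples subjects with replacement; replicates that lose one of the
    classes are redrawn implicitly by being skipped.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    stats = []
    while len(stats) < n_boot:
        pick = rng.integers(0, y.size, y.size)
        yb = y[pick]
        if yb.min() == yb.max():
            continue
        stats.append(roc_curve(yb, s[pick]).auc)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def mean_ci_bootstrap(
    values: Sequence[float], n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean of a small sample (e.g. the
    per-seed AUCs of replicate synthetic cohorts)."""
    v = np.asarray(list(values), dtype=float)
    rng = np.random.default_rng(seed)
    means = v[rng.integers(0, v.size, (n_boot, v.size))].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)
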