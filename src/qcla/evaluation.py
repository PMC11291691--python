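"""Result-layer statistics.

Confusion matrices (rows = predicted class, columns = true condition),
per-class accuracy/precision/specificity/sensitivity/F1, overall accuracy,
a chi-square comparison of two classifiers' correct proportions with a phi
effect size, pooled-variance t-tests, two-tailed variance-ratio F-tests,
Pearson correlations and Bonferroni correction.

Metrics whose denominator is zero are *undefined* and carried as NaN, never
silently as 0; ``format_metric`` renders them as an en dash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CLASS_ORDER",
    "UNDEFINED",
    "ConfusionMatrix",
    "MetricsReport",
    "ComparisonResult",
    "confusion",
    "metrics_from_confusion",
    "overall_accuracy",
    "compare_proportions",
    "phi_from_chi2",
    "two_sample_t",
    "variance_f_test",
    "pearson",
    "bonferroni",
    "format_metric",
]

#: Fixed class ordering used by every confusion matrix and report.
CLASS_ORDER: tuple[str, ...] = ("harmony", "satisfaction", "depression", "anxiety")

#: Marker for a metric with a zero denominator.
UNDEFINED = float("nan")

_METRIC_NAMES = ("accuracy", "precision", "specificity", "sensitivity", "f1")


@dataclass
class ConfusionMatrix:
    """Predicted-by-true class counts."""

    counts: np.ndarray  # (n_classes, n_classes) ints; rows predicted, cols true
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.class_order)
        if self.counts.shape != (n, n):
            raise ValueError("confusion matrix shape does not match class order")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.class_order, name="predicted"),
            columns=pd.Index(self.class_order, name="true"),
        )


def confusion(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    class_order: tuple[str, ...] = CLASS_ORDER,
) -> ConfusionMatrix:
    """Tally predicted-by-true counts in a fixed class order."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, class_order)


@dataclass
class MetricsReport:
    """Per-class metric panel plus overall accuracy (NaN = undefined)."""

    per_class: pd.DataFrame  # rows metric names, columns classes
    overall_accuracy: float

    def metric(self, name: str, cls: str) -> float:
        return float(self.per_class.loc[name, cls])


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, specificity, sensitivity and F1 per class.

    For class c: TP = diagonal cell, FP = rest of its predicted row,
    FN = rest of its true column, TN = everything else. Any metric with a
    zero denominator is undefined (NaN).
    """
    counts = cm.counts
    n = cm.total
    if n < 1:
        raise ValueError("confusion matrix is empty")
    table = {}
    for i, cls in enumerate(cm.class_order):
        tp = counts[i, i]
        fp = counts[i, :].sum() - tp
        fn = counts[:, i].sum() - tp
        tn = n - tp - fp - fn
        sens = tp / (tp + fn) if tp + fn > 0 else UNDEFINED
        prec = tp / (tp + fp) if tp + fp > 0 else UNDEFINED
        spec = tn / (tn + fp) if tn + fp > 0 else UNDEFINED
        acc = (tp + tn) / n
        if math.isnan(sens) or math.isnan(prec) or prec + sens == 0:
            f1 = UNDEFINED
        else:
            f1 = 2 * prec * sens / (prec + sens)
        table[cls] = {
            "accuracy": acc,
            "precision": prec,
            "specificity": spec,
            "sensitivity": sens,
            "f1": f1,
        }
    frame = pd.DataFrame(table).loc[list(_METRIC_NAMES), list(cm.class_order)]
    return MetricsReport(per_class=frame, overall_accuracy=overall_accuracy(cm))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over grand total."""
    if cm.total < 1:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(cm.counts) / cm.total)


@dataclass
class ComparisonResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_size: float | None = None
    test_name: str = ""
    two_tailed: bool = True


def phi_from_chi2(chi2: float, n: int) -> float:
    """Phi effect size sqrt(chi2 / N) for a 2x2 table."""
    if n <= 0:
        raise ValueError("N must be positive")
    return math.sqrt(chi2 / n)


def compare_proportions(
    correct_a: int,
    n_a: int,
    correct_b: int,
    n_b: int,
    phi_n: int | None = None,
) -> ComparisonResult:
    """Pearson chi-square comparing two correct/incorrect proportions.

    2x2 table of correct vs incorrect counts, df = 1, no continuity
    correction. ``phi_n`` overrides the N used for the phi effect size
    (defaults to the table total), so a published phi computed under a
    different N convention can be reproduced.
    """
    if not (0 <= correct_a <= n_a and 0 <= correct_b <= n_b):
        raise ValueError("correct counts must lie within their sample sizes")
    table = np.array(
        [[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return ComparisonResult(
            UNDEFINED, 1, UNDEFINED, UNDEFINED, "chi2_proportions"
        )
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    n = phi_n if phi_n is not None else int(table.sum())
    return ComparisonResult(
        statistic=float(chi2),
        df=float(df),
        p_value=float(p),
        effect_size=phi_from_chi2(float(chi2), n),
        test_name="chi2_proportions",
    )


def two_sample_t(
    x: Sequence[float], y: Sequence[float], two_tailed: bool = True
) -> ComparisonResult:
    """Pooled-variance independent-samples t-test, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    df = x.size + y.size - 2
    pooled = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled == 0:
        return ComparisonResult(UNDEFINED, df, UNDEFINED, None, "t_pooled", two_tailed)
    res = stats.ttest_ind(x, y, equal_var=True)
    p = float(res.pvalue) if two_tailed else float(res.pvalue) / 2
    return ComparisonResult(float(res.statistic), df, p, None, "t_pooled", two_tailed)


def variance_f_test(
    x: Sequence[float], y: Sequence[float], two_tailed: bool = True
) -> ComparisonResult:
    """Variance-ratio F-test, F = s_x^2 / s_y^2, df = (n1-1, n2-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dfn, dfd = x.size - 1, y.size - 1
    if vx == 0 or vy == 0:
        return ComparisonResult(UNDEFINED, (dfn, dfd), UNDEFINED, None, "f_variance", two_tailed)
    f = vx / vy
    cdf = stats.f.cdf(f, dfn, dfd)
    p = 2 * min(cdf, 1 - cdf) if two_tailed else 1 - cdf
    return ComparisonResult(float(f), (dfn, dfd), float(min(p, 1.0)), None, "f_variance", two_tailed)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its t-based two-tailed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("pearson requires n >= 3")
    if x.var() == 0 or y.var() == 0:
        return UNDEFINED, UNDEFINED
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Per-test significance flags at the family-wise level alpha.

    Flag i is true iff p_i <= alpha / m with m the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return p <= alpha / p.size


def format_metric(value: float, digits: int = 2) -> str:
    """Render a metric, using an en dash for undefined values."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "–"
    return f"{value:.{digits}f}"
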