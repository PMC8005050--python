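"""Confusion tallies and one-vs-rest predictability metrics.

Per behavior category c the confusion matrix yields TP (true c predicted
c), FP (other categories predicted c), FN (true c predicted otherwise) and
TN (the rest), from which

    accuracy_c  = (TP + TN) / (TP + TN + FP + FN)
    precision_c = TP / (TP + FP)
    recall_c    = TP / (TP + FN)

Note the per-category "accuracy" is one-vs-rest over the full prediction
set — the true-negative term makes it a different (and larger) number than
the global fraction-correct many libraries call accuracy. Overall metrics
are unweighted arithmetic means over categories with defined values;
zero-denominator ratios are reported as not-applicable (NaN) and excluded
from the means.

The two devices' per-category accuracies are compared with the classical
paired t-test on the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps


@dataclass
class ConfusionMatrix:
    categories: list[str]
    counts: np.ndarray  # counts[true_index, predicted_index]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the category list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, category: str) -> int:
        try:
            return self.categories.index(category)
        except ValueError:
            raise KeyError(f"unknown category {category!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.categories, columns=self.categories
        )


def confusion(predictions: pd.DataFrame) -> ConfusionMatrix:
    """Tally (true, predicted) pairs over the union of observed categories."""
    if predictions.empty:
        raise ValueError("no predictions to tally")
    cats = sorted(set(predictions["true"]) | set(predictions["predicted"]))
    pos = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=int)
    for t, p in zip(predictions["true"], predictions["predicted"]):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(categories=cats, counts=counts)


def category_metrics(
    cm: ConfusionMatrix, category: str
) -> tuple[float, float, float]:
    """One-vs-rest (accuracy, precision, recall); NaN where undefined."""
    i = cm.index(category)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[:, i].sum() - tp)
    fn = int(cm.counts[i, :].sum() - tp)
    tn = cm.total - tp - fp - fn
    accuracy = (tp + tn) / cm.total if cm.total else math.nan
    precision = tp / (tp + fp) if (tp + fp) else math.nan
    recall = tp / (tp + fn) if (tp + fn) else math.nan
    return accuracy, precision, recall


@dataclass
class MetricsReport:
    """Per-category and overall predictability metrics for one analysis."""

    confusion: ConfusionMatrix
    per_category: pd.DataFrame  # index category, cols accuracy/precision/recall
    overall: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = self.per_category.copy()
        frame.loc["mean"] = [
            self.overall["accuracy"],
            self.overall["precision"],
            self.overall["recall"],
        ]
        return frame


def overall_metrics(per_category: pd.DataFrame) -> dict[str, float]:
    """Unweighted means over categories with defined values."""
    if per_category.empty:
        raise ValueError("no categories to average")
    return {
        col: float(per_category[col].dropna().mean())
        for col in ("accuracy", "precision", "recall")
    }


def report(predictions: pd.DataFrame) -> MetricsReport:
    """Full metrics report for one PredictionSet.

    Categories are the union of true and predicted labels; categories that
    never occur as a true label contribute precision only (their recall is
    undefined and excluded from the mean).
    """
    cm = confusion(predictions)
    rows = {
        c: category_metrics(cm, c) for c in cm.categories
    }
    per_category = pd.DataFrame.from_dict(
        rows, orient="index", columns=["accuracy", "precision", "recall"]
    )
    return MetricsReport(
        confusion=cm,
        per_category=per_category,
        overall=overall_metrics(per_category),
    )


def fraction_correct(predictions: pd.DataFrame) -> float:
    """Global proportion of correctly classified bursts (trace / total)."""
    return float((predictions["true"] == predictions["predicted"]).mean())


@dataclass(frozen=True)
class PairedComparison:
    t: float
    p_two_sided: float
    p_one_sided: float
    df: int


def paired_device_comparison(
    acc_device1: Sequence[float], acc_device2: Sequence[float]
) -> PairedComparison:
    """Classical paired t-test on per-category accuracy differences.

    t = mean(d) / (sd(d) / sqrt(n)) with d = acc1 - acc2 over matched
    categories, df = n - 1. Both tail conventions are reported (the
    one-sided tail tests device 1 > device 2). Identical vectors give
    t = 0; a constant non-zero difference has zero sd and yields an
    infinite t with p = 0.
    """
    d = np.asarray(acc_device1, dtype=float) - np.asarray(acc_device2, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 paired categories")
    n = len(d)
    mean_d = d.mean()
    sd_d = d.std(ddof=1)
    if sd_d == 0.0:
        if mean_d == 0.0:
            t = 0.0
        else:
            t = math.inf if mean_d > 0 else -math.inf
    else:
        t = mean_d / (sd_d / math.sqrt(n))
    df = n - 1
    if math.isinf(t):
        p_two, p_one = 0.0, 0.0 if t > 0 else 1.0
    else:
        p_two = float(2 * _sps.t.sf(abs(t), df))
        p_one = float(_sps.t.sf(t, df))
    return PairedComparison(t=float(t), p_two_sided=p_two, p_one_sided=p_one, df=df)
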