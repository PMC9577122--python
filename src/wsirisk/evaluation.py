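"""Classification metrics with bootstrap confidence intervals.

Per-class and support-weighted precision/recall/F1/accuracy over the
two risk classes, confusion matrices, and percentile-bootstrap 95%
confidence intervals (n-out-of-n resampling of slides).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from wsirisk._random import substream
from wsirisk.synthetic import HIGH_RISK, LOW_RISK

__all__ = [
    "RISK_LABELS",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "bootstrap_ci",
    "metric_value",
    "report_with_cis",
]

RISK_LABELS = (LOW_RISK, HIGH_RISK)


class ValidationError(ValueError):
    pass


def confusion_matrix(
    truths: Sequence[str], predictions: Sequence[str]
) -> np.ndarray:
    """2x2 counts, rows = truth, cols = prediction, order (low, high)."""
    truths, predictions = list(truths), list(predictions)
    if len(truths) != len(predictions):
        raise ValidationError("truths and predictions differ in length")
    unknown = (set(truths) | set(predictions)) - set(RISK_LABELS)
    if unknown:
        raise ValidationError(f"unknown labels {sorted(unknown)}")
    if not truths:
        warnings.warn("empty input; returning all-zero confusion matrix")
    index = {label: i for i, label in enumerate(RISK_LABELS)}
    out = np.zeros((2, 2), dtype=int)
    for t, p in zip(truths, predictions):
        out[index[t], index[p]] += 1
    return out


@dataclass
class MetricsReport:
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    weighted: dict[str, float]
    accuracy: float
    zero_support_classes: list[str] = field(default_factory=list)
    cis: dict[str, tuple[float, float]] = field(default_factory=dict)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def classification_metrics(confusion: np.ndarray) -> MetricsReport:
    """Point metrics from a 2x2 confusion matrix.

    Weighted averages weight each class by its true support; classes
    with zero support are flagged and excluded from the weighting. A
    zero denominator yields a 0.0 metric by convention.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (2, 2) or confusion.sum() == 0:
        raise ValidationError("confusion matrix must be 2x2 and nonempty")
    n = confusion.sum()
    per_class: dict[str, dict[str, float]] = {}
    supports = confusion.sum(axis=1)
    zero_support = [RISK_LABELS[i] for i in range(2) if supports[i] == 0]
    for i, label in enumerate(RISK_LABELS):
        tp = int(confusion[i, i])
        fp = int(confusion[1 - i, i])
        fn = int(confusion[i, 1 - i])
        precision, recall, f1 = _prf(tp, fp, fn)
        per_class[label] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            # Per-class accuracy in the binary setting equals overall
            # accuracy; reported per class for table symmetry.
            "accuracy": float(np.trace(confusion) / n),
            "support": int(supports[i]),
        }
    weights = np.array(
        [supports[i] if RISK_LABELS[i] not in zero_support else 0 for i in range(2)],
        dtype=float,
    )
    weights /= weights.sum()
    weighted = {
        m: float(
            sum(weights[i] * per_class[RISK_LABELS[i]][m] for i in range(2))
        )
        for m in ("precision", "recall", "f1", "accuracy")
    }
    return MetricsReport(
        confusion=confusion,
        per_class=per_class,
        weighted=weighted,
        accuracy=float(np.trace(confusion) / n),
        zero_support_classes=zero_support,
    )


def metric_value(truths: Sequence[str], predictions: Sequence[str], metric: str) -> float:
    """Named metric on raw label sequences, e.g. 'weighted_f1',
    'accuracy', 'low_risk_precision'."""
    report = classification_metrics(confusion_matrix(truths, predictions))
    if metric == "accuracy":
        return report.accuracy
    prefix, _, name = metric.rpartition("_")
    if prefix == "weighted":
        return report.weighted[name]
    for label in RISK_LABELS:
        if metric.startswith(label + "_"):
            return report.per_class[label][metric[len(label) + 1 :]]
    raise ValidationError(f"unknown metric {metric!r}")


def bootstrap_ci(
    truths: Sequence[str],
    predictions: Sequence[str],
    metric: str | Callable[[Sequence[str], Sequence[str]], float] = "weighted_f1",
    iterations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for a metric.

    Resamples slides with replacement n-out-of-n; replicates where the
    metric is undefined (NaN or degenerate confusion) are skipped and
    counted in a warning.
    """
    truths = np.asarray(list(truths))
    predictions = np.asarray(list(predictions))
    if len(truths) < 2:
        raise ValidationError("need at least 2 samples to bootstrap")
    if iterations < 1:
        raise ValidationError("iterations must be >= 1")
    fn = (
        metric
        if callable(metric)
        else lambda t, p: metric_value(t, p, metric)  # noqa: E731
    )
    rng = substream(seed, "bootstrap")
    n = len(truths)
    values = []
    skipped = 0
    for _ in range(iterations):
        idx = rng.integers(0, n, size=n)
        try:
            value = fn(truths[idx], predictions[idx])
        except (ValidationError, ZeroDivisionError):
            skipped += 1
            continue
        if np.isnan(value):
            skipped += 1
            continue
        values.append(value)
    if skipped:
        warnings.warn(f"{skipped} bootstrap replicates skipped (metric undefined)")
    if not values:
        raise ValidationError("metric undefined in every bootstrap replicate")
    lower, upper = np.percentile(values, [2.5, 97.5])
    return float(lower), float(upper)


def report_with_cis(
    truths: Sequence[str],
    predictions: Sequence[str],
    iterations: int = 10_000,
    seed: int = 0,
) -> MetricsReport:
    """Full metrics report with bootstrap CIs on the weighted averages."""
    report = classification_metrics(confusion_matrix(truths, predictions))
    for name in ("precision", "recall", "f1"):
        report.cis[f"weighted_{name}"] = bootstrap_ci(
            truths, predictions, f"weighted_{name}", iterations, seed
        )
    report.cis["accuracy"] = bootstrap_ci(truths, predictions, "accuracy", iterations, seed)
    return report
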