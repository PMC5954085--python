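"""Confusion counts, precision/recall, PR curves, and threshold selection.

A pair is predicted plausible iff its confidence metric is >= the
threshold (inclusive by default; a strict mode is available).  Precision
with no predicted positives is reported as missing (None), never 0 or 1,
and such points are skipped by threshold selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "AnnotatedMatch",
    "ConfusionCounts",
    "PRPoint",
    "PRCurve",
    "confusion_at_threshold",
    "precision",
    "recall",
    "pr_curve",
    "stratified_pr_curves",
    "threshold_for_precision",
]

ITEM_CLASSES = ("directly_mappable", "other", "any")


@dataclass(frozen=True)
class AnnotatedMatch:
    """A scored candidate pair plus its human plausibility label."""

    query_id: str
    candidate_id: str
    fuzzy_score: float
    ediff: Optional[float] = None
    c5_probability: Optional[float] = None
    label: str = "non_plausible"  # "plausible" or "non_plausible"
    item_class: str = "any"

    def __post_init__(self) -> None:
        if self.label not in ("plausible", "non_plausible"):
            raise ValueError(f"bad label {self.label!r}")

    def metric_value(self, metric: str) -> float:
        """Confidence on a 0-100 scale ("fuzzy" or "c5")."""
        if metric == "fuzzy":
            return float(self.fuzzy_score)
        if metric == "c5":
            if self.c5_probability is None:
                raise ValueError(f"pair ({self.query_id}, {self.candidate_id}) has no c5 probability")
            return 100.0 * float(self.c5_probability)
        raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )


def precision(c: ConfusionCounts) -> Optional[float]:
    """tp / (tp + fp); None (missing) when nothing is predicted positive."""
    denom = c.tp + c.fp
    return None if denom == 0 else c.tp / denom


def recall(c: ConfusionCounts) -> Optional[float]:
    """tp / (tp + fn); None when there are no positive labels."""
    denom = c.tp + c.fn
    return None if denom == 0 else c.tp / denom


def confusion_at_threshold(
    annotated: Iterable[AnnotatedMatch],
    metric: str,
    threshold: float,
    inclusive: bool = True,
) -> ConfusionCounts:
    """Cross-tabulate predicted-plausible (metric >= threshold) vs labels."""
    tp = fp = fn = tn = 0
    for a in annotated:
        v = a.metric_value(metric)
        predicted = v >= threshold if inclusive else v > threshold
        positive = a.label == "plausible"
        if predicted and positive:
            tp += 1
        elif predicted:
            fp += 1
        elif positive:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: Optional[float]
    recall: Optional[float]
    counts: ConfusionCounts


@dataclass(frozen=True)
class PRCurve:
    """Ordered (threshold, precision, recall) points with their counts."""

    points: tuple = field(default_factory=tuple)
    metric: str = "fuzzy"
    item_class: str = "any"

    def __post_init__(self) -> None:
        ts = [p.threshold for p in self.points]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def thresholds(self) -> list:
        return [p.threshold for p in self.points]


def _default_grid(values: Sequence[float]) -> list:
    grid = sorted(set(float(v) for v in values) | {0.0, 100.0})
    return grid


def pr_curve(
    annotated: Sequence[AnnotatedMatch],
    metric: str = "fuzzy",
    thresholds: Optional[Sequence[float]] = None,
    item_class: str = "any",
    inclusive: bool = True,
) -> PRCurve:
    """One PR point per threshold.

    The default grid is every observed distinct metric value plus 0 and
    100 (the exact curve).  ``item_class`` restricts to one stratum of the
    id-based cross-match partition ("any" keeps everything).
    """
    if not annotated:
        raise ValueError("no annotated pairs")
    if item_class != "any":
        annotated = [a for a in annotated if a.item_class == item_class]
    if thresholds is None:
        if not annotated:
            thresholds = [0.0, 100.0]
        else:
            thresholds = _default_grid([a.metric_value(metric) for a in annotated])
    else:
        thresholds = sorted(set(float(t) for t in thresholds))
    points = []
    for t in thresholds:
        c = confusion_at_threshold(annotated, metric, t, inclusive=inclusive)
        points.append(PRPoint(threshold=t, precision=precision(c), recall=recall(c), counts=c))
    return PRCurve(points=tuple(points), metric=metric, item_class=item_class)


def stratified_pr_curves(
    annotated: Sequence[AnnotatedMatch],
    metric: str = "fuzzy",
    thresholds: Optional[Sequence[float]] = None,
    inclusive: bool = True,
) -> dict:
    """PR curves per item class plus the pooled "any" curve.

    All three share one threshold grid so the "any" counts equal the
    element-wise sum of the strata at every threshold.
    """
    if thresholds is None:
        thresholds = _default_grid([a.metric_value(metric) for a in annotated])
    return {
        cls: pr_curve(annotated, metric, thresholds, item_class=cls, inclusive=inclusive)
        for cls in ITEM_CLASSES
    }


def threshold_for_precision(curve: PRCurve, target: float) -> Optional[PRPoint]:
    """The point at the smallest threshold whose precision reaches target.

    Points with undefined (missing) precision are skipped.  None when the
    target precision is unreachable anywhere on the curve.
    """
    if not curve.points:
        raise ValueError("empty curve")
    for p in curve.points:
        if p.precision is not None and p.precision >= target:
            return p
    return None
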