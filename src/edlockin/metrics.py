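"""Confusion-matrix metrics, majority baselines and subgroup stratification.

Conventions used throughout the package:

* A metric with a zero denominator (e.g. precision with no positive
  predictions) is *undefined* and carried as ``None`` — never silently
  coerced to 0.
* The majority baseline for a subgroup is the accuracy of always predicting
  that subgroup's larger class, i.e. ``max(admitted share, 1 - admitted
  share)``; the single-direction variants (always-admit / never-admit) are
  exposed separately.
* Table-style rounding is half-up to two decimals, matching how such
  metrics are conventionally printed.
* Quartiles use linear interpolation between order statistics (the numpy
  default, quantile type 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "TimeSavedSummary",
    "DIMENSION_LEVELS",
    "confusion_metrics",
    "majority_accuracy",
    "always_admit_accuracy",
    "never_admit_accuracy",
    "age_bin",
    "part_of_day",
    "median_iqr",
    "round_half_up",
    "stratify",
    "coherence_crosstab",
    "stratification_table",
]

AGE_GROUP_LEVELS = (
    "18-27", "28-37", "38-47", "48-57", "58-67", "68-77", "78-87", "≥88",
)
PART_OF_DAY_LEVELS = ("night", "morning", "afternoon", "evening")
# triage / specialty level sets live with the generator; imported lazily in
# DIMENSION_LEVELS to keep this module free of a circular import.


def _dimension_levels() -> dict[str, tuple[str, ...]]:
    from .cohort import SPECIALTY_LABELS, TRIAGE_LABELS

    return {
        "age_group": AGE_GROUP_LEVELS,
        "specialty": SPECIALTY_LABELS,
        "triage": TRIAGE_LABELS,
        "part_of_day": PART_OF_DAY_LEVELS,
    }


class _LazyLevels(Mapping):
    def __getitem__(self, key):
        return _dimension_levels()[key]

    def __iter__(self):
        return iter(_dimension_levels())

    def __len__(self):
        return len(_dimension_levels())


#: dimension name -> ordered level labels, for the four stratification axes
DIMENSION_LEVELS: Mapping[str, tuple[str, ...]] = _LazyLevels()


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 outcome counts for admit-vs-discharge predictions."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name}={v!r} must be a non-negative integer")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """Derived classification metrics; ``None`` marks an undefined value."""

    precision: float | None
    recall: float | None
    accuracy: float | None
    f1: float | None
    majority_accuracy: float | None

    def rounded(self, ndigits: int = 2) -> "MetricSet":
        r = lambda v: None if v is None else round_half_up(v, ndigits)
        return MetricSet(
            r(self.precision), r(self.recall), r(self.accuracy),
            r(self.f1), r(self.majority_accuracy),
        )


@dataclass(frozen=True)
class TimeSavedSummary:
    """Median and quartiles (minutes) of a time-saved sample."""

    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.n >= 1 and not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles out of order")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Precision, recall, accuracy, F1 and majority baseline from counts."""
    if counts.n == 0:
        raise ValueError("empty confusion table (n=0)")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    accuracy = (counts.tp + counts.tn) / counts.n
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(precision, recall, accuracy, f1, majority_accuracy(counts))


def always_admit_accuracy(counts: ConfusionCounts) -> float:
    """Accuracy of predicting admission for every visit."""
    if counts.n == 0:
        raise ValueError("empty confusion table (n=0)")
    return (counts.tp + counts.fn) / counts.n


def never_admit_accuracy(counts: ConfusionCounts) -> float:
    """Accuracy of predicting discharge for every visit."""
    if counts.n == 0:
        raise ValueError("empty confusion table (n=0)")
    return (counts.tn + counts.fp) / counts.n


def majority_accuracy(counts: ConfusionCounts) -> float:
    """Accuracy of always predicting the subgroup's larger class."""
    return max(always_admit_accuracy(counts), never_admit_accuracy(counts))


def age_bin(age_years: int) -> str:
    """Decade age-group label, final open bin ≥88; minors are excluded."""
    if age_years < 18:
        raise ValueError(f"age_years={age_years}: population excludes minors")
    if age_years >= 88:
        return "≥88"
    if age_years < 28:
        return "18-27"
    return AGE_GROUP_LEVELS[1 + (int(age_years) - 28) // 10]


def part_of_day(arrival_minute_of_day: int) -> str:
    """Arrival-period label over half-open 6-hour windows of the day."""
    m = arrival_minute_of_day
    if not (0 <= m < 1440):
        raise ValueError(f"arrival_minute_of_day={m!r} outside [0, 1440)")
    return PART_OF_DAY_LEVELS[int(m) // 360]


def median_iqr(values: Iterable[float]) -> TimeSavedSummary:
    """Median and quartiles by linear interpolation between order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr of an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return TimeSavedSummary(int(arr.size), float(med), float(q1), float(q3))


_OUTCOME_TO_FIELD = {"TP": "tp", "TN": "tn", "FP": "fp", "FN": "fn"}


def _counts_from_outcomes(outcomes: pd.Series) -> ConfusionCounts:
    c = outcomes.value_counts()
    return ConfusionCounts(
        int(c.get("TP", 0)), int(c.get("TN", 0)),
        int(c.get("FP", 0)), int(c.get("FN", 0)),
    )


def _require_joined(decisions: pd.DataFrame, dimension: str) -> None:
    levels = DIMENSION_LEVELS.get(dimension)
    if levels is None:
        raise ValueError(
            f"unknown dimension {dimension!r}; expected one of {list(DIMENSION_LEVELS)}")
    if dimension not in decisions.columns:
        raise ValueError(
            f"decisions frame lacks the {dimension!r} column; join visits first")
    stray = set(decisions[dimension].dropna()) - set(levels)
    if stray:
        raise ValueError(f"unknown {dimension} levels {sorted(stray)[:3]}")
    if decisions[dimension].isna().any():
        raise ValueError(f"decision rows with no {dimension!r} value (unjoinable)")


def stratify(
    decisions: pd.DataFrame, dimension: str
) -> dict[str, tuple[ConfusionCounts, MetricSet, TimeSavedSummary | None]]:
    """Per-level confusion counts, metrics and TP time-saved summaries.

    ``decisions`` must carry ``outcome_class``, ``time_saved_minutes`` and
    the stratification column (see
    :meth:`~edlockin.lockin.LockInResults.decisions_joined`).  Levels with
    no visits are omitted; a level with visits but no true positives gets a
    ``None`` time-saved summary.
    """
    _require_joined(decisions, dimension)
    out: dict[str, tuple[ConfusionCounts, MetricSet, TimeSavedSummary | None]] = {}
    for level in DIMENSION_LEVELS[dimension]:
        sub = decisions[decisions[dimension] == level]
        if len(sub) == 0:
            continue
        counts = _counts_from_outcomes(sub["outcome_class"])
        saved = sub.loc[sub["outcome_class"] == "TP", "time_saved_minutes"]
        summary = median_iqr(saved) if len(saved) else None
        out[level] = (counts, confusion_metrics(counts), summary)
    return out


def coherence_crosstab(
    decisions: pd.DataFrame, dimension_a: str, dimension_b: str
) -> pd.DataFrame:
    """Median time saved (minutes) over TP visits per (level_a, level_b) cell.

    Cells with no true-positive visit are NaN (empty, distinct from a
    zero-minute saving).  Rows/columns follow the canonical level order.
    """
    if dimension_a == dimension_b:
        raise ValueError("coherence crosstab needs two distinct dimensions")
    _require_joined(decisions, dimension_a)
    _require_joined(decisions, dimension_b)
    tp = decisions[decisions["outcome_class"] == "TP"]
    table = tp.pivot_table(
        index=dimension_a, columns=dimension_b,
        values="time_saved_minutes", aggfunc="median",
    )
    table = table.reindex(
        index=list(DIMENSION_LEVELS[dimension_a]),
        columns=list(DIMENSION_LEVELS[dimension_b]),
    )
    table.index.name = dimension_a
    table.columns.name = dimension_b
    return table


def stratification_table(
    strat: Mapping[str, tuple[ConfusionCounts, MetricSet, TimeSavedSummary | None]],
    dimension: str,
) -> pd.DataFrame:
    """Render a stratification as a printable table (raw + 2-dp metrics)."""
    rows = []
    for level, (c, m, s) in strat.items():
        mr = m.rounded(2)
        rows.append({
            dimension: level, "n": c.n,
            "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
            "precision": mr.precision, "recall": mr.recall,
            "accuracy": mr.accuracy, "f1": mr.f1,
            "majority_accuracy": mr.majority_accuracy,
            "precision_raw": m.precision, "recall_raw": m.recall,
            "accuracy_raw": m.accuracy,
            "n_tp": 0 if s is None else s.n,
            "time_saved_median": None if s is None else s.median,
            "time_saved_q1": None if s is None else s.q1,
            "time_saved_q3": None if s is None else s.q3,
        })
    return pd.DataFrame(rows)
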