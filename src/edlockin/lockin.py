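"""Irreversible ("lock-in") decision simulation over the evaluation grid.

The deployed rule mimics clinical commitment: the visit's admission
probability is re-scored every grid step, and the first time it *strictly
exceeds* the 50% threshold the prediction locks to "admit" and can never
revert — later, lower probabilities are ignored.  A visit whose trace never
crosses is a predicted discharge, with its decision time set to the
evaluation horizon.

Per-time-point metrics treat visits not yet locked at time t as
provisional negatives, so the TP and FP series are non-decreasing in t and
the horizon counts equal the end-of-simulation confusion counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    ConfusionCounts,
    MetricSet,
    TimeSavedSummary,
    age_bin,
    coherence_crosstab,
    confusion_metrics,
    median_iqr,
    part_of_day,
    stratification_table,
    stratify,
)
from .snapshots import TimeGrid

__all__ = [
    "PredictionTrace",
    "LockedDecision",
    "simulate_lockin",
    "classify_outcome",
    "time_saved",
    "metrics_over_time",
    "LockInEvaluation",
    "LockInResults",
    "DECISION_COLUMNS",
]

DECISION_COLUMNS = (
    "visit_id", "predicted_admit", "ai_decision_minutes", "outcome_class",
    "clinician_decision_minutes", "time_saved_minutes",
)


def simulate_lockin(
    probabilities, grid: TimeGrid, threshold: float = 0.5
) -> float | None:
    """First grid point whose probability strictly exceeds ``threshold``.

    Returns that grid time in minutes, or ``None`` if no point qualifies
    (including a trace sitting exactly at the threshold).  Values after the
    first crossing never alter the result.
    """
    p = np.asarray(probabilities, dtype=float)
    points = grid.points
    if p.shape != points.shape:
        raise ValueError(
            f"trace length {p.size} does not match grid ({points.size} points)")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    above = p > threshold
    if not above.any():
        return None
    return float(points[int(np.argmax(above))])


@dataclass(frozen=True)
class PredictionTrace:
    """One visit's probability trajectory on the grid, plus its lock time."""

    visit_id: str
    grid: TimeGrid
    probabilities: tuple[float, ...]
    threshold: float = 0.5
    lock_time_minutes: float | None = field(init=False)

    def __post_init__(self) -> None:
        lock = simulate_lockin(self.probabilities, self.grid, self.threshold)
        object.__setattr__(self, "lock_time_minutes", lock)


def classify_outcome(predicted_admit: bool, admitted: bool) -> str:
    """Standard 2x2 mapping of (prediction, truth) to TP/TN/FP/FN."""
    if predicted_admit:
        return "TP" if admitted else "FP"
    return "FN" if admitted else "TN"


def time_saved(
    clinician_decision_minutes: float, ai_decision_minutes: float
) -> float:
    """Clinician minus model decision time; negative if the model was later."""
    if clinician_decision_minutes < 0 or ai_decision_minutes < 0:
        raise ValueError("decision times must be non-negative")
    return float(clinician_decision_minutes) - float(ai_decision_minutes)


@dataclass(frozen=True)
class LockedDecision:
    """The simulator's irreversible prediction for one visit."""

    visit_id: str
    predicted_admit: bool
    ai_decision_minutes: float
    outcome_class: str
    clinician_decision_minutes: float
    time_saved_minutes: float | None  # defined for TP visits only

    def __post_init__(self) -> None:
        admitted = self.outcome_class in ("TP", "FN")
        if classify_outcome(self.predicted_admit, admitted) != self.outcome_class:
            raise ValueError(
                f"outcome_class {self.outcome_class} inconsistent with "
                f"predicted_admit={self.predicted_admit}")


def metrics_over_time(
    lock_times: np.ndarray, admitted: np.ndarray, grid: TimeGrid
) -> pd.DataFrame:
    """Confusion counts and metrics at every grid point under lock-in.

    ``lock_times`` holds NaN for never-locked visits.  At time t a visit is
    a predicted admission iff it locked at or before t; otherwise it is a
    provisional negative.  Consequently TP(t) and FP(t) are non-decreasing
    and TP+TN+FP+FN = n at every t.
    """
    lock_times = np.asarray(lock_times, dtype=float)
    admitted = np.asarray(admitted, dtype=bool)
    if lock_times.shape != admitted.shape:
        raise ValueError("lock_times and admitted must align")
    rows = []
    for t in grid.points:
        locked = ~np.isnan(lock_times) & (lock_times <= t)
        tp = int((locked & admitted).sum())
        fp = int((locked & ~admitted).sum())
        fn = int((~locked & admitted).sum())
        tn = int((~locked & ~admitted).sum())
        c = ConfusionCounts(tp, tn, fp, fn)
        m = confusion_metrics(c) if c.n else None
        rows.append({
            "t_minutes": int(t), "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "precision": None if m is None else m.precision,
            "recall": None if m is None else m.recall,
            "accuracy": None if m is None else m.accuracy,
        })
    return pd.DataFrame(rows)


class LockInEvaluation:
    """Run the irreversible-decision simulation for a scored test cohort.

    Parameters
    ----------
    results
        A fitted :class:`~edlockin.model.AdmissionModelResults`.
    snapshots
        Snapshot rows of the visits to evaluate (all grid points present
    	for each visit).
    visits
        The visit table covering those visits (for outcomes, clinician
        times and subgroup covariates).
    threshold
        Lock threshold; the prediction locks when probability strictly
        exceeds it.
    """

    def __init__(self, results, snapshots: pd.DataFrame, visits: pd.DataFrame,
                 grid: TimeGrid | None = None, threshold: float = 0.5):
        from .snapshots import make_time_grid

        self.results = results
        self.snapshots = snapshots
        self.visits = visits
        self.grid = grid or make_time_grid()
        self.threshold = float(threshold)

    def run(self) -> "LockInResults":
        grid = self.grid
        points = grid.points
        snaps = self.snapshots.sort_values(
            ["visit_id", "t_minutes"], kind="mergesort")
        per_visit = snaps.groupby("visit_id", sort=True).size()
        if (per_visit != len(points)).any():
            bad = per_visit[per_visit != len(points)].index[0]
            raise ValueError(
                f"visit {bad!r} lacks a snapshot at every grid point")
        visit_ids = per_visit.index.to_numpy(dtype=object)
        missing = set(visit_ids) - set(self.visits["visit_id"])
        if missing:
            raise ValueError(
                f"snapshot visits absent from visit table, e.g. "
                f"{sorted(missing)[:3]}")

        probs = self.results.predict_proba(snaps).reshape(
            len(visit_ids), len(points))
        above = probs > self.threshold
        any_lock = above.any(axis=1)
        first = np.argmax(above, axis=1)
        lock_times = np.where(any_lock, points[first], np.nan).astype(float)

        vis = (self.visits.set_index("visit_id")
               .loc[visit_ids]
               .reset_index())
        admitted = vis["admitted"].to_numpy().astype(bool)
        clin = vis["clinician_decision_minutes"].to_numpy(dtype=float)
        predicted = any_lock
        ai_minutes = np.where(any_lock, lock_times, float(grid.horizon_minutes))
        outcome = np.array([
            classify_outcome(bool(p), bool(a))
            for p, a in zip(predicted, admitted)
        ], dtype=object)
        saved = clin - ai_minutes
        saved = np.where(outcome == "TP", saved, np.nan)

        decisions = pd.DataFrame({
            "visit_id": visit_ids,
            "predicted_admit": predicted.astype(int),
            "ai_decision_minutes": ai_minutes,
            "outcome_class": outcome,
            "clinician_decision_minutes": clin,
            "time_saved_minutes": saved,
        })
        covariates = pd.DataFrame({
            "visit_id": visit_ids,
            "age_group": [age_bin(a) for a in vis["age_years"]],
            "specialty": vis["specialty"].to_numpy(),
            "triage": vis["triage"].to_numpy(),
            "part_of_day": [part_of_day(m) for m in vis["arrival_minute_of_day"]],
        })
        mot = metrics_over_time(lock_times, admitted, grid)
        return LockInResults(
            decisions=decisions,
            covariates=covariates,
            metrics_over_time=mot,
            grid=grid,
            threshold=self.threshold,
            probabilities=pd.DataFrame(
                probs, index=pd.Index(visit_ids, name="visit_id"),
                columns=[int(t) for t in points]),
        )


@dataclass
class LockInResults:
    """Outputs of the lock-in simulation for one evaluated cohort."""

    decisions: pd.DataFrame
    covariates: pd.DataFrame
    metrics_over_time: pd.DataFrame
    grid: TimeGrid
    threshold: float
    probabilities: pd.DataFrame

    def decisions_joined(self) -> pd.DataFrame:
        """Decisions joined to subgroup covariates (one row per visit)."""
        return self.decisions.merge(self.covariates, on="visit_id", how="left")

    @property
    def confusion(self) -> ConfusionCounts:
        c = self.decisions["outcome_class"].value_counts()
        return ConfusionCounts(
            int(c.get("TP", 0)), int(c.get("TN", 0)),
            int(c.get("FP", 0)), int(c.get("FN", 0)),
        )

    @property
    def metric_set(self) -> MetricSet:
        return confusion_metrics(self.confusion)

    def time_saved_summary(self) -> TimeSavedSummary | None:
        """Median/IQR of minutes saved over true-positive visits."""
        tp = self.decisions.loc[
            self.decisions["outcome_class"] == "TP", "time_saved_minutes"]
        return median_iqr(tp) if len(tp) else None

    def ai_decision_time_summary(self) -> TimeSavedSummary | None:
        """Median/IQR of the model's decision time over TP visits."""
        tp = self.decisions.loc[
            self.decisions["outcome_class"] == "TP", "ai_decision_minutes"]
        return median_iqr(tp) if len(tp) else None

    def stratify(self, dimension: str):
        return stratify(self.decisions_joined(), dimension)

    def stratification_table(self, dimension: str) -> pd.DataFrame:
        return stratification_table(self.stratify(dimension), dimension)

    def coherence(self, dimension_a: str, dimension_b: str) -> pd.DataFrame:
        return coherence_crosstab(self.decisions_joined(), dimension_a, dimension_b)

    def summary(self) -> str:
        c = self.confusion
        m = self.metric_set.rounded(2)
        ts = self.time_saved_summary()
        ai = self.ai_decision_time_summary()
        fmt = lambda v: "undefined" if v is None else f"{v:.2f}"
        lines = [
            "Lock-in evaluation",
            "=" * 44,
            f"visits evaluated     : {c.n}",
            f"threshold            : p > {self.threshold:g} locks 'admit'",
            f"TP / TN / FP / FN    : {c.tp} / {c.tn} / {c.fp} / {c.fn}",
            f"precision            : {fmt(m.precision)}",
            f"recall               : {fmt(m.recall)}",
            f"accuracy             : {fmt(m.accuracy)}",
            f"F1                   : {fmt(m.f1)}",
            f"majority baseline    : {fmt(m.majority_accuracy)}",
        ]
        if ai is not None:
            lines.append(
                f"model decision time  : median {ai.median:.0f} "
                f"(IQR {ai.q1:.0f}-{ai.q3:.0f}) min over {ai.n} TP visits")
        if ts is not None:
            lines.append(
                f"time saved (TP)      : median {ts.median:.0f} "
                f"(IQR {ts.q1:.0f}-{ts.q3:.0f}) min")
        return "\n".join(lines)
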