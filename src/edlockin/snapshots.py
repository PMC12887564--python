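"""Cumulative feature snapshots on the 10-minute evaluation grid.

A visit's event stream is converted into one feature vector per grid point
t, aggregating exactly the events with ``offset_minutes <= t`` (closed
boundary: an event landing exactly on a grid point is visible at that
point, mirroring "the most recent information available").  Static context
(age, triage, specialty, arrival period) is constant across a visit's
snapshots; per-category aggregates are a cumulative count, an any-seen
flag, and the last observed value (0 with flag 0 before the first event,
so tree models can split on the flag rather than a sentinel).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    EVENT_CATEGORIES,
    PART_OF_DAY_LABELS,
    SPECIALTY_LABELS,
    TRIAGE_LABELS,
    TRIAGE_EVENT_CATEGORY,
)
from .metrics import part_of_day

__all__ = [
    "TimeGrid",
    "FeatureSchema",
    "FeatureSnapshot",
    "make_time_grid",
    "build_snapshots",
    "snapshot_matrix",
    "SNAPSHOT_ID_COLUMNS",
]

SNAPSHOT_ID_COLUMNS = ("visit_id", "t_minutes", "label")


@dataclass(frozen=True)
class TimeGrid:
    """Inclusive evaluation grid [0, step, ..., horizon] in minutes."""

    step_minutes: int = 10
    horizon_minutes: int = 180

    def __post_init__(self) -> None:
        if self.step_minutes <= 0 or self.horizon_minutes <= 0:
            raise ValueError("step and horizon must be positive")
        if self.horizon_minutes % self.step_minutes != 0:
            raise ValueError(
                f"step {self.step_minutes} does not divide horizon "
                f"{self.horizon_minutes}"
            )

    @property
    def points(self) -> np.ndarray:
        return np.arange(
            0, self.horizon_minutes + self.step_minutes, self.step_minutes
        )

    def __len__(self) -> int:
        return self.horizon_minutes // self.step_minutes + 1


def make_time_grid(step_minutes: int = 10, horizon_minutes: int = 180) -> TimeGrid:
    """Build the evaluation grid; defaults give the 19 points 0..180."""
    return TimeGrid(int(step_minutes), int(horizon_minutes))


_DEFAULT_STATICS = ("age_years", "triage", "specialty", "part_of_day")


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed, ordered layout of the snapshot feature vector.

    The layout (and hence the model input contract) is summarised by
    :meth:`schema_hash`; a trained model refuses vectors built under a
    different hash.
    """

    static_fields: tuple[str, ...] = _DEFAULT_STATICS
    event_categories: tuple[str, ...] = tuple(
        [TRIAGE_EVENT_CATEGORY] + list(EVENT_CATEGORIES)
    )

    _LEVELS = {
        "triage": TRIAGE_LABELS,
        "specialty": SPECIALTY_LABELS,
        "part_of_day": PART_OF_DAY_LABELS,
    }

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for f in self.static_fields:
            if f in self._LEVELS:
                names.extend(f"{f}={lv}" for lv in self._LEVELS[f])
            else:
                names.append(f)
        for cat in self.event_categories:
            names.extend((f"{cat}__count", f"{cat}__any", f"{cat}__last"))
        return names

    def schema_hash(self) -> str:
        payload = json.dumps(
            {"static": list(self.static_fields),
             "events": list(self.event_categories),
             "features": self.feature_names},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> str:
        return json.dumps(
            {"static_fields": list(self.static_fields),
             "event_categories": list(self.event_categories),
             "schema_hash": self.schema_hash()},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        schema = cls(
            static_fields=tuple(d["static_fields"]),
            event_categories=tuple(d["event_categories"]),
        )
        stored = d.get("schema_hash")
        if stored is not None and stored != schema.schema_hash():
            raise ValueError(
                f"schema hash mismatch: file says {stored}, "
                f"reconstructed {schema.schema_hash()}"
            )
        return schema


@dataclass(frozen=True)
class FeatureSnapshot:
    """The feature vector available for one visit at one grid point."""

    visit_id: str
    t_minutes: int
    vector: np.ndarray = field(repr=False)
    label: bool


def _static_features(visits: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """One row per visit with the static part of the feature vector."""
    cols: dict[str, np.ndarray] = {}
    for f in schema.static_fields:
        if f == "part_of_day":
            pod = visits["arrival_minute_of_day"].map(part_of_day)
            for lv in PART_OF_DAY_LABELS:
                cols[f"part_of_day={lv}"] = (pod == lv).to_numpy(dtype=float)
        elif f in schema._LEVELS:
            for lv in schema._LEVELS[f]:
                cols[f"{f}={lv}"] = (visits[f] == lv).to_numpy(dtype=float)
        else:
            cols[f] = visits[f].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=visits["visit_id"])


def build_snapshots(
    visit: pd.Series | dict,
    events: pd.DataFrame,
    grid: TimeGrid,
    schema: FeatureSchema,
) -> list[FeatureSnapshot]:
    """Snapshot a single visit: one :class:`FeatureSnapshot` per grid point.

    Reference (per-visit) implementation; :func:`snapshot_matrix` is the
    vectorised whole-cohort path and must agree with it exactly.
    """
    visit = pd.Series(visit)
    if len(events) and (events["visit_id"] != visit["visit_id"]).any():
        stray = events.loc[events["visit_id"] != visit["visit_id"], "visit_id"].iloc[0]
        raise ValueError(
            f"event for visit {stray!r} passed to snapshots of {visit['visit_id']!r}"
        )
    static = _static_features(pd.DataFrame([visit]), schema).iloc[0]
    ev = events.sort_values(["offset_minutes", "value"], kind="mergesort")
    out = []
    for t in grid.points:
        vec = list(static.to_numpy(dtype=float))
        upto = ev[ev["offset_minutes"] <= t]
        for cat in schema.event_categories:
            sub = upto[upto["category"] == cat]
            count = float(len(sub))
            last = float(sub["value"].iloc[-1]) if count else 0.0
            vec.extend((count, 1.0 if count else 0.0, last))
        out.append(FeatureSnapshot(
            visit_id=str(visit["visit_id"]),
            t_minutes=int(t),
            vector=np.asarray(vec, dtype=float),
            label=bool(visit["admitted"]),
        ))
    return out


def snapshot_matrix(
    visits: pd.DataFrame,
    events: pd.DataFrame,
    grid: TimeGrid | None = None,
    schema: FeatureSchema | None = None,
) -> pd.DataFrame:
    """Cumulative snapshots for a whole cohort.

    Returns a frame with one row per (visit, grid point), ordered by
    (visit_id, t_minutes): identifier columns ``visit_id, t_minutes, label``
    followed by the schema's feature columns.  Invariant under permutations
    of the event table.
    """
    grid = grid or make_time_grid()
    schema = schema or FeatureSchema()
    if visits["visit_id"].duplicated().any():
        dup = visits.loc[visits["visit_id"].duplicated(), "visit_id"].iloc[0]
        raise ValueError(f"duplicated visit_id {dup!r}")
    known = set(visits["visit_id"])
    stray = set(events["visit_id"]) - known
    if stray:
        raise ValueError(f"events reference unknown visits, e.g. {sorted(stray)[:3]}")
    if (events["offset_minutes"] < 0).any():
        raise ValueError("negative event offset")

    visits = visits.sort_values("visit_id", kind="mergesort").reset_index(drop=True)
    n = len(visits)
    points = grid.points
    G = len(points)
    cats = list(schema.event_categories)
    C = len(cats)
    vid_index = pd.Index(visits["visit_id"])

    # Events enter the first grid point >= offset; later points inherit by
    # cumulation/forward-fill.  Events beyond the horizon never enter.
    ev = events[events["offset_minutes"] <= grid.horizon_minutes]
    ev = ev[ev["category"].isin(cats)]
    ev = ev.sort_values(["visit_id", "category", "offset_minutes", "value"],
                        kind="mergesort")
    vi = vid_index.get_indexer(ev["visit_id"])
    ci = pd.Index(cats).get_indexer(ev["category"])
    bins = np.ceil(ev["offset_minutes"].to_numpy() / grid.step_minutes).astype(int)

    counts = np.zeros((n, C, G))
    np.add.at(counts, (vi, ci, bins), 1.0)
    counts = np.cumsum(counts, axis=2)

    last = np.full((n, C, G), np.nan)
    # rows are sorted by offset (then value) within visit/category, so later
    # assignments overwrite earlier ones, leaving each bin's final value
    last[vi, ci, bins] = ev["value"].to_numpy(dtype=float)
    seen = ~np.isnan(last)
    idx = np.where(seen, np.arange(G)[None, None, :], -1)
    idx = np.maximum.accumulate(idx, axis=2)
    filled = np.take_along_axis(
        np.where(seen, last, 0.0), np.clip(idx, 0, None), axis=2)
    last = np.where(idx >= 0, filled, 0.0)
    any_flag = (counts > 0).astype(float)

    static = _static_features(visits, schema)
    out = pd.DataFrame({
        "visit_id": np.repeat(visits["visit_id"].to_numpy(), G),
        "t_minutes": np.tile(points, n),
        "label": np.repeat(visits["admitted"].to_numpy().astype(int), G),
    })
    for col in static.columns:
        out[col] = np.repeat(static[col].to_numpy(), G)
    for j, cat in enumerate(cats):
        out[f"{cat}__count"] = counts[:, j, :].reshape(-1)
        out[f"{cat}__any"] = any_flag[:, j, :].reshape(-1)
        out[f"{cat}__last"] = last[:, j, :].reshape(-1)
    return out
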