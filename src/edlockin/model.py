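"""Boosted-tree admission classifier over snapshot features.

Shaped like a statsmodels model: :class:`AdmissionModel` is built from a
snapshot frame (or directly from visit/event tables via
:meth:`AdmissionModel.from_frames`), and :meth:`AdmissionModel.fit` returns
an :class:`AdmissionModelResults` carrying the fitted ensemble, its input
contract (schema hash), gain-based feature importances, and evaluation
helpers.

Training rows are all (visit × grid point) snapshots, labelled with the
visit-level outcome: the deployed model must score partial information at
every interval, so it is trained on exactly those partial views.  Splits
are always at the visit level — row-level splitting would leak a visit's
own future snapshots into training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score

from .metrics import ConfusionCounts, MetricSet, confusion_metrics
from .snapshots import SNAPSHOT_ID_COLUMNS, FeatureSchema, TimeGrid, make_time_grid

__all__ = [
    "HyperParams",
    "SchemaMismatchError",
    "AdmissionModel",
    "AdmissionModelResults",
    "split_by_visit",
    "train_model",
    "predict_admission_probability",
]


@dataclass(frozen=True)
class HyperParams:
    """Gradient-boosting hyperparameters.

    The five tree-shape/learning values are the tuned operating point for
    this problem class; the number of boosting rounds is capped at
    ``n_rounds`` with early stopping (patience ``early_stopping_rounds``)
    on a 10% visit-level validation split carved from the training data.
    """

    colsample_bytree: float = 0.7
    gamma: float = 0.0
    learning_rate: float = 0.1
    max_depth: int = 15
    min_child_weight: int = 7
    n_rounds: int = 200
    early_stopping_rounds: int = 20
    objective: str = "binary:logistic"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


class SchemaMismatchError(ValueError):
    """Scoring input was built under a different feature schema."""

    def __init__(self, trained_hash: str, given_hash: str):
        self.trained_hash = trained_hash
        self.given_hash = given_hash
        super().__init__(
            f"feature-schema mismatch: model trained under hash "
            f"{trained_hash}, scoring input has hash {given_hash}"
        )


def split_by_visit(
    visit_ids, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint visit-level partition into (train, test) id arrays.

    All snapshots of a visit fall on one side, preventing leakage of a
    visit's own trajectory across the split.  ``|train| = round(f·n)``.
    """
    raw = list(visit_ids)
    ids = pd.unique(pd.Series(raw)) if raw else np.array([], dtype=object)
    if len(ids) == 0:
        raise ValueError("cannot split an empty cohort")
    if len(ids) != len(raw):
        raise ValueError("visit ids are not unique")
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction={train_fraction} outside (0,1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    shuffled = np.asarray(ids, dtype=object)[order]
    return np.sort(shuffled[:n_train]), np.sort(shuffled[n_train:])


def _columns_hash(columns) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(list(columns)).encode()).hexdigest()[:16]


class AdmissionModel:
    """Admission-probability model over cumulative snapshot features.

    Parameters
    ----------
    snapshots
        Training rows: identifier columns ``visit_id, t_minutes, label``
        followed by feature columns (the output of
        :func:`edlockin.snapshots.snapshot_matrix`).
    schema
        The feature schema the snapshots were built under; its column list
        must match the frame's feature columns.
    hyperparams
        Boosting configuration; defaults to :class:`HyperParams`.
    """

    def __init__(
        self,
        snapshots: pd.DataFrame,
        schema: FeatureSchema | None = None,
        hyperparams: HyperParams | None = None,
    ):
        self.schema = schema or FeatureSchema()
        self.hyperparams = hyperparams or HyperParams()
        feature_cols = [c for c in snapshots.columns if c not in SNAPSHOT_ID_COLUMNS]
        expected = self.schema.feature_names
        if feature_cols != expected:
            raise SchemaMismatchError(
                _columns_hash(expected), _columns_hash(feature_cols))
        self.snapshots = snapshots
        self.feature_names = feature_cols

    @classmethod
    def from_frames(
        cls,
        visits: pd.DataFrame,
        events: pd.DataFrame,
        grid: TimeGrid | None = None,
        schema: FeatureSchema | None = None,
        hyperparams: HyperParams | None = None,
    ) -> "AdmissionModel":
        """Build the snapshot matrix from visit/event tables and wrap it."""
        from .snapshots import snapshot_matrix

        grid = grid or make_time_grid()
        schema = schema or FeatureSchema()
        snaps = snapshot_matrix(visits, events, grid, schema)
        return cls(snaps, schema, hyperparams)

    def fit(self, seed: int | None = None) -> "AdmissionModelResults":
        """Fit the boosted ensemble; returns an :class:`AdmissionModelResults`.

        A 10% visit-level slice of the training data is held out for early
        stopping.  Deterministic for a fixed seed and input
        (single-threaded histogram builder).
        """
        hp = self.hyperparams
        seed = hp.seed if seed is None else seed
        y = self.snapshots["label"].to_numpy()
        if len(np.unique(y)) < 2:
            raise ValueError("training labels are single-class; cannot fit")
        fit_ids, val_ids = split_by_visit(
            self.snapshots["visit_id"].unique(), train_fraction=0.9, seed=seed)
        if len(val_ids) == 0:  # tiny cohorts: no early-stopping split
            fit_mask = np.ones(len(self.snapshots), dtype=bool)
            val_mask = None
        else:
            fit_mask = self.snapshots["visit_id"].isin(fit_ids).to_numpy()
            val_mask = ~fit_mask
            if len(np.unique(y[fit_mask])) < 2 or len(np.unique(y[val_mask])) < 2:
                fit_mask = np.ones(len(self.snapshots), dtype=bool)
                val_mask = None
        X = self.snapshots[self.feature_names].to_numpy(dtype=np.float32)

        clf = xgb.XGBClassifier(
            n_estimators=hp.n_rounds,
            colsample_bytree=hp.colsample_bytree,
            gamma=hp.gamma,
            learning_rate=hp.learning_rate,
            max_depth=hp.max_depth,
            min_child_weight=hp.min_child_weight,
            objective=hp.objective,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            early_stopping_rounds=(
                hp.early_stopping_rounds if val_mask is not None else None),
        )
        if val_mask is not None:
            clf.fit(X[fit_mask], y[fit_mask],
                    eval_set=[(X[val_mask], y[val_mask])], verbose=False)
        else:
            clf.fit(X, y, verbose=False)
        return AdmissionModelResults(
            model=self,
            booster=clf,
            schema_hash=self.schema.schema_hash(),
            columns_hash=_columns_hash(self.feature_names),
            seed=seed,
            n_train_visits=int(self.snapshots["visit_id"].nunique()),
            n_train_rows=int(len(self.snapshots)),
        )


@dataclass
class AdmissionModelResults:
    """A fitted admission model plus its input contract and diagnostics."""

    model: AdmissionModel
    booster: xgb.XGBClassifier
    schema_hash: str
    columns_hash: str
    seed: int
    n_train_visits: int
    n_train_rows: int
    _importance_cache: pd.Series | None = field(default=None, repr=False)

    @property
    def feature_names(self) -> list[str]:
        return self.model.feature_names

    def _check_schema(self, snapshots: pd.DataFrame) -> np.ndarray:
        cols = [c for c in snapshots.columns if c not in SNAPSHOT_ID_COLUMNS]
        given = _columns_hash(cols)
        if given != self.columns_hash:
            raise SchemaMismatchError(self.columns_hash, given)
        return snapshots[cols].to_numpy(dtype=np.float32)

    def predict_proba(self, snapshots: pd.DataFrame) -> np.ndarray:
        """Admission probability in [0,1] per snapshot row."""
        X = self._check_schema(snapshots)
        p = self.booster.predict_proba(X)[:, 1]
        return np.clip(p.astype(float), 0.0, 1.0)

    def feature_importances(self) -> pd.Series:
        """Gain-based importances, normalised to sum 1, sorted descending."""
        if self._importance_cache is None:
            raw = self.booster.get_booster().get_score(importance_type="gain")
            # boosters fit on bare arrays name features f0..fN
            scores = pd.Series(
                {name: raw.get(name, raw.get(f"f{i}", 0.0))
                 for i, name in enumerate(self.feature_names)},
                dtype=float,
            )
            total = scores.sum()
            if total > 0:
                scores = scores / total
            self._importance_cache = scores.sort_values(
                ascending=False, kind="mergesort")
        return self._importance_cache.copy()

    def evaluate_static(
        self,
        snapshots: pd.DataFrame,
        t_minutes: int | None = None,
        threshold: float = 0.5,
    ) -> tuple[ConfusionCounts, MetricSet, float | None]:
        """Fixed-time-point evaluation: counts, metrics and AUROC.

        Thresholds each row's probability at ``threshold`` (strictly
        greater ⇒ predicted admission, matching the lock-in rule).  AUROC
        is rank-based and ``None`` (flagged) on a single-class sample.
        """
        rows = snapshots
        if t_minutes is not None:
            rows = snapshots[snapshots["t_minutes"] == t_minutes]
            if len(rows) == 0:
                raise ValueError(f"no snapshot rows at t={t_minutes}")
        y = rows["label"].to_numpy().astype(bool)
        p = self.predict_proba(rows)
        pred = p > threshold
        counts = ConfusionCounts(
            tp=int((pred & y).sum()), tn=int((~pred & ~y).sum()),
            fp=int((pred & ~y).sum()), fn=int((~pred & y).sum()),
        )
        auroc = None if len(np.unique(y)) < 2 else float(roc_auc_score(y, p))
        return counts, confusion_metrics(counts), auroc

    def summary(self) -> str:
        hp = self.model.hyperparams
        best = getattr(self.booster, "best_iteration", None)
        lines = [
            "Admission model (gradient-boosted trees)",
            "=" * 44,
            f"training visits      : {self.n_train_visits}",
            f"training rows        : {self.n_train_rows}",
            f"features             : {len(self.feature_names)}",
            f"schema hash          : {self.schema_hash}",
            f"seed                 : {self.seed}",
            f"max boosting rounds  : {hp.n_rounds}"
            + (f" (stopped at {best})" if best is not None else ""),
            f"learning rate        : {hp.learning_rate}",
            f"max depth            : {hp.max_depth}",
            f"min child weight     : {hp.min_child_weight}",
            f"colsample_bytree     : {hp.colsample_bytree}",
            f"gamma                : {hp.gamma}",
            "",
            "top features (gain share):",
        ]
        for name, score in self.feature_importances().head(8).items():
            lines.append(f"  {name:<36s} {score:.3f}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> Path:
        """Persist to one JSON file: booster + schema + hyperparameters."""
        path = Path(path)
        payload = {
            "format": "edlockin-admission-model",
            "schema": json.loads(self.model.schema.to_json()),
            "columns_hash": self.columns_hash,
            "hyperparams": self.model.hyperparams.to_dict(),
            "seed": self.seed,
            "n_train_visits": self.n_train_visits,
            "n_train_rows": self.n_train_rows,
            "feature_names": self.feature_names,
            "booster": json.loads(
                self.booster.get_booster().save_raw("json").decode()),
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path) -> "AdmissionModelResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "edlockin-admission-model":
            raise ValueError(f"{path} is not a saved admission model")
        schema = FeatureSchema.from_json(json.dumps(payload["schema"]))
        hp = HyperParams(**payload["hyperparams"])
        clf = xgb.XGBClassifier()
        clf.load_model(bytearray(json.dumps(payload["booster"]).encode()))
        # empty model shell: carries schema + features, not training rows
        shell = cls.__new__(cls)
        shell.model = AdmissionModel.__new__(AdmissionModel)
        shell.model.schema = schema
        shell.model.hyperparams = hp
        shell.model.feature_names = payload["feature_names"]
        shell.model.snapshots = None
        shell.booster = clf
        shell.schema_hash = schema.schema_hash()
        shell.columns_hash = payload["columns_hash"]
        shell.seed = payload["seed"]
        shell.n_train_visits = payload["n_train_visits"]
        shell.n_train_rows = payload["n_train_rows"]
        shell._importance_cache = None
        return shell


def train_model(
    snapshots: pd.DataFrame,
    schema: FeatureSchema | None = None,
    hyperparams: HyperParams | None = None,
    seed: int | None = None,
) -> AdmissionModelResults:
    """Functional wrapper: build an :class:`AdmissionModel` and fit it."""
    return AdmissionModel(snapshots, schema, hyperparams).fit(seed=seed)


def predict_admission_probability(
    results: AdmissionModelResults, snapshots: pd.DataFrame
) -> np.ndarray:
    """Score snapshot rows with a fitted model (schema-checked)."""
    return results.predict_proba(snapshots)
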