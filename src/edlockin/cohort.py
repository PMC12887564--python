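"""Synthetic emergency-department cohort generation.

Real ED disposition data are not publicly shareable, so every downstream
stage of this package is exercised on synthetic cohorts that reproduce the
statistical structure the evaluation assumes: an adult population with a
~39.4% admission prevalence, subgroup mixes over age decades, presenting
specialty, Dutch triage urgency (U0--U5) and arrival period, clinician
decision-to-disposition times with a median of 151 (IQR 95-228) minutes
overall and 131 (IQR 75-201) minutes for admitted patients, and in-visit
clinical event streams (lab orders, vitals) whose informativeness about the
admission outcome grows over the stay.

Decision times are modelled as a two-parameter gamma distribution per
outcome.  The admitted-patient parameters are solved by least squares in
log-quantile space from the target quartiles; the discharged-patient
parameters are solved so that the outcome mixture at the configured
prevalence reproduces the overall quartiles.  A gamma is preferred over a
log-normal here because the target quartiles are less log-skewed than a
log-normal permits (the median exceeds the geometric mean of the quartiles),
and the gamma reproduces all three quartiles to within ~2 minutes.

Admission outcomes are drawn from a logistic propensity: each covariate
level (age bin, specialty, triage, arrival period) contributes its
anchor log-odds offset, and the intercept is calibrated per cohort so the
expected admitted fraction equals the configured prevalence.  Event streams
are per-category homogeneous Poisson processes whose rates (and value
distributions) depend on the admission outcome, scaled by
``signal_strength``; at t=0 only a triage-assignment event exists, so the
information available to a classifier grows with time since arrival.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields as dc_fields
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "AGE_BIN_LABELS",
    "SPECIALTY_LABELS",
    "TRIAGE_LABELS",
    "PART_OF_DAY_LABELS",
    "EVENT_CATEGORIES",
    "ConfigurationError",
    "CohortValidationError",
    "VisitRecord",
    "ClinicalEvent",
    "DecisionTimeModel",
    "GeneratorConfig",
    "gamma_from_quantiles",
    "sample_clinician_decision_time",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
]

# ---------------------------------------------------------------------------
# Label sets and default cohort composition
# ---------------------------------------------------------------------------

AGE_BIN_LABELS = (
    "18-27", "28-37", "38-47", "48-57", "58-67", "68-77", "78-87", "≥88",
)
SPECIALTY_LABELS = (
    "Obstetrics and gynecology",
    "Urology",
    "Orthopedics",
    "Neurology",
    "Gastrointestinal and liver diseases",
    "Pulmonology",
    "Otorhinolaryngology",
    "Internal medicine",
    "Surgery",
    "Cardiology",
)
TRIAGE_LABELS = ("Unknown", "U0", "U1", "U2", "U3", "U4", "U5")
PART_OF_DAY_LABELS = ("night", "morning", "afternoon", "evening")

# Default marginal mixes: proportional to observed subgroup sizes in a large
# Dutch ED evaluation cohort (~47k visits).  Joint structure is sampled
# independently per dimension; only the marginals are anchored.
_AGE_COUNTS = {
    "18-27": 4658, "28-37": 5312, "38-47": 4730, "48-57": 6064,
    "58-67": 7330, "68-77": 9437, "78-87": 7444, "≥88": 2332,
}
_SPECIALTY_COUNTS = {
    "Obstetrics and gynecology": 1003,
    "Urology": 1931,
    "Orthopedics": 1878,
    "Neurology": 4659,
    "Gastrointestinal and liver diseases": 2502,
    "Pulmonology": 6068,
    "Otorhinolaryngology": 643,
    "Internal medicine": 7810,
    "Surgery": 17720,
    "Cardiology": 916,
}
_TRIAGE_COUNTS = {
    "Unknown": 1355, "U0": 178, "U1": 4257, "U2": 18403,
    "U3": 17362, "U4": 5733, "U5": 19,
}
_PART_OF_DAY_COUNTS = {
    "night": 3311, "morning": 11251, "afternoon": 22093, "evening": 10652,
}

# Per-level admitted fractions in the same reference cohort.  These anchor
# the log-odds offsets of the admission propensity (relative to the
# reference prevalence) so that synthetic subgroups reproduce realistic
# admission-rate gradients: admission rises steeply with age and urgency.
_REFERENCE_PREVALENCE = 0.394
_ADMIT_SHARE = {
    "age_group": {
        "18-27": 0.1629, "28-37": 0.2204, "38-47": 0.2413, "48-57": 0.3312,
        "58-67": 0.4150, "68-77": 0.5167, "78-87": 0.5680, "≥88": 0.5974,
    },
    "specialty": {
        "Obstetrics and gynecology": 0.2891,
        "Urology": 0.4624,
        "Orthopedics": 0.1810,
        "Neurology": 0.4041,
        "Gastrointestinal and liver diseases": 0.6247,
        "Pulmonology": 0.5793,
        "Otorhinolaryngology": 0.1633,
        "Internal medicine": 0.5210,
        "Surgery": 0.2636,
        "Cardiology": 0.5426,
    },
    "triage": {
        "Unknown": 0.2930, "U0": 0.9663, "U1": 0.6005, "U2": 0.5151,
        "U3": 0.2766, "U4": 0.2105, "U5": 0.2105,
    },
    "part_of_day": {
        "night": 0.4527, "morning": 0.3852,
        "afternoon": 0.3825, "evening": 0.4070,
    },
}

# Event-stream process: category -> (base rate per hour, log-rate shift per
# unit signal, value-mean shift per unit signal).  Rates multiply by
# exp(±shift·signal/2) for admitted/discharged visits.  Lab-order categories
# mirror the feature families that dominate admission prediction in EDs
# (inflammation markers, kidney function, blood counts, blood cultures).
EVENT_CATEGORIES: Mapping[str, tuple[float, float, float]] = {
    "order:inflammation": (0.55, 0.90, 0.40),
    "order:kidney_function": (0.45, 0.70, 0.30),
    "order:blood_count": (0.65, 0.60, 0.30),
    "order:blood_culture": (0.10, 1.20, 0.20),
    "vital": (1.30, 0.30, 0.80),
}
TRIAGE_EVENT_CATEGORY = "triage_assigned"
_EVENT_WINDOW_MINUTES = 240.0  # events may fall past the 180-min horizon

_PART_OF_DAY_WINDOW = {
    "night": (0, 360), "morning": (360, 720),
    "afternoon": (720, 1080), "evening": (1080, 1440),
}
_AGE_BIN_RANGE = {
    "18-27": (18, 27), "28-37": (28, 37), "38-47": (38, 47),
    "48-57": (48, 57), "58-67": (58, 67), "68-77": (68, 77),
    "78-87": (78, 87), "≥88": (88, 99),
}

VISIT_COLUMNS = (
    "visit_id", "arrival_date_index", "arrival_minute_of_day", "age_years",
    "specialty", "triage", "admitted", "clinician_decision_minutes",
)
EVENT_COLUMNS = ("visit_id", "offset_minutes", "category", "value")


class ConfigurationError(ValueError):
    """A generator configuration field violates its contract."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"invalid GeneratorConfig.{field_name}: {message}")


class CohortValidationError(ValueError):
    """A visit or event table violates a cohort invariant."""


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VisitRecord:
    """One ED visit: demographics, context, outcome and clinician timing."""

    visit_id: str
    arrival_date_index: int
    arrival_minute_of_day: int
    age_years: int
    specialty: str
    triage: str
    admitted: bool
    clinician_decision_minutes: float

    def __post_init__(self) -> None:
        if self.age_years < 18:
            raise CohortValidationError(
                f"visit {self.visit_id}: age_years={self.age_years} < 18 "
                "(adult-only population)"
            )
        if self.specialty not in SPECIALTY_LABELS:
            raise CohortValidationError(
                f"visit {self.visit_id}: unknown specialty {self.specialty!r}"
            )
        if self.triage not in TRIAGE_LABELS:
            raise CohortValidationError(
                f"visit {self.visit_id}: unknown triage {self.triage!r}"
            )
        if not (0 <= self.arrival_minute_of_day < 1440):
            raise CohortValidationError(
                f"visit {self.visit_id}: arrival_minute_of_day out of [0,1440)"
            )
        t = self.clinician_decision_minutes
        if not np.isfinite(t) or t < 0:
            raise CohortValidationError(
                f"visit {self.visit_id}: clinician_decision_minutes={t!r} "
                "must be finite and non-negative"
            )


@dataclass(frozen=True)
class ClinicalEvent:
    """A timestamped in-visit observation or order."""

    visit_id: str
    offset_minutes: float
    category: str
    value: float

    def __post_init__(self) -> None:
        if self.offset_minutes < 0:
            raise CohortValidationError(
                f"event for visit {self.visit_id}: offset_minutes="
                f"{self.offset_minutes} < 0"
            )


# ---------------------------------------------------------------------------
# Decision-time calibration
# ---------------------------------------------------------------------------

def gamma_from_quantiles(q1: float, median: float, q3: float) -> tuple[float, float]:
    """Solve gamma (shape, scale) by least squares in log-quantile space.

    Minimises the squared log differences between the gamma quartiles and
    the targets ``(q1, median, q3)``.  Two parameters against three targets:
    the fit is exact only if the targets happen to be gamma quartiles, but
    in practice lands within a couple of minutes of each target.
    """
    if not (0 < q1 < median < q3):
        raise ValueError("require 0 < q1 < median < q3")
    targets = np.log([q1, median, q3])
    probs = np.array([0.25, 0.5, 0.75])

    def loss(params: np.ndarray) -> float:
        shape, scale = np.exp(params)
        q = scale * special.gammaincinv(shape, probs)
        return float(np.sum((np.log(q) - targets) ** 2))

    res = optimize.minimize(
        loss, x0=[np.log(2.0), np.log(median / 2.0)], method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    shape, scale = np.exp(res.x)
    return float(shape), float(scale)


@lru_cache(maxsize=32)
def _calibrate_decision_times(
    admitted_quartiles: tuple[float, float, float],
    overall_quartiles: tuple[float, float, float],
    prevalence: float,
) -> tuple[float, float, float, float]:
    """Solve per-outcome gamma parameters from target quartiles.

    The admitted-outcome gamma is fit directly; the discharged-outcome gamma
    is then fit so the prevalence-weighted mixture matches the overall
    quartiles.  Returns (shape_adm, scale_adm, shape_dis, scale_dis).
    """
    k_a, th_a = gamma_from_quantiles(*admitted_quartiles)
    targets = np.log(overall_quartiles)
    probs = (0.25, 0.5, 0.75)
    hi = 50.0 * overall_quartiles[2]

    def mixture_quartiles(params: np.ndarray) -> np.ndarray:
        k_d, th_d = np.exp(params)
        out = np.empty(3)
        for i, p in enumerate(probs):
            out[i] = optimize.brentq(
                lambda x: prevalence * stats.gamma.cdf(x, k_a, scale=th_a)
                + (1.0 - prevalence) * stats.gamma.cdf(x, k_d, scale=th_d)
                - p,
                1e-9, hi,
            )
        return out

    def loss(params: np.ndarray) -> float:
        return float(np.sum((np.log(mixture_quartiles(params)) - targets) ** 2))

    res = optimize.minimize(
        loss, x0=[np.log(2.5), np.log(overall_quartiles[1] / 2.5)],
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-13, "maxiter": 2000},
    )
    k_d, th_d = np.exp(res.x)
    return float(k_a), float(th_a), float(k_d), float(th_d)


@dataclass(frozen=True)
class DecisionTimeModel:
    """Gamma decision-time distributions for admitted and discharged visits."""

    admitted_shape: float
    admitted_scale: float
    discharged_shape: float
    discharged_scale: float

    @classmethod
    def calibrate(
        cls,
        admitted_quartiles: Sequence[float] = (75.0, 131.0, 201.0),
        overall_quartiles: Sequence[float] = (95.0, 151.0, 228.0),
        prevalence: float = _REFERENCE_PREVALENCE,
    ) -> "DecisionTimeModel":
        params = _calibrate_decision_times(
            tuple(float(x) for x in admitted_quartiles),
            tuple(float(x) for x in overall_quartiles),
            float(prevalence),
        )
        return cls(*params)

    def sample(self, admitted: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        admitted = np.asarray(admitted, dtype=bool)
        out = np.empty(admitted.shape, dtype=float)
        n_adm = int(admitted.sum())
        out[admitted] = rng.gamma(self.admitted_shape, self.admitted_scale, n_adm)
        out[~admitted] = rng.gamma(
            self.discharged_shape, self.discharged_scale, admitted.size - n_adm
        )
        return out


def sample_clinician_decision_time(
    admitted,
    rng: np.random.Generator,
    model: DecisionTimeModel | None = None,
):
    """Draw clinician decision-to-disposition times in minutes.

    ``admitted`` may be a scalar bool or a boolean array; a scalar input
    returns a scalar draw.
    """
    if model is None:
        model = DecisionTimeModel.calibrate()
    scalar = np.isscalar(admitted) or np.ndim(admitted) == 0
    draws = model.sample(np.atleast_1d(admitted), rng)
    return float(draws[0]) if scalar else draws


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

def _normalized(counts: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(counts.values()))
    return {k: v / total for k, v in counts.items()}


def _check_mix(name: str, mix: Mapping[str, float], labels: Sequence[str]) -> None:
    unknown = set(mix) - set(labels)
    if unknown:
        raise ConfigurationError(name, f"unknown levels {sorted(unknown)}")
    vals = np.array(list(mix.values()), dtype=float)
    if (vals < 0).any():
        raise ConfigurationError(name, "negative probability")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ConfigurationError(name, f"probabilities sum to {vals.sum()!r}, not 1")


@dataclass
class GeneratorConfig:
    """Everything needed to draw one reproducible synthetic cohort."""

    n_visits: int
    seed: int
    admission_prevalence: float = _REFERENCE_PREVALENCE
    age_mix: dict[str, float] = field(
        default_factory=lambda: _normalized(_AGE_COUNTS))
    specialty_mix: dict[str, float] = field(
        default_factory=lambda: _normalized(_SPECIALTY_COUNTS))
    triage_mix: dict[str, float] = field(
        default_factory=lambda: _normalized(_TRIAGE_COUNTS))
    part_of_day_mix: dict[str, float] = field(
        default_factory=lambda: _normalized(_PART_OF_DAY_COUNTS))
    admitted_decision_quartiles: tuple[float, float, float] = (75.0, 131.0, 201.0)
    overall_decision_quartiles: tuple[float, float, float] = (95.0, 151.0, 228.0)
    signal_strength: float = 1.0
    n_days: int = 365

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_visits, (int, np.integer)) or self.n_visits <= 0:
            raise ConfigurationError("n_visits", f"{self.n_visits!r} (need a positive integer)")
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed", f"{self.seed!r} (an explicit integer seed is required)")
        if not (0.0 < self.admission_prevalence < 1.0):
            raise ConfigurationError(
                "admission_prevalence",
                f"{self.admission_prevalence!r} (must lie strictly in (0,1))",
            )
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength", f"{self.signal_strength!r} (must be ≥ 0)")
        if self.n_days <= 0:
            raise ConfigurationError("n_days", f"{self.n_days!r} (must be positive)")
        _check_mix("age_mix", self.age_mix, AGE_BIN_LABELS)
        _check_mix("specialty_mix", self.specialty_mix, SPECIALTY_LABELS)
        _check_mix("triage_mix", self.triage_mix, TRIAGE_LABELS)
        _check_mix("part_of_day_mix", self.part_of_day_mix, PART_OF_DAY_LABELS)
        for name in ("admitted_decision_quartiles", "overall_decision_quartiles"):
            q = getattr(self, name)
            if len(q) != 3 or not (0 < q[0] < q[1] < q[2]):
                raise ConfigurationError(name, f"{q!r} (need increasing positive (q1, median, q3))")

    def decision_time_model(self) -> DecisionTimeModel:
        return DecisionTimeModel.calibrate(
            self.admitted_decision_quartiles,
            self.overall_decision_quartiles,
            self.admission_prevalence,
        )

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(sorted(unknown)[0], "unknown configuration key")
        for required in ("n_visits", "seed"):
            if required not in d:
                raise ConfigurationError(required, "required key is absent")
        kwargs = dict(d)
        for name in ("admitted_decision_quartiles", "overall_decision_quartiles"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _logit(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _sample_levels(
    rng: np.random.Generator, mix: Mapping[str, float], n: int
) -> np.ndarray:
    labels = np.array(list(mix.keys()), dtype=object)
    probs = np.array(list(mix.values()), dtype=float)
    return rng.choice(labels, size=n, p=probs / probs.sum())


def age_bin_label(age_years: int) -> str:
    """Decade age-group label for an adult age (final open bin ≥88)."""
    if age_years < 18:
        raise ValueError(f"age_years={age_years}: population excludes minors")
    if age_years >= 88:
        return "≥88"
    if age_years < 28:
        return "18-27"
    return AGE_BIN_LABELS[1 + (int(age_years) - 28) // 10]


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort: one visit table and one clinical-event table.

    Returns ``(visits, events)`` DataFrames with the canonical column sets
    (:data:`VISIT_COLUMNS`, :data:`EVENT_COLUMNS`).  Identical configs give
    bitwise-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n_visits)

    age_groups = _sample_levels(rng, config.age_mix, n)
    lo = np.array([_AGE_BIN_RANGE[g][0] for g in age_groups])
    hi = np.array([_AGE_BIN_RANGE[g][1] for g in age_groups])
    ages = lo + rng.integers(0, hi - lo + 1, size=n)

    specialty = _sample_levels(rng, config.specialty_mix, n)
    triage = _sample_levels(rng, config.triage_mix, n)
    pod = _sample_levels(rng, config.part_of_day_mix, n)
    win_lo = np.array([_PART_OF_DAY_WINDOW[p][0] for p in pod])
    win_hi = np.array([_PART_OF_DAY_WINDOW[p][1] for p in pod])
    arrival_minute = win_lo + rng.integers(0, win_hi - win_lo, size=n)
    arrival_date = rng.integers(0, config.n_days, size=n)

    # Admission propensity: additive log-odds anchors per covariate level,
    # intercept calibrated so the cohort's expected prevalence is exact.
    base = _logit(_REFERENCE_PREVALENCE)
    eta = np.zeros(n)
    for dim, levels in (
        ("age_group", age_groups), ("specialty", specialty),
        ("triage", triage), ("part_of_day", pod),
    ):
        share = _ADMIT_SHARE[dim]
        eta += np.array([_logit(share[lv]) - base for lv in levels])

    def mean_prob(intercept: float) -> float:
        return float(np.mean(special.expit(eta + intercept)))

    target = config.admission_prevalence
    intercept = optimize.brentq(lambda b: mean_prob(b) - target, -30.0, 30.0)
    p_admit = special.expit(eta + intercept)
    admitted = rng.random(n) < p_admit

    decision_times = config.decision_time_model().sample(admitted, rng)

    visit_ids = np.array([f"V{i:07d}" for i in range(n)], dtype=object)
    visits = pd.DataFrame({
        "visit_id": visit_ids,
        "arrival_date_index": arrival_date.astype(np.int64),
        "arrival_minute_of_day": arrival_minute.astype(np.int64),
        "age_years": ages.astype(np.int64),
        "specialty": specialty,
        "triage": triage,
        "admitted": admitted.astype(np.int64),
        "clinician_decision_minutes": decision_times,
    })

    events = _generate_events(rng, visit_ids, triage, admitted, config.signal_strength)
    return visits, events


def _generate_events(
    rng: np.random.Generator,
    visit_ids: np.ndarray,
    triage: np.ndarray,
    admitted: np.ndarray,
    signal_strength: float,
) -> pd.DataFrame:
    """Per-category Poisson event streams plus a t=0 triage-assignment event."""
    n = visit_ids.size
    z = np.where(admitted, 0.5, -0.5)  # centred outcome indicator

    frames = []
    # Triage assignment at arrival, value = numeric urgency (Unknown -> -1).
    urgency = np.array(
        [-1.0 if t == "Unknown" else float(t[1:]) for t in triage])
    frames.append(pd.DataFrame({
        "visit_id": visit_ids,
        "offset_minutes": np.zeros(n),
        "category": TRIAGE_EVENT_CATEGORY,
        "value": urgency,
    }))

    hours = _EVENT_WINDOW_MINUTES / 60.0
    for cat, (base_rate, rate_shift, value_shift) in EVENT_CATEGORIES.items():
        rate = base_rate * np.exp(rate_shift * signal_strength * z)
        counts = rng.poisson(rate * hours)
        total = int(counts.sum())
        idx = np.repeat(np.arange(n), counts)
        offsets = np.round(rng.uniform(0.0, _EVENT_WINDOW_MINUTES, total), 1)
        values = rng.normal(value_shift * signal_strength * z[idx], 1.0)
        frames.append(pd.DataFrame({
            "visit_id": visit_ids[idx],
            "offset_minutes": offsets,
            "category": cat,
            "value": np.round(values, 4),
        }))

    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(
        ["visit_id", "offset_minutes", "category", "value"], kind="mergesort"
    ).reset_index(drop=True)
    return events


# ---------------------------------------------------------------------------
# Validation and I/O
# ---------------------------------------------------------------------------

def validate_cohort(visits: pd.DataFrame, events: pd.DataFrame) -> None:
    """Raise :class:`CohortValidationError` on any violated invariant."""
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise CohortValidationError(f"visit table missing columns {sorted(missing)}")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise CohortValidationError(f"event table missing columns {sorted(missing)}")
    if visits["visit_id"].duplicated().any():
        dup = visits.loc[visits["visit_id"].duplicated(), "visit_id"].iloc[0]
        raise CohortValidationError(f"duplicated visit_id {dup!r}")
    if (visits["age_years"] < 18).any():
        raise CohortValidationError("age_years < 18 present (adult-only population)")
    t = visits["clinician_decision_minutes"]
    if (~np.isfinite(t)).any() or (t < 0).any():
        raise CohortValidationError("clinician_decision_minutes must be finite and ≥ 0")
    bad_spec = set(visits["specialty"]) - set(SPECIALTY_LABELS)
    if bad_spec:
        raise CohortValidationError(f"unknown specialty labels {sorted(bad_spec)}")
    bad_triage = set(visits["triage"]) - set(TRIAGE_LABELS)
    if bad_triage:
        raise CohortValidationError(f"unknown triage labels {sorted(bad_triage)}")
    if (events["offset_minutes"] < 0).any():
        raise CohortValidationError("event offset_minutes < 0")
    orphans = set(events["visit_id"]) - set(visits["visit_id"])
    if orphans:
        raise CohortValidationError(
            f"{len(orphans)} event(s) reference missing visits, e.g. {sorted(orphans)[:3]}"
        )


def write_cohort(visits: pd.DataFrame, events: pd.DataFrame, out_dir) -> tuple[Path, Path]:
    """Write ``visits.csv`` and ``events.csv`` (UTF-8, RFC-4180)."""
    validate_cohort(visits, events)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    visits_path = out / "visits.csv"
    events_path = out / "events.csv"
    visits[list(VISIT_COLUMNS)].to_csv(visits_path, index=False, encoding="utf-8")
    events[list(EVENT_COLUMNS)].to_csv(events_path, index=False, encoding="utf-8")
    return visits_path, events_path


def read_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort` and re-validate it."""
    in_dir = Path(in_dir)
    visits = pd.read_csv(
        in_dir / "visits.csv",
        dtype={"visit_id": str, "specialty": str, "triage": str},
        encoding="utf-8",
    )
    events = pd.read_csv(
        in_dir / "events.csv",
        dtype={"visit_id": str, "category": str},
        encoding="utf-8",
    )
    validate_cohort(visits, events)
    return visits, events
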