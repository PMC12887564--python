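"""Synthetic cohort generator: determinism, calibration, validation, I/O."""

import numpy as np
import pandas as pd
import pytest

import edlockin as edl
from edlockin.cohort import (
    AGE_BIN_LABELS,
    PART_OF_DAY_LABELS,
    SPECIALTY_LABELS,
    TRIAGE_LABELS,
    ConfigurationError,
    CohortValidationError,
    DecisionTimeModel,
    gamma_from_quantiles,
    validate_cohort,
)


class TestConfigValidation:
    def test_invalid_fields_name_the_offender(self):
        with pytest.raises(ConfigurationError, match="n_visits"):
            edl.GeneratorConfig(n_visits=0, seed=1)
        with pytest.raises(ConfigurationError, match="admission_prevalence"):
            edl.GeneratorConfig(n_visits=10, seed=1, admission_prevalence=1.0)
        with pytest.raises(ConfigurationError, match="seed"):
            edl.GeneratorConfig(n_visits=10, seed=None)
        with pytest.raises(ConfigurationError, match="signal_strength"):
            edl.GeneratorConfig(n_visits=10, seed=1, signal_strength=-0.5)

    def test_mix_must_sum_to_one(self):
        bad = {k: 0.5 for k in PART_OF_DAY_LABELS}
        with pytest.raises(ConfigurationError, match="part_of_day_mix"):
            edl.GeneratorConfig(n_visits=10, seed=1, part_of_day_mix=bad)

    def test_mix_rejects_unknown_levels(self):
        bad = {"night": 0.5, "midday": 0.5}
        with pytest.raises(ConfigurationError, match="part_of_day_mix"):
            edl.GeneratorConfig(n_visits=10, seed=1, part_of_day_mix=bad)

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ConfigurationError, match="n_patients"):
            edl.GeneratorConfig.from_dict({"n_visits": 5, "seed": 1, "n_patients": 5})


class TestGenerateCohort:
    def test_seed_determinism_bitwise(self):
        cfg = edl.GeneratorConfig(n_visits=400, seed=7)
        v1, e1 = edl.generate_cohort(cfg)
        v2, e2 = edl.generate_cohort(edl.GeneratorConfig(n_visits=400, seed=7))
        pd.testing.assert_frame_equal(v1, v2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_different_seeds_differ(self):
        v1, _ = edl.generate_cohort(edl.GeneratorConfig(n_visits=400, seed=7))
        v2, _ = edl.generate_cohort(edl.GeneratorConfig(n_visits=400, seed=8))
        assert not v1.equals(v2)

    def test_row_count_and_invariants(self, small_cohort):
        visits, events = small_cohort
        assert len(visits) == 600
        validate_cohort(visits, events)  # no raise
        assert visits["age_years"].min() >= 18
        assert set(visits["specialty"]) <= set(SPECIALTY_LABELS)
        assert set(visits["triage"]) <= set(TRIAGE_LABELS)
        assert (visits["clinician_decision_minutes"] >= 0).all()
        assert (events["offset_minutes"] >= 0).all()

    def test_prevalence_recovery_within_3se(self):
        n = 50_000
        cfg = edl.GeneratorConfig(n_visits=n, seed=29)
        visits, _ = edl.generate_cohort(cfg)
        p = cfg.admission_prevalence
        se = np.sqrt(p * (1 - p) / n)
        assert abs(visits["admitted"].mean() - p) < 3 * se

    def test_categorical_mix_recovery_within_3se(self):
        n = 50_000
        cfg = edl.GeneratorConfig(n_visits=n, seed=31)
        visits, _ = edl.generate_cohort(cfg)
        for column, mix in (
            ("specialty", cfg.specialty_mix),
            ("triage", cfg.triage_mix),
        ):
            observed = visits[column].value_counts(normalize=True)
            for level, p in mix.items():
                se = np.sqrt(p * (1 - p) / n)
                assert abs(observed.get(level, 0.0) - p) <= 3 * se, (column, level)

    def test_admission_rate_rises_with_age_and_urgency(self):
        visits, _ = edl.generate_cohort(edl.GeneratorConfig(n_visits=30_000, seed=13))
        by_age = visits.groupby(
            visits["age_years"].map(edl.age_bin))["admitted"].mean()
        assert by_age["≥88"] > by_age["18-27"] + 0.2
        by_triage = visits.groupby("triage")["admitted"].mean()
        assert by_triage["U0"] > 0.8
        assert by_triage["U0"] > by_triage["U3"] > by_triage["U4"] - 0.05

    def test_every_visit_has_triage_event_at_zero(self, small_cohort):
        visits, events = small_cohort
        at_zero = events[(events["category"] == "triage_assigned")]
        assert (at_zero["offset_minutes"] == 0).all()
        assert set(at_zero["visit_id"]) == set(visits["visit_id"])

    def test_zero_signal_removes_event_outcome_association(self):
        cfg = edl.GeneratorConfig(n_visits=8000, seed=17, signal_strength=0.0)
        visits, events = edl.generate_cohort(cfg)
        counts = (events[events["category"] != "triage_assigned"]
                  .groupby("visit_id").size()
                  .reindex(visits["visit_id"]).fillna(0).to_numpy())
        admitted = visits["admitted"].to_numpy().astype(bool)
        # difference of mean event counts should be within noise
        diff = counts[admitted].mean() - counts[~admitted].mean()
        pooled_se = np.sqrt(counts[admitted].var() / admitted.sum()
                            + counts[~admitted].var() / (~admitted).sum())
        assert abs(diff) < 4 * pooled_se


class TestDecisionTimes:
    def test_gamma_quantile_solver_roundtrip(self):
        # targets that ARE gamma quartiles must be recovered exactly
        from scipy import stats
        q = stats.gamma.ppf([0.25, 0.5, 0.75], 2.3, scale=60.0)
        shape, scale = gamma_from_quantiles(*q)
        assert shape == pytest.approx(2.3, rel=1e-4)
        assert scale == pytest.approx(60.0, rel=1e-4)

    def test_admitted_sample_quartiles_match_targets(self):
        rng = np.random.default_rng(101)
        draws = edl.sample_clinician_decision_time(
            np.ones(100_000, dtype=bool), rng)
        q1, med, q3 = np.percentile(draws, [25, 50, 75])
        assert 125 <= med <= 137
        assert 70 <= q1 <= 80
        assert 192 <= q3 <= 210

    def test_mixture_median_matches_overall_target(self):
        rng = np.random.default_rng(103)
        admitted = rng.random(100_000) < 0.394
        draws = edl.sample_clinician_decision_time(admitted, rng)
        assert 144 <= np.median(draws) <= 158
        assert (draws >= 0).all()

    def test_scalar_draw_nonnegative(self):
        rng = np.random.default_rng(1)
        for admitted in (True, False):
            t = edl.sample_clinician_decision_time(admitted, rng)
            assert isinstance(t, float) and t >= 0

    def test_discharged_slower_than_admitted(self):
        model = DecisionTimeModel.calibrate()
        from scipy import stats
        med_adm = stats.gamma.ppf(0.5, model.admitted_shape, scale=model.admitted_scale)
        med_dis = stats.gamma.ppf(0.5, model.discharged_shape, scale=model.discharged_scale)
        assert med_dis > med_adm


class TestCohortIO:
    def test_write_read_roundtrip(self, small_cohort, tmp_path):
        visits, events = small_cohort
        edl.write_cohort(visits, events, tmp_path)
        v2, e2 = edl.read_cohort(tmp_path)
        pd.testing.assert_frame_equal(
            visits.reset_index(drop=True), v2, check_dtype=False)
        pd.testing.assert_frame_equal(
            events.reset_index(drop=True), e2, check_dtype=False)

    def test_visit_without_events_still_serialized(self, tmp_path):
        from conftest import make_visit

        visits = pd.DataFrame([make_visit("V1")])
        events = pd.DataFrame(
            columns=["visit_id", "offset_minutes", "category", "value"])
        edl.write_cohort(visits, events, tmp_path)
        v2, e2 = edl.read_cohort(tmp_path)
        assert list(v2["visit_id"]) == ["V1"]
        assert len(e2) == 0

    def test_orphan_event_rejected(self, small_cohort, tmp_path):
        visits, events = small_cohort
        bad = pd.concat([events, pd.DataFrame([{
            "visit_id": "NOPE", "offset_minutes": 5.0,
            "category": "vital", "value": 0.0}])], ignore_index=True)
        with pytest.raises(CohortValidationError, match="missing visits"):
            edl.write_cohort(visits, bad, tmp_path)

    def test_negative_offset_rejected(self, small_cohort, tmp_path):
        visits, events = small_cohort
        bad = events.copy()
        bad.loc[bad.index[0], "offset_minutes"] = -1.0
        with pytest.raises(CohortValidationError, match="offset"):
            edl.write_cohort(visits, bad, tmp_path)


def test_visit_record_rejects_minors_and_bad_labels():
    kwargs = dict(visit_id="V1", arrival_date_index=0, arrival_minute_of_day=10,
                  age_years=44, specialty="Surgery", triage="U2",
                  admitted=True, clinician_decision_minutes=90.0)
    edl.VisitRecord(**kwargs)  # valid
    with pytest.raises(CohortValidationError):
        edl.VisitRecord(**{**kwargs, "age_years": 17})
    with pytest.raises(CohortValidationError):
        edl.VisitRecord(**{**kwargs, "triage": "U9"})
    with pytest.raises(CohortValidationError):
        edl.VisitRecord(**{**kwargs, "clinician_decision_minutes": -3.0})
    with pytest.raises(CohortValidationError):
        edl.ClinicalEvent("V1", -0.5, "vital", 0.0)
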