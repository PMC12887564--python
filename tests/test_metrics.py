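"""Metric arithmetic, binning, quantiles, stratification and crosstabs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import edlockin as edl
from edlockin.metrics import (
    ConfusionCounts,
    always_admit_accuracy,
    never_admit_accuracy,
    round_half_up,
    stratification_table,
)
from reference_tables import REFERENCE_ROWS


class TestConfusionMetrics:
    def test_reference_table_cells_reproduced(self):
        """All printed subgroup rows: counts reproduce every 2-dp metric cell."""
        for row in REFERENCE_ROWS:
            c = ConfusionCounts(row.tp, row.tn, row.fp, row.fn)
            assert c.n == row.n, row.level
            m = edl.confusion_metrics(c).rounded(2)
            assert m.precision == pytest.approx(row.precision), row.level
            assert m.recall == pytest.approx(row.recall), row.level
            assert m.accuracy == pytest.approx(row.accuracy), row.level
            if not row.majority_discordant:
                assert round_half_up(edl.majority_accuracy(c)) == pytest.approx(
                    row.majority_accuracy), row.level

    def test_undefined_metrics_flagged_not_zero(self):
        m = edl.confusion_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.precision is None and m.f1 is None
        assert m.recall is None  # no admitted visits either
        assert m.accuracy == 1.0
        with pytest.raises(ValueError):
            edl.confusion_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_f1_is_harmonic_mean(self):
        m = edl.confusion_metrics(ConfusionCounts(50, 30, 10, 20))
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestMajorityBaseline:
    @pytest.mark.parametrize("counts,expected", [
        ((2852, 11758, 1290, 1820), 0.74),   # larger class = discharged
        ((1300, 1175, 637, 199), 0.55),      # larger class = discharged, close call
        ((170, 0, 6, 2), 0.97),              # nearly everyone admitted
    ])
    def test_better_direction_rule(self, counts, expected):
        c = ConfusionCounts(*counts)
        assert round_half_up(edl.majority_accuracy(c)) == pytest.approx(expected)

    def test_balanced_classes_give_half(self):
        c = ConfusionCounts(tp=10, tn=10, fp=15, fn=15)
        assert edl.majority_accuracy(c) == 0.5

    def test_directional_variants_bracket_majority(self):
        c = ConfusionCounts(346, 3561, 338, 413)
        maj = edl.majority_accuracy(c)
        assert maj == max(always_admit_accuracy(c), never_admit_accuracy(c))
        assert always_admit_accuracy(c) + never_admit_accuracy(c) == pytest.approx(1.0)

    def test_dominates_prevalence(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 40, 4)
            if tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            prev = (c.tp + c.fn) / c.n
            assert edl.majority_accuracy(c) >= max(prev, 1 - prev) - 1e-12


class TestBinning:
    @pytest.mark.parametrize("age,label", [
        (18, "18-27"), (27, "18-27"), (28, "28-37"), (37, "28-37"),
        (47, "38-47"), (57, "48-57"), (67, "58-67"), (77, "68-77"),
        (87, "78-87"), (88, "≥88"), (99, "≥88"),
    ])
    def test_age_bins(self, age, label):
        assert edl.age_bin(age) == label

    def test_minor_rejected(self):
        with pytest.raises(ValueError):
            edl.age_bin(17)

    @pytest.mark.parametrize("minute,label", [
        (0, "night"), (359, "night"), (360, "morning"), (719, "morning"),
        (720, "afternoon"), (1079, "afternoon"), (1080, "evening"),
        (1439, "evening"),
    ])
    def test_part_of_day_half_open_windows(self, minute, label):
        assert edl.part_of_day(minute) == label

    def test_out_of_range_minute_rejected(self):
        for m in (-1, 1440):
            with pytest.raises(ValueError):
                edl.part_of_day(m)


class TestMedianIqr:
    def test_odd_length_exact(self):
        s = edl.median_iqr([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3) == (3, 2, 4)

    def test_single_value_degenerate(self):
        s = edl.median_iqr([42.0])
        assert (s.median, s.q1, s.q3) == (42.0, 42.0, 42.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            edl.median_iqr([])

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            values = rng.normal(size=rng.integers(1, 500)) * 100
            s = edl.median_iqr(values)
            srt = np.sort(values)

            def quantile(p):
                h = (len(srt) - 1) * p
                lo = int(np.floor(h))
                hi = min(lo + 1, len(srt) - 1)
                return srt[lo] + (h - lo) * (srt[hi] - srt[lo])

            assert s.q1 == pytest.approx(quantile(0.25), abs=1e-9)
            assert s.median == pytest.approx(quantile(0.5), abs=1e-9)
            assert s.q3 == pytest.approx(quantile(0.75), abs=1e-9)


def test_round_half_up_at_boundary():
    assert round_half_up(0.515) == 0.52
    assert round_half_up(0.585) == 0.59
    assert round_half_up(0.5849) == 0.58


def _decisions_fixture(rng, n=200):
    """A synthetic joined-decisions frame for stratification tests."""
    from edlockin.metrics import DIMENSION_LEVELS

    levels = {d: list(v) for d, v in DIMENSION_LEVELS.items()}
    out = pd.DataFrame({
        "visit_id": [f"V{i}" for i in range(n)],
        "outcome_class": rng.choice(["TP", "TN", "FP", "FN"], n),
        "age_group": rng.choice(levels["age_group"], n),
        "specialty": rng.choice(levels["specialty"], n),
        "triage": rng.choice(levels["triage"], n),
        "part_of_day": rng.choice(levels["part_of_day"], n),
    })
    saved = rng.normal(100, 40, n)
    out["time_saved_minutes"] = np.where(out["outcome_class"] == "TP", saved, np.nan)
    out["clinician_decision_minutes"] = rng.gamma(3, 50, n)
    out["ai_decision_minutes"] = rng.choice(np.arange(0, 190, 10), n)
    return out


class TestStratify:
    def test_partition_conservation_all_dimensions(self):
        decisions = _decisions_fixture(np.random.default_rng(5))
        total = len(decisions)
        for dim in ("age_group", "specialty", "triage", "part_of_day"):
            strat = edl.stratify(decisions, dim)
            assert sum(c.n for c, _, _ in strat.values()) == total
            # per-level counts equal a brute-force group-and-count
            for level, (c, _, _) in strat.items():
                sub = decisions[decisions[dim] == level]
                for cls, attr in (("TP", "tp"), ("TN", "tn"), ("FP", "fp"), ("FN", "fn")):
                    assert getattr(c, attr) == (sub["outcome_class"] == cls).sum()

    def test_time_saved_over_tp_only(self):
        decisions = _decisions_fixture(np.random.default_rng(6))
        strat = edl.stratify(decisions, "part_of_day")
        for level, (_, _, summary) in strat.items():
            tp = decisions[(decisions["part_of_day"] == level)
                           & (decisions["outcome_class"] == "TP")]
            if len(tp) == 0:
                assert summary is None
            else:
                assert summary.n == len(tp)
                assert summary.median == pytest.approx(
                    np.median(tp["time_saved_minutes"]))

    def test_single_level_cohort(self):
        decisions = _decisions_fixture(np.random.default_rng(7))
        decisions["specialty"] = "Cardiology"
        strat = edl.stratify(decisions, "specialty")
        assert list(strat) == ["Cardiology"]

    def test_unknown_dimension_and_unjoined_rows_rejected(self):
        decisions = _decisions_fixture(np.random.default_rng(8))
        with pytest.raises(ValueError, match="unknown dimension"):
            edl.stratify(decisions, "weekday")
        broken = decisions.drop(columns=["triage"])
        with pytest.raises(ValueError, match="join"):
            edl.stratify(broken, "triage")

    def test_table_rendering_has_raw_and_rounded(self):
        decisions = _decisions_fixture(np.random.default_rng(9))
        table = stratification_table(edl.stratify(decisions, "age_group"), "age_group")
        assert {"precision", "precision_raw", "n_tp", "time_saved_median"} <= set(table.columns)


class TestCoherenceCrosstab:
    def test_cell_medians_match_filter_oracle(self):
        decisions = _decisions_fixture(np.random.default_rng(10), n=400)
        tab = edl.coherence_crosstab(decisions, "age_group", "part_of_day")
        assert tab.shape == (8, 4)
        for a in tab.index:
            for b in tab.columns:
                cell = decisions[(decisions["age_group"] == a)
                                 & (decisions["part_of_day"] == b)
                                 & (decisions["outcome_class"] == "TP")]
                if len(cell) == 0:
                    assert np.isnan(tab.loc[a, b])
                else:
                    assert tab.loc[a, b] == pytest.approx(
                        np.median(cell["time_saved_minutes"]))

    def test_empty_cell_is_nan_not_zero(self):
        decisions = _decisions_fixture(np.random.default_rng(11), n=30)
        decisions.loc[decisions["triage"] == "U5", "outcome_class"] = "TN"
        tab = edl.coherence_crosstab(decisions, "triage", "part_of_day")
        assert tab.loc["U5"].isna().all()

    def test_identical_dimensions_rejected(self):
        decisions = _decisions_fixture(np.random.default_rng(12))
        with pytest.raises(ValueError, match="distinct"):
            edl.coherence_crosstab(decisions, "triage", "triage")


@settings(max_examples=50, deadline=None)
@given(tp=st.integers(0, 500), tn=st.integers(0, 500),
       fp=st.integers(0, 500), fn=st.integers(0, 500))
def test_metric_identities_property(tp, tn, fp, fn):
    """Accuracy and F1 identities hold for every non-empty confusion table."""
    if tp + tn + fp + fn == 0:
        return
    c = ConfusionCounts(tp, tn, fp, fn)
    m = edl.confusion_metrics(c)
    assert m.accuracy == (tp + tn) / c.n
    for v in (m.precision, m.recall, m.accuracy, m.f1, m.majority_accuracy):
        assert v is None or 0.0 <= v <= 1.0
    if m.precision is not None and m.recall is not None and m.precision + m.recall > 0:
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall))
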