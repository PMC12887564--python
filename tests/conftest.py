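import numpy as np
import pandas as pd
import pytest

import edlockin as edl


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-visit synthetic cohort shared across test modules."""
    cfg = edl.GeneratorConfig(n_visits=600, seed=11)
    visits, events = edl.generate_cohort(cfg)
    return visits, events


@pytest.fixture(scope="session")
def small_snapshots(small_cohort):
    visits, events = small_cohort
    return edl.snapshot_matrix(visits, events)


@pytest.fixture(scope="session")
def cheap_hp():
    """Shallow, few-round boosting config for fast unit tests."""
    return edl.HyperParams(n_rounds=40, max_depth=5, min_child_weight=2, seed=3)


@pytest.fixture(scope="session")
def fitted(small_cohort, small_snapshots, cheap_hp):
    """(results, train_ids, test_ids) for the shared small cohort."""
    visits, _ = small_cohort
    train_ids, test_ids = edl.split_by_visit(visits["visit_id"], 0.8, seed=5)
    train = small_snapshots[small_snapshots["visit_id"].isin(train_ids)]
    results = edl.AdmissionModel(train, hyperparams=cheap_hp).fit()
    return results, train_ids, test_ids


@pytest.fixture(scope="session")
def lock_results(small_cohort, small_snapshots, fitted):
    visits, _ = small_cohort
    results, _, test_ids = fitted
    test = small_snapshots[small_snapshots["visit_id"].isin(test_ids)]
    return edl.LockInEvaluation(results, test, visits).run()


def make_visit(visit_id="V1", admitted=True, **overrides):
    """A single hand-built visit row for boundary tests."""
    row = {
        "visit_id": visit_id,
        "arrival_date_index": 0,
        "arrival_minute_of_day": 600,
        "age_years": 54,
        "specialty": "Surgery",
        "triage": "U2",
        "admitted": int(admitted),
        "clinician_decision_minutes": 120.0,
    }
    row.update(overrides)
    return pd.Series(row)


def make_events(visit_id, rows):
    """Event frame from (offset, category, value) triples."""
    return pd.DataFrame(
        [{"visit_id": visit_id, "offset_minutes": o, "category": c, "value": v}
         for o, c, v in rows],
        columns=["visit_id", "offset_minutes", "category", "value"],
    )
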