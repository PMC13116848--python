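"""Index-event selection, intervention hierarchy and the volume filter."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokecost import cohort
from conftest import STUDY_END, STUDY_START


@pytest.fixture(scope="module")
def toy_events(toy_tables):
    patients, providers, hosp, _ = toy_tables
    return cohort.select_index_events(hosp, patients, providers, STUDY_START, STUDY_END)


def test_earliest_i63_admission_selected(toy_events):
    events, _ = toy_events
    p1 = events[events["patient_id"] == "P1"].iloc[0]
    assert p1["index_date"] == pd.Timestamp("2018-03-01")
    assert p1["primary_claim_id"] == "H01"


def test_under18_excluded_with_reason(toy_events):
    events, rejects = toy_events
    assert "P2" not in set(events["patient_id"])
    assert rejects.set_index("patient_id").loc["P2", "reason"] == cohort.REASON_UNDER18


def test_90day_follow_up_boundary(toy_events):
    """Admission 2020-08-01 leaves <90 days before study end 2020-10-02 ->
    excluded; 2020-07-01 -> included."""
    events, rejects = toy_events
    assert "P3" not in set(events["patient_id"])
    assert rejects.set_index("patient_id").loc["P3", "reason"] == cohort.REASON_LATE_INDEX
    assert "P4" in set(events["patient_id"])


def test_intervention_hierarchy_and_partition(toy_events):
    events, _ = toy_events
    by_pid = events.set_index("patient_id")["intervention"]
    assert by_pid["P1"] == "thrombectomy"  # both flags set -> thrombectomy wins
    assert by_pid["P5"] == "thrombolysis"
    assert by_pid["P6"] == "other"
    assert set(events["intervention"]) <= {"thrombectomy", "thrombolysis", "other"}


def test_classify_intervention_scalar_and_array():
    assert cohort.classify_intervention(True, True) == "thrombectomy"
    assert cohort.classify_intervention(False, True) == "thrombolysis"
    assert cohort.classify_intervention(False, False) == "other"
    out = cohort.classify_intervention([True, False], [True, True])
    assert list(out) == ["thrombectomy", "thrombolysis"]


def test_los_in_whole_days(toy_events):
    events, _ = toy_events
    los = events.set_index("patient_id")["los"]
    assert los["P1"] == 9
    assert los["P6"] == 0


def test_missing_birth_date_rejected(toy_tables):
    patients, providers, hosp, _ = toy_tables
    pat = patients.copy()
    pat.loc[pat["patient_id"] == "P6", "birth_date"] = pd.NaT
    events, rejects = cohort.select_index_events(hosp, pat, providers, STUDY_START, STUDY_END)
    assert "P6" not in set(events["patient_id"])
    assert rejects.set_index("patient_id").loc["P6", "reason"] == cohort.REASON_BAD_RECORD


def test_malformed_dx_rejected(toy_tables):
    patients, providers, hosp, _ = toy_tables
    bad = hosp.copy()
    bad.loc[bad["claim_id"] == "H10", "main_dx"] = ""
    events, rejects = cohort.select_index_events(bad, patients, providers, STUDY_START, STUDY_END)
    assert "P6" not in set(events["patient_id"])
    assert cohort.REASON_BAD_RECORD in set(rejects["reason"])


def test_same_day_tie_broken_by_claim_id(toy_tables):
    patients, providers, hosp, _ = toy_tables
    dup = hosp.copy()
    extra = dup[dup["claim_id"] == "H01"].assign(claim_id="H00", cost=123.0)
    dup = pd.concat([dup, extra], ignore_index=True)
    events, _ = cohort.select_index_events(dup, patients, providers, STUDY_START, STUDY_END)
    assert events.set_index("patient_id").loc["P1", "primary_claim_id"] == "H00"


def test_idempotence_on_selected_claims(toy_tables):
    """Re-running selection on only the selected index claims returns the
    same index set."""
    patients, providers, hosp, _ = toy_tables
    events, _ = cohort.select_index_events(hosp, patients, providers, STUDY_START, STUDY_END)
    subset = hosp[hosp["claim_id"].isin(events["primary_claim_id"])]
    again, _ = cohort.select_index_events(subset, patients, providers, STUDY_START, STUDY_END)
    pd.testing.assert_frame_equal(
        events.sort_values("patient_id").reset_index(drop=True),
        again.sort_values("patient_id").reset_index(drop=True),
    )


# --- volume filter ---------------------------------------------------------


def _events_for_providers(counts: dict[str, int]) -> pd.DataFrame:
    rows = []
    i = 0
    for prov, n in counts.items():
        for _ in range(n):
            i += 1
            rows.append({"patient_id": f"P{i}", "provider_id": prov, "provider_type": "PSC"})
    return pd.DataFrame(rows)


def test_volume_filter_boundary():
    events = _events_for_providers({"A": 29, "B": 30})
    kept, excluded, rejects = cohort.apply_volume_filter(events, min_volume=30)
    assert excluded == ["A"]
    assert len(kept) == 30 and set(kept["provider_id"]) == {"B"}
    assert len(rejects) == 29 and set(rejects["reason"]) == {cohort.REASON_LOW_VOLUME}


def test_volume_filter_two_providers_counting():
    events = _events_for_providers({"A": 29, "B": 31})
    kept, _, _ = cohort.apply_volume_filter(events, min_volume=30)
    assert len(kept) == 31
    assert kept["provider_id"].nunique() == 1


def test_volume_filter_single_pass_not_iterative():
    """Exclusion is computed on pre-filter counts: a provider keeping exactly
    min_volume events stays even if removals elsewhere change nothing."""
    events = _events_for_providers({"A": 30, "B": 10})
    kept, excluded, _ = cohort.apply_volume_filter(events, min_volume=30)
    assert excluded == ["B"] and len(kept) == 30


def test_volume_filter_rejects_bad_min_volume():
    with pytest.raises(ValueError):
        cohort.apply_volume_filter(_events_for_providers({"A": 5}), min_volume=0)


@settings(deadline=None, max_examples=25)
@given(
    counts=st.dictionaries(
        st.sampled_from(["A", "B", "C", "D", "E"]), st.integers(0, 60), min_size=1
    ),
    mv1=st.integers(1, 50),
    mv2=st.integers(1, 50),
)
def test_volume_filter_monotone_in_threshold(counts, mv1, mv2):
    """Raising min_volume never increases the number of kept events."""
    events = _events_for_providers({k: v for k, v in counts.items() if v > 0})
    if events.empty:
        return
    lo, hi = sorted((mv1, mv2))
    kept_lo, _, _ = cohort.apply_volume_filter(events, lo)
    kept_hi, _, _ = cohort.apply_volume_filter(events, hi)
    assert len(kept_hi) <= len(kept_lo)
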