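"""Cohort construction from raw claim tables.

Operationalization rules:

* the index event is the patient's earliest hospitalization within the study
  window whose main diagnosis is ICD-10 I63 (any subcode);
* patients younger than 18 at the index admission are excluded;
* the index admission must leave a full 90-day follow-up before the study end
  (index_date + 90 days <= study_end);
* intervention is classified from the procedure flags on the index claim with
  the hierarchy thrombectomy > thrombolysis > other;
* every episode is attributed to the provider reporting the index
  hospitalization;
* providers with fewer than ``min_volume`` index events (computed once, on
  pre-filter counts) are removed together with their patients.

All exclusions are returned as a rejects table with reason codes
(BAD_RECORD, UNDER18, LATE_INDEX, LOW_VOLUME).
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

INDEX_DX_PREFIX = "I63"

REASON_UNDER18 = "UNDER18"
REASON_LATE_INDEX = "LATE_INDEX"
REASON_LOW_VOLUME = "LOW_VOLUME"
REASON_BAD_RECORD = "BAD_RECORD"

INDEX_EVENT_COLUMNS = [
    "patient_id",
    "index_date",
    "primary_claim_id",
    "provider_id",
    "provider_type",
    "age_at_index",
    "sex",
    "intervention",
    "los",
]


def _reject(frame: pd.DataFrame, reason: str) -> pd.DataFrame:
    out = frame[["patient_id"]].copy()
    out["reason"] = reason
    return out


def classify_intervention(has_thrombectomy, has_thrombolysis):
    """Intervention label(s) from claim procedure flags.

    Thrombectomy takes precedence over thrombolysis when both flags are set
    (bridging therapy is counted as thrombectomy), so the three labels
    partition the cohort.  Accepts scalars or arrays.
    """
    tby = np.asarray(has_thrombectomy, dtype=bool)
    tly = np.asarray(has_thrombolysis, dtype=bool)
    out = np.where(tby, "thrombectomy", np.where(tly, "thrombolysis", "other"))
    if out.ndim == 0:
        return out.item()
    return out


def _calendar_age(birth: pd.Series, at: pd.Series) -> pd.Series:
    """Completed years between two date Series (birthday-exact)."""
    before_birthday = (at.dt.month < birth.dt.month) | (
        (at.dt.month == birth.dt.month) & (at.dt.day < birth.dt.day)
    )
    return at.dt.year - birth.dt.year - before_birthday.astype(int)


def select_index_events(
    hosp_claims: pd.DataFrame,
    patients: pd.DataFrame,
    providers: pd.DataFrame,
    study_start: date,
    study_end: date,
    min_age: int = 18,
    horizon_days: int = 90,
):
    """Select one index event per patient and log every exclusion.

    Returns ``(index_events, rejects)``.  ``index_events`` has one row per
    retained patient (columns ``INDEX_EVENT_COLUMNS``); ``rejects`` lists
    patient_id/reason pairs for records dropped by the eligibility rules.
    """
    claims = hosp_claims.copy()
    claims["admission_date"] = pd.to_datetime(claims["admission_date"])
    claims["discharge_date"] = pd.to_datetime(claims["discharge_date"])
    start = pd.Timestamp(study_start)
    end = pd.Timestamp(study_end)

    rejects: list[pd.DataFrame] = []

    dx = claims["main_dx"].astype("string")
    malformed = dx.isna() | (dx.str.strip() == "")
    if malformed.any():
        rejects.append(_reject(claims[malformed], REASON_BAD_RECORD))
    is_index_dx = dx.str.strip().str.upper().str.startswith(INDEX_DX_PREFIX) & ~malformed

    candidates = claims[is_index_dx & (claims["admission_date"] >= start)].copy()

    # earliest I63 admission per patient; same-day ties broken by claim_id
    candidates = candidates.sort_values(["patient_id", "admission_date", "claim_id"])
    first = candidates.groupby("patient_id", as_index=False).first()

    pat = patients.copy()
    pat["birth_date"] = pd.to_datetime(pat["birth_date"])
    merged = first.merge(pat[["patient_id", "birth_date", "sex"]], on="patient_id", how="left")

    no_birth = merged["birth_date"].isna()
    if no_birth.any():
        rejects.append(_reject(merged[no_birth], REASON_BAD_RECORD))
    merged = merged[~no_birth].copy()

    merged["age_at_index"] = _calendar_age(merged["birth_date"], merged["admission_date"])

    under = merged["age_at_index"] < min_age
    if under.any():
        rejects.append(_reject(merged[under], REASON_UNDER18))
    merged = merged[~under]

    late = merged["admission_date"] + pd.Timedelta(days=horizon_days) > end
    if late.any():
        rejects.append(_reject(merged[late], REASON_LATE_INDEX))
    merged = merged[~late].copy()

    merged["intervention"] = classify_intervention(
        merged["has_thrombectomy"], merged["has_thrombolysis"]
    )
    merged["los"] = (merged["discharge_date"] - merged["admission_date"]).dt.days

    merged = merged.merge(providers[["provider_id", "provider_type"]], on="provider_id", how="left")
    merged = merged.rename(
        columns={"admission_date": "index_date", "claim_id": "primary_claim_id"}
    )
    events = merged[INDEX_EVENT_COLUMNS].reset_index(drop=True)

    reject_df = (
        pd.concat(rejects, ignore_index=True)
        if rejects
        else pd.DataFrame(columns=["patient_id", "reason"])
    )
    return events, reject_df


def apply_volume_filter(index_events: pd.DataFrame, min_volume: int = 30):
    """Drop all events of providers with fewer than ``min_volume`` index events.

    The threshold is applied once to the pre-filter counts (no iterative
    re-filtering).  Returns ``(kept_events, excluded_providers, rejects)``.
    """
    if min_volume < 1:
        raise ValueError("min_volume must be at least 1")
    counts = index_events["provider_id"].value_counts()
    excluded = sorted(counts[counts < min_volume].index.tolist())
    low = index_events["provider_id"].isin(excluded)
    rejects = _reject(index_events[low], REASON_LOW_VOLUME)
    kept = index_events[~low].reset_index(drop=True)
    return kept, excluded, rejects
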