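"""90-day episode cost aggregation and vital status, from the payer perspective.

Window convention: day 1 is the admission day of the index hospitalization and
the episode covers day offsets [0, horizon) — i.e. events strictly before
``index_date + horizon_days``.  A later hospitalization belongs to the episode
if its *admission* falls inside the window; the full claim cost is counted
even when discharge is later (claims are indivisible payer units, no
prorating).  A death exactly at offset ``horizon_days`` counts as survival.
"""

from __future__ import annotations

import pandas as pd

EPISODE_COLUMNS = [
    "cost_primary",
    "cost_other_hosp",
    "cost_outpatient",
    "cost_total",
    "died_90d",
]


class DataIntegrityError(ValueError):
    """Raised when claim or patient records violate basic integrity rules."""


def compute_mortality_flag(
    index_events: pd.DataFrame, patients: pd.DataFrame, horizon_days: int = 90
) -> pd.Series:
    """All-cause death within ``horizon_days`` of the index admission.

    True iff a death date exists and death_date - index_date < horizon_days
    (half-open window: a death on day ``horizon_days`` is a survivor).
    """
    pat = patients.copy()
    pat["death_date"] = pd.to_datetime(pat["death_date"])
    merged = index_events[["patient_id", "index_date"]].merge(
        pat[["patient_id", "death_date"]], on="patient_id", how="left"
    )
    merged["index_date"] = pd.to_datetime(merged["index_date"])
    offset = (merged["death_date"] - merged["index_date"]).dt.days
    if (offset < 0).any():
        bad = merged.loc[offset < 0, "patient_id"].tolist()
        raise DataIntegrityError(f"death before index admission for patients {bad[:5]}")
    flag = offset.notna() & (offset < horizon_days)
    flag.index = index_events.index
    return flag.rename("died_90d")


def _window_sum(claims, events, date_col, horizon_days):
    """Sum claim costs per patient for claims dated inside the episode window."""
    joined = claims.merge(events[["patient_id", "index_date"]], on="patient_id", how="inner")
    offset = (joined[date_col] - joined["index_date"]).dt.days
    in_window = (offset >= 0) & (offset < horizon_days)
    return joined[in_window].groupby("patient_id")["cost"].sum()


def compute_episode_costs(
    index_events: pd.DataFrame,
    hosp_claims: pd.DataFrame,
    outpatient_claims: pd.DataFrame,
    patients: pd.DataFrame | None = None,
    horizon_days: int = 90,
) -> pd.DataFrame:
    """One episode record per index event with the 90-day cost decomposition.

    * ``cost_primary``: cost of the index claim itself;
    * ``cost_other_hosp``: all other hospitalization claims of the patient with
      admission in [index_date, index_date + horizon);
    * ``cost_outpatient``: outpatient claims with service date in the window;
    * ``cost_total``: exact sum of the three components;
    * ``died_90d``: added when a patient table is supplied.
    """
    if (hosp_claims["cost"] < 0).any() or (outpatient_claims["cost"] < 0).any():
        raise DataIntegrityError("negative claim cost")

    events = index_events.copy()
    events["index_date"] = pd.to_datetime(events["index_date"])

    hosp = hosp_claims.copy()
    hosp["admission_date"] = pd.to_datetime(hosp["admission_date"])
    outp = outpatient_claims.copy()
    outp["service_date"] = pd.to_datetime(outp["service_date"])

    primary = hosp.set_index("claim_id")["cost"]
    events["cost_primary"] = events["primary_claim_id"].map(primary).astype(float)

    other = hosp[~hosp["claim_id"].isin(events["primary_claim_id"])]
    other_sum = _window_sum(other, events, "admission_date", horizon_days)
    outp_sum = _window_sum(outp, events, "service_date", horizon_days)

    events["cost_other_hosp"] = (
        events["patient_id"].map(other_sum).fillna(0.0).astype(float)
    )
    events["cost_outpatient"] = (
        events["patient_id"].map(outp_sum).fillna(0.0).astype(float)
    )
    events["cost_total"] = (
        events["cost_primary"] + events["cost_other_hosp"] + events["cost_outpatient"]
    )

    if patients is not None:
        events["died_90d"] = compute_mortality_flag(events, patients, horizon_days).to_numpy()
    return events
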