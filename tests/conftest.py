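"""Shared fixtures: a hand-audited micro-fixture of claim tables and a
medium synthetic world reused by several test modules."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from strokecost import synthetic

STUDY_START = date(2017, 1, 1)
STUDY_END = date(2020, 10, 2)


def _d(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture(scope="session")
def toy_tables():
    """Hand-constructed claim tables exercising every cohort/costing rule.

    Patients (all providers have >= 1 event; volume filter not applied here):

    * P1: index 2018-03-01 (earlier of two I63 admissions), thrombectomy+lysis
      flags, secondary hospitalization at day 30 (cost 500), outpatient 100+50
      in window and 200 at day 95; survives.  Expected costs (1000, 500, 150).
    * P2: I63 admission aged 17 -> UNDER18 reject.
    * P3: admission 2020-08-01 -> LATE_INDEX (fewer than 90 follow-up days);
      admission date chosen against study_end 2020-10-02.
    * P4: admission 2020-07-01 -> kept (exactly 90 follow-up days remain, but
      2020-07-01 + 90d = 2020-09-29 <= study_end... kept); dies day 89.
    * P5: thrombolysis only; other hospitalization admitted on day 90 ->
      excluded from costs; death on day 90 -> survivor.
    * P6: no claims besides index (cost 800); death on index day -> died.
    """
    patients = pd.DataFrame(
        [
            ("P1", _d("1950-06-15"), "F", pd.NaT),
            ("P2", _d("2001-05-01"), "M", pd.NaT),
            ("P3", _d("1940-01-01"), "F", pd.NaT),
            ("P4", _d("1945-02-02"), "M", _d("2020-09-28")),  # day 89 after 2020-07-01
            ("P5", _d("1952-12-31"), "F", _d("2018-06-10")),  # day 90 after 2018-03-12
            ("P6", _d("1938-07-07"), "M", _d("2019-04-04")),  # index day
        ],
        columns=["patient_id", "birth_date", "sex", "death_date"],
    )
    providers = pd.DataFrame(
        [("CSC-1", "CSC"), ("PSC-1", "PSC"), ("SRH-1", "SRH")],
        columns=["provider_id", "provider_type"],
    )
    hosp = pd.DataFrame(
        [
            # P1: two I63 admissions (earliest wins), one secondary, one late hosp
            ("H01", "P1", "CSC-1", _d("2018-03-01"), _d("2018-03-10"), "I63.5", True, True, 1000.0),
            ("H02", "P1", "CSC-1", _d("2019-05-01"), _d("2019-05-08"), "I63.5", False, False, 999.0),
            ("H03", "P1", "PSC-1", _d("2018-03-31"), _d("2018-04-02"), "J18.9", False, False, 500.0),
            # P2 under 18 at admission (turns 18 on 2019-05-01)
            ("H04", "P2", "PSC-1", _d("2019-04-30"), _d("2019-05-03"), "I63.0", False, False, 700.0),
            # P3 too close to study end
            ("H05", "P3", "SRH-1", _d("2020-08-01"), _d("2020-08-09"), "I63.1", False, False, 600.0),
            # P4 exactly 90 follow-up days remain
            ("H06", "P4", "SRH-1", _d("2020-07-01"), _d("2020-07-12"), "I63.8", False, False, 900.0),
            # P5 thrombolysis; other hosp on day 90 (out of window)
            ("H07", "P5", "PSC-1", _d("2018-03-12"), _d("2018-03-20"), "I63.9", False, True, 1200.0),
            ("H08", "P5", "CSC-1", _d("2018-06-10"), _d("2018-06-15"), "I48", False, False, 400.0),
            # P5 other hosp on day 89 (in window)
            ("H09", "P5", "CSC-1", _d("2018-06-09"), _d("2018-06-12"), "I10", False, False, 300.0),
            # P6 index only
            ("H10", "P6", "CSC-1", _d("2019-04-04"), _d("2019-04-04"), "I63.3", False, False, 800.0),
        ],
        columns=[
            "claim_id", "patient_id", "provider_id", "admission_date", "discharge_date",
            "main_dx", "has_thrombectomy", "has_thrombolysis", "cost",
        ],
    )
    outp = pd.DataFrame(
        [
            ("O01", "P1", _d("2018-03-05"), 100.0),
            ("O02", "P1", _d("2018-05-20"), 50.0),   # day 80
            ("O03", "P1", _d("2018-06-04"), 200.0),  # day 95, out of window
            ("O04", "P5", _d("2018-03-12"), 75.0),   # index day
        ],
        columns=["claim_id", "patient_id", "service_date", "cost"],
    )
    return patients, providers, hosp, outp


@pytest.fixture(scope="session")
def sim_config():
    return synthetic.default_sim_config(seed=20_260_921, n_patients=6000)


@pytest.fixture(scope="session")
def world(sim_config):
    return synthetic.generate_world(sim_config)
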