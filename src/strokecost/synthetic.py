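"""Seeded synthetic claims generator.

Emulates the statistical structure of an administrative stroke-claims
database: one index-eligible I63 hospitalization per patient, right-skewed
lognormal costs split into primary hospitalization / other hospitalization /
outpatient components, age-dependent 90-day mortality on the log-odds scale,
and a configurable roster of providers (comprehensive stroke centres CSC,
primary stroke centres PSC, stroke-ready hospitals SRH, and others) with
realistic patient shares and intervention mixes.  Edge cases (under-18
admissions, repeated index events, admissions too close to the study end,
a low-volume provider) are injected deliberately so that every downstream
exclusion rule is exercised.

All randomness flows from a single ``numpy.random.Generator`` seeded from
``SimConfig.seed``; identical configs produce byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

PROVIDER_TYPES = ("CSC", "PSC", "SRH", "OTHER")
INTERVENTIONS = ("thrombectomy", "thrombolysis", "other")
COST_COMPONENTS = ("primary", "other_hosp", "outpatient")

#: non-stroke main diagnoses used for secondary hospitalizations
_SECONDARY_DX = ("I69.3", "J18.9", "I48", "N39.0", "I10", "S72.0")


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class LogNormalParams:
    """Location/scale of a lognormal cost distribution (EUR)."""

    mu: float
    sigma: float

    @classmethod
    def from_mean_median(cls, mean: float, median: float) -> "LogNormalParams":
        # mean = exp(mu + sigma^2/2), median = exp(mu)
        if median <= 0 or mean < median:
            raise ConfigError(f"need 0 < median <= mean, got mean={mean}, median={median}")
        return cls(mu=math.log(median), sigma=math.sqrt(2.0 * math.log(mean / median)))

    @classmethod
    def from_mean_sigma(cls, mean: float, sigma: float) -> "LogNormalParams":
        return cls(mu=math.log(mean) - 0.5 * sigma**2, sigma=sigma)


@dataclass(frozen=True)
class MortalityModel:
    """Logistic model for death within 90 days of the index admission.

    logit p = intercept + offset[intervention] + beta_per_decade * (age - age_ref)/10
    ``intercept`` applies to the "other treatment" group; the reperfusion
    groups carry additive offsets on the log-odds scale.
    """

    intercept: float
    beta_per_decade: float
    offsets: dict[str, float]
    age_ref: float = 70.6

    def probability(self, age: np.ndarray, intervention: np.ndarray) -> np.ndarray:
        off = np.array([self.offsets.get(i, 0.0) for i in intervention])
        lp = self.intercept + off + self.beta_per_decade * (np.asarray(age) - self.age_ref) / 10.0
        return expit(lp)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_patients: int = 23_568
    study_start: date = date(2017, 1, 1)
    study_end: date = date(2020, 10, 2)
    #: (provider_type, number of providers, expected patient volume per provider)
    provider_plan: tuple[tuple[str, int, float], ...] = (
        ("CSC", 13, 0.35 / 13),
        ("PSC", 32, 0.46 / 32),
        ("SRH", 25, 0.17 / 25),
        ("OTHER", 15, 0.019 / 15),
    )
    age_mean: float = 70.6
    age_sd: float = 12.4
    age_floor: float = 18.0
    female_fraction: float = 0.47
    #: provider_type -> (p_thrombectomy, p_thrombolysis, p_other); rows sum to 1
    intervention_mix_by_provider_type: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: _DEFAULT_INTERVENTION_MIX.copy()
    )
    cost_params: dict[tuple[str, str], LogNormalParams] = field(
        default_factory=lambda: _DEFAULT_COST_PARAMS.copy()
    )
    mortality_model: MortalityModel | None = None
    los_mean: float = 8.8
    los_sd: float = 7.3
    p_secondary_hosp: float = 0.35
    #: bridging therapy: thrombectomy claims that also carry the thrombolysis flag
    p_bridging: float = 0.30
    #: fraction of 90-day survivors who die later (exercises the window boundary)
    p_late_death: float = 0.03
    edge_case_counts: dict[str, int] = field(
        default_factory=lambda: {
            "under18": 5,
            "repeat_index": 5,
            "late_index": 5,
            "low_volume_provider": 10,
        }
    )
    currency_scale: float = 1.0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be a proportion")
        if not 0.0 <= self.p_secondary_hosp <= 1.0:
            raise ConfigError("p_secondary_hosp must be a proportion")
        for ptype, count, vol in self.provider_plan:
            if ptype not in PROVIDER_TYPES:
                raise ConfigError(f"unknown provider type {ptype!r}")
            if count < 0 or vol < 0:
                raise ConfigError("provider counts and volumes must be non-negative")
        for ptype, mix in self.intervention_mix_by_provider_type.items():
            if ptype not in PROVIDER_TYPES:
                raise ConfigError(f"unknown provider type {ptype!r} in intervention mix")
            if len(mix) != 3 or any(p < 0 for p in mix):
                raise ConfigError("intervention mix rows need 3 non-negative entries")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ConfigError(f"intervention mix for {ptype} sums to {sum(mix)}, not 1")
        for n in self.edge_case_counts.values():
            if n < 0:
                raise ConfigError("edge case counts must be non-negative")


# Intervention mix per provider type, from the column-wise composition of a
# 23,568-patient Czech cohort (e.g. 1147 of 8159 CSC patients thrombectomized).
_DEFAULT_INTERVENTION_MIX: dict[str, tuple[float, float, float]] = {
    "CSC": (1147 / 8159, 1834 / 8159, 5178 / 8159),
    "PSC": (146 / 10885, 2107 / 10885, 8632 / 10885),
    "SRH": (13 / 4066, 99 / 4066, 3954 / 4066),
    "OTHER": (1 / 458, 2 / 458, 455 / 458),
}

# Lognormal cost parameters per (intervention, component), in EUR.  Primary and
# outpatient parameters are solved from published group mean/median pairs; the
# other-hospitalization component is conditional on any secondary admission
# occurring (probability p_secondary_hosp), so its conditional mean is the
# unconditional group mean divided by that probability.
_P_SEC = 0.35
_DEFAULT_COST_PARAMS: dict[tuple[str, str], LogNormalParams] = {
    ("thrombectomy", "primary"): LogNormalParams.from_mean_median(9243, 8482),
    ("thrombolysis", "primary"): LogNormalParams.from_mean_median(2476, 1920),
    ("other", "primary"): LogNormalParams.from_mean_median(1285, 791),
    ("thrombectomy", "other_hosp"): LogNormalParams.from_mean_sigma(2335 / _P_SEC, 1.0),
    ("thrombolysis", "other_hosp"): LogNormalParams.from_mean_sigma(948 / _P_SEC, 1.0),
    ("other", "other_hosp"): LogNormalParams.from_mean_sigma(704 / _P_SEC, 1.0),
    ("thrombectomy", "outpatient"): LogNormalParams.from_mean_median(2275, 465),
    ("thrombolysis", "outpatient"): LogNormalParams.from_mean_median(824, 481),
    ("other", "outpatient"): LogNormalParams.from_mean_median(735, 433),
}


def solve_marginal_logit(
    target_rate: float,
    age_mean: float,
    age_sd: float,
    beta_per_decade: float,
    age_floor: float = 18.0,
    age_ref: float | None = None,
) -> float:
    """Intercept b such that E[expit(b + beta*(A-age_ref)/10)] = target_rate.

    The expectation is over A ~ Normal(age_mean, age_sd) truncated below at
    ``age_floor``, evaluated on a fine quadrature grid.
    """
    if not 0.0 < target_rate < 1.0:
        raise ConfigError("target_rate must be in (0, 1)")
    ref = age_mean if age_ref is None else age_ref
    a = (age_floor - age_mean) / age_sd
    dist = stats.truncnorm(a, np.inf, loc=age_mean, scale=age_sd)
    grid = np.linspace(age_floor, age_mean + 8 * age_sd, 4001)
    w = dist.pdf(grid)
    w = w / w.sum()

    def marginal(b: float) -> float:
        return float(np.sum(w * expit(b + beta_per_decade * (grid - ref) / 10.0))) - target_rate

    return optimize.brentq(marginal, -20.0, 20.0, xtol=1e-12)


def default_mortality_model(
    age_mean: float = 70.6,
    age_sd: float = 12.4,
    beta_per_decade: float = 0.7,
    target_rates: dict[str, float] | None = None,
) -> MortalityModel:
    """Logistic mortality model whose marginal 90-day rates over the cohort age
    distribution match observed per-intervention rates (thrombectomy 29.3%,
    thrombolysis 14.9%, other treatment 14.4%)."""
    targets = target_rates or {"thrombectomy": 0.293, "thrombolysis": 0.149, "other": 0.144}
    logits = {
        k: solve_marginal_logit(v, age_mean, age_sd, beta_per_decade) for k, v in targets.items()
    }
    base = logits["other"]
    return MortalityModel(
        intercept=base,
        beta_per_decade=beta_per_decade,
        offsets={k: v - base for k, v in logits.items() if k != "other"},
        age_ref=age_mean,
    )


def default_sim_config(seed: int = 0, n_patients: int = 23_568) -> SimConfig:
    """Study-condition defaults with the mortality model solved numerically."""
    cfg = SimConfig(seed=seed, n_patients=n_patients)
    return replace(cfg, mortality_model=default_mortality_model(cfg.age_mean, cfg.age_sd))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _birth_dates(admission: pd.Series, age_years: np.ndarray):
    """Birth dates whose completed calendar age at admission is round(age_years).

    Rounding (rather than flooring) the continuous age keeps the mean of the
    reported completed-years age equal to the configured age_mean.  The
    birthday is placed a fraction of a year before the admission anniversary,
    so the completed age is exact regardless of leap years.
    """
    shifted = np.asarray(age_years, dtype=float) + 0.5
    k = np.floor(shifted).astype(int)
    extra_days = np.minimum((shifted - k) * 364.0, 364.0).astype(int)
    day = admission.dt.day.where(~((admission.dt.month == 2) & (admission.dt.day == 29)), 28)
    anniversary = pd.to_datetime(
        {"year": admission.dt.year - k, "month": admission.dt.month, "day": day}
    )
    return anniversary - pd.to_timedelta(extra_days, unit="D")


def _sample_ages(rng, n, mean, sd, floor):
    a = (floor - mean) / sd
    return stats.truncnorm(a, np.inf, loc=mean, scale=sd).rvs(n, random_state=rng)


def _sample_los(rng, n, mean, sd):
    if sd <= 0:
        return np.full(n, int(round(mean)))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return np.round(rng.gamma(shape, scale, size=n)).astype(int)


def generate_world(config: SimConfig):
    """Generate (patients, providers, hosp_claims, outpatient_claims) tables.

    Returns four pandas DataFrames with referential integrity: every claim's
    patient_id/provider_id exists in the corresponding table.  Non-edge-case
    patients have exactly one index-eligible I63 hospitalization; edge cases
    are appended per ``config.edge_case_counts``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    model = config.mortality_model or default_mortality_model(config.age_mean, config.age_sd)

    # provider roster
    prov_rows = []
    prov_weights = []
    for ptype, count, vol in config.provider_plan:
        for i in range(count):
            prov_rows.append((f"{ptype}-{i + 1:02d}", ptype))
            prov_weights.append(vol)
    providers = pd.DataFrame(prov_rows, columns=["provider_id", "provider_type"])
    weights = np.asarray(prov_weights, dtype=float)
    weights = weights / weights.sum()

    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    last_eligible = (end - start).days - 90  # latest admission offset with full follow-up

    n = config.n_patients
    ages = _sample_ages(rng, n, config.age_mean, config.age_sd, config.age_floor)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    prov_idx = rng.choice(len(providers), size=n, p=weights)
    ptype_arr = providers["provider_type"].to_numpy()[prov_idx]
    pid_arr = providers["provider_id"].to_numpy()[prov_idx]

    intervention = np.empty(n, dtype=object)
    for ptype in PROVIDER_TYPES:
        mask = ptype_arr == ptype
        if mask.any():
            mix = config.intervention_mix_by_provider_type[ptype]
            intervention[mask] = rng.choice(INTERVENTIONS, size=int(mask.sum()), p=mix)

    adm_offset = rng.integers(0, last_eligible + 1, size=n)
    admission = start + pd.to_timedelta(adm_offset, unit="D")
    los = _sample_los(rng, n, config.los_mean, config.los_sd)

    p_death = model.probability(ages, intervention)
    died = rng.random(n) < p_death
    death_offset = np.where(died, rng.integers(0, 90, size=n), -1)
    late = (~died) & (rng.random(n) < config.p_late_death)
    death_offset = np.where(late, rng.integers(90, 366, size=n), death_offset)

    patient_ids = np.array([f"P{i + 1:06d}" for i in range(n)])
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "birth_date": _birth_dates(pd.Series(admission), ages),
            "sex": sex,
            "death_date": pd.Series(admission)
            + pd.to_timedelta(np.where(death_offset >= 0, death_offset, 0), unit="D"),
        }
    )
    patients.loc[death_offset < 0, "death_date"] = pd.NaT

    scale = config.currency_scale

    def _cost(interv_arr, component, size_mask=None):
        out = np.zeros(len(interv_arr))
        for interv in INTERVENTIONS:
            m = interv_arr == interv
            if m.any():
                p = config.cost_params[(interv, component)]
                out[m] = rng.lognormal(p.mu, p.sigma, size=int(m.sum()))
        return out * scale

    hosp_rows: list[dict] = []
    outp_rows: list[dict] = []
    claim_no = 0
    outp_no = 0

    def add_hosp(pid, prov, adm, disc, dx, tby, tly, cost):
        nonlocal claim_no
        claim_no += 1
        hosp_rows.append(
            {
                "claim_id": f"H{claim_no:07d}",
                "patient_id": pid,
                "provider_id": prov,
                "admission_date": adm,
                "discharge_date": disc,
                "main_dx": dx,
                "has_thrombectomy": tby,
                "has_thrombolysis": tly,
                "cost": cost,
            }
        )

    def add_outp(pid, svc, cost):
        nonlocal outp_no
        outp_no += 1
        outp_rows.append(
            {"claim_id": f"O{outp_no:07d}", "patient_id": pid, "service_date": svc, "cost": cost}
        )

    # primary hospitalization claims
    primary_cost = _cost(intervention, "primary")
    i63_sub = rng.integers(0, 10, size=n)
    tby_flag = intervention == "thrombectomy"
    tly_flag = (intervention == "thrombolysis") | (
        tby_flag & (rng.random(n) < config.p_bridging)
    )
    for i in range(n):
        add_hosp(
            patient_ids[i],
            pid_arr[i],
            admission[i],
            admission[i] + pd.Timedelta(days=int(los[i])),
            f"I63.{i63_sub[i]}",
            bool(tby_flag[i]),
            bool(tly_flag[i]),
            round(float(primary_cost[i]), 2),
        )

    # secondary hospitalizations (inside the 90-day window)
    has_sec = rng.random(n) < config.p_secondary_hosp
    sec_cost = _cost(intervention, "other_hosp")
    sec_offset = rng.integers(1, 86, size=n)
    sec_los = _sample_los(rng, n, 6.0, 5.0)
    sec_prov = rng.choice(providers["provider_id"].to_numpy(), size=n)
    sec_dx = rng.choice(_SECONDARY_DX, size=n)
    # out-of-window hospitalizations (admission on or after day 90)
    has_out = rng.random(n) < 0.10
    out_offset = rng.integers(90, 181, size=n)
    out_cost = _cost(intervention, "other_hosp")
    for i in range(n):
        if has_sec[i]:
            adm2 = admission[i] + pd.Timedelta(days=int(sec_offset[i]))
            add_hosp(
                patient_ids[i], sec_prov[i], adm2,
                adm2 + pd.Timedelta(days=int(sec_los[i])),
                str(sec_dx[i]), False, False, round(float(sec_cost[i]), 2),
            )
        if has_out[i]:
            adm3 = admission[i] + pd.Timedelta(days=int(out_offset[i]))
            add_hosp(
                patient_ids[i], sec_prov[i], adm3,
                adm3 + pd.Timedelta(days=4),
                str(sec_dx[i]), False, False, round(float(out_cost[i]) * 0.5, 2),
            )

    # outpatient claims: in-window total split over 1+Poisson(2) visits
    outp_total = _cost(intervention, "outpatient")
    n_visits = 1 + rng.poisson(2.0, size=n)
    has_outp_out = rng.random(n) < 0.30
    for i in range(n):
        k = int(n_visits[i])
        shares = rng.dirichlet(np.ones(k))
        offsets = rng.integers(0, 90, size=k)
        for j in range(k):
            add_outp(
                patient_ids[i],
                admission[i] + pd.Timedelta(days=int(offsets[j])),
                round(float(outp_total[i] * shares[j]), 2),
            )
        if has_outp_out[i]:
            add_outp(
                patient_ids[i],
                admission[i] + pd.Timedelta(days=int(rng.integers(90, 181))),
                round(float(rng.lognormal(4.5, 1.0)) * scale, 2),
            )

    # --- injected edge cases -------------------------------------------------
    edge = config.edge_case_counts
    extra_patients: list[dict] = []
    eid = 0

    def new_patient(age_years: float, adm: pd.Timestamp) -> str:
        nonlocal eid
        eid += 1
        pid = f"E{eid:05d}"
        bd = _birth_dates(pd.Series([adm]), np.array([age_years])).iloc[0]
        extra_patients.append(
            {"patient_id": pid, "birth_date": bd, "sex": "F" if rng.random() < 0.5 else "M",
             "death_date": pd.NaT}
        )
        return pid

    mid = start + pd.Timedelta(days=last_eligible // 2)
    any_provider = providers["provider_id"].iloc[0]

    for _ in range(edge.get("under18", 0)):
        adm = start + pd.Timedelta(days=int(rng.integers(0, last_eligible + 1)))
        pid = new_patient(float(rng.integers(1, 18)) - 0.4, adm)
        add_hosp(pid, any_provider, adm, adm + pd.Timedelta(days=5), "I63.9",
                 False, False, round(float(rng.lognormal(7.0, 0.5)) * scale, 2))

    for _ in range(edge.get("repeat_index", 0)):
        adm = start + pd.Timedelta(days=int(rng.integers(0, max(last_eligible - 300, 1))))
        pid = new_patient(float(rng.integers(40, 90)) + 0.5, adm)
        add_hosp(pid, any_provider, adm, adm + pd.Timedelta(days=7), "I63.3",
                 False, False, round(float(rng.lognormal(7.0, 0.8)) * scale, 2))
        adm2 = adm + pd.Timedelta(days=int(rng.integers(30, 300)))
        add_hosp(pid, any_provider, adm2, adm2 + pd.Timedelta(days=7), "I63.3",
                 False, False, round(float(rng.lognormal(7.0, 0.8)) * scale, 2))

    for _ in range(edge.get("late_index", 0)):
        adm = end - pd.Timedelta(days=int(rng.integers(0, 89)))
        pid = new_patient(float(rng.integers(40, 90)) + 0.5, adm)
        add_hosp(pid, any_provider, adm, adm + pd.Timedelta(days=4), "I63.8",
                 False, False, round(float(rng.lognormal(7.0, 0.8)) * scale, 2))

    n_lv = edge.get("low_volume_provider", 0)
    if n_lv:
        lv_id = "SRH-LV"
        providers = pd.concat(
            [providers, pd.DataFrame([{"provider_id": lv_id, "provider_type": "SRH"}])],
            ignore_index=True,
        )
        for _ in range(n_lv):
            adm = mid + pd.Timedelta(days=int(rng.integers(0, 200)))
            pid = new_patient(float(rng.integers(40, 90)) + 0.5, adm)
            add_hosp(pid, lv_id, adm, adm + pd.Timedelta(days=6), "I63.5",
                     False, False, round(float(rng.lognormal(7.0, 0.8)) * scale, 2))

    if extra_patients:
        patients = pd.concat([patients, pd.DataFrame(extra_patients)], ignore_index=True)

    hosp_claims = pd.DataFrame(hosp_rows)
    outpatient_claims = pd.DataFrame(outp_rows)
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    patients["death_date"] = pd.to_datetime(patients["death_date"])
    return patients, providers, hosp_claims, outpatient_claims


def calibration_report(tables, config: SimConfig) -> dict:
    """Summarize the realized structure of generated tables.

    Runs the cohort and costing stages on the generated claims and reports the
    realized age mean/sd, sex mix, intervention mix, 90-day mortality and the
    mean/median of each cost component, so the generator can be checked
    against its configured targets.
    """
    from strokecost.cohort import select_index_events
    from strokecost.costing import compute_episode_costs

    patients, providers, hosp_claims, outpatient_claims = tables
    if len(patients) == 0 or len(hosp_claims) == 0:
        raise ValueError("calibration_report requires non-empty patient and claim tables")

    events, _ = select_index_events(
        hosp_claims, patients, providers, config.study_start, config.study_end
    )
    episodes = compute_episode_costs(events, hosp_claims, outpatient_claims, patients)

    report: dict = {
        "n_cohort": int(len(episodes)),
        "age_mean": float(episodes["age_at_index"].mean()),
        "age_sd": float(episodes["age_at_index"].std()),
        "female_share": float((episodes["sex"] == "F").mean()),
        "mortality_90d": float(episodes["died_90d"].mean()),
        "mean_los": float(episodes["los"].mean()),
        "intervention_mix": episodes["intervention"].value_counts(normalize=True).to_dict(),
        "cost_components": {},
    }
    for comp in ("cost_primary", "cost_other_hosp", "cost_outpatient", "cost_total"):
        report["cost_components"][comp] = {
            "mean": float(episodes[comp].mean()),
            "median": float(episodes[comp].median()),
        }
    return report
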