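"""Indirect age standardization of 90-day mortality.

Follows the indirect-standardization scheme used by the AHRQ quality
indicators: the reference population is the whole analyzed cohort, stratified
into age bands; each patient's expected death probability p_i is the death
rate of their age stratum in the reference population; a group's standardized
mortality is

    (O / E) * r_bar,    O = observed deaths, E = sum of p_i, r_bar = reference
                        crude mortality,

reported as a probability in [0, 1] (not truncated above 1 — tiny groups with
O >> E can exceed 1, which is flagged with a warning rather than clipped).

A logistic-regression alternative for p_i (death ~ age, fit on the reference
population) is available for users who prefer a smooth age effect over
stratum rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default age strata, half-open [lo, hi)
DEFAULT_AGE_BANDS: tuple[float, ...] = (18.0, 45.0, 55.0, 65.0, 75.0, 85.0, np.inf)


@dataclass(frozen=True)
class ReferenceModel:
    """Age-stratum 90-day death rates of the reference population.

    ``band_edges`` are the k+1 ordered edges of k half-open bands
    [e_0, e_1), ..., [e_{k-1}, e_k); ``rates`` the per-band death rates and
    ``overall_rate`` the reference crude mortality.
    """

    band_edges: tuple[float, ...]
    rates: tuple[float, ...]
    overall_rate: float

    def __post_init__(self):
        edges = np.asarray(self.band_edges, dtype=float)
        if len(edges) != len(self.rates) + 1 or not np.all(np.diff(edges) > 0):
            raise ValueError("band_edges must be strictly increasing with one more edge than rates")
        if any(not 0.0 <= r <= 1.0 for r in self.rates):
            raise ValueError("stratum rates must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_lo": self.band_edges[:-1],
                "age_hi": self.band_edges[1:],
                "rate": self.rates,
                "overall_rate": self.overall_rate,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ReferenceModel":
        edges = tuple(frame["age_lo"].tolist()) + (float(frame["age_hi"].iloc[-1]),)
        return cls(edges, tuple(frame["rate"].tolist()), float(frame["overall_rate"].iloc[0]))


@dataclass(frozen=True)
class StandardizedRate:
    """Standardized mortality of one group: O observed, E expected deaths."""

    observed: int
    expected: float
    overall_rate: float

    @property
    def ratio(self) -> float:
        return self.observed / self.expected

    @property
    def rate(self) -> float:
        return self.ratio * self.overall_rate


def fit_reference(
    episodes: pd.DataFrame, age_bands: tuple[float, ...] = DEFAULT_AGE_BANDS
) -> ReferenceModel:
    """Per-band death rates from the reference population (all episodes).

    Bands with no members inherit the overall rate, so ``expected_probability``
    is total on the whole age range.
    """
    if len(episodes) == 0:
        raise ValueError("cannot fit a reference model on an empty episode table")
    edges = np.asarray(age_bands, dtype=float)
    ages = episodes["age_at_index"].to_numpy(dtype=float)
    died = episodes["died_90d"].to_numpy(dtype=bool)
    if ages.min() < edges[0] or ages.max() >= edges[-1]:
        raise ValueError("every age must fall inside the band range")
    overall = float(died.mean())
    idx = np.digitize(ages, edges[1:-1], right=False)
    rates = []
    for b in range(len(edges) - 1):
        mask = idx == b
        rates.append(float(died[mask].mean()) if mask.any() else overall)
    return ReferenceModel(tuple(edges.tolist()), tuple(rates), overall)


def expected_probability(age, model: ReferenceModel):
    """Expected death probability: the rate of the band containing ``age``.

    Bands are half-open, so an age on a lower edge belongs to that band.
    Accepts scalars or arrays.
    """
    ages = np.asarray(age, dtype=float)
    edges = np.asarray(model.band_edges)
    if np.any(ages < edges[0]):
        raise ValueError(f"age below the first band edge {edges[0]}")
    idx = np.digitize(ages, edges[1:-1], right=False)
    out = np.asarray(model.rates)[idx]
    if out.ndim == 0:
        return float(out)
    return out


def add_expected(episodes: pd.DataFrame, model: ReferenceModel) -> pd.DataFrame:
    """Attach the per-patient expected death probability column ``p_expected``."""
    out = episodes.copy()
    out["p_expected"] = expected_probability(out["age_at_index"].to_numpy(), model)
    return out


def standardized_mortality(group_episodes: pd.DataFrame, model: ReferenceModel) -> StandardizedRate:
    """Indirectly standardized 90-day mortality of one group of episodes."""
    if len(group_episodes) == 0:
        raise ValueError("cannot standardize an empty group")
    observed = int(group_episodes["died_90d"].sum())
    expected = float(
        np.sum(expected_probability(group_episodes["age_at_index"].to_numpy(), model))
    )
    if expected <= 0.0:
        raise ValueError("expected deaths are zero; standardized rate undefined")
    rate = observed / expected * model.overall_rate
    if rate > 1.0:
        logger.warning(
            "standardized rate %.3f exceeds 1 (O=%d, E=%.2f); reported untruncated",
            rate, observed, expected,
        )
    return StandardizedRate(observed, expected, model.overall_rate)


def fit_logistic_expected(episodes: pd.DataFrame) -> pd.Series:
    """Alternative p_i estimator: logistic regression of death on age.

    Fit on the reference population (all episodes) with statsmodels; returns
    the predicted death probability per episode, aligned to the input index.
    """
    import statsmodels.api as sm

    x = sm.add_constant(episodes["age_at_index"].to_numpy(dtype=float))
    y = episodes["died_90d"].to_numpy(dtype=float)
    fit = sm.Logit(y, x).fit(disp=0)
    return pd.Series(fit.predict(x), index=episodes.index, name="p_expected")
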