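"""ECPS and group summary tables.

ECPS (effective cost per survivor) divides a group's total 90-day cost by its
number of 90-day survivors:

    ECPS = sum_i C_i / (N - D)

where C_i is the total 90-day cost of patient i, N the group size and D the
deaths within 90 days.  With D = 0 it equals the mean cost; it is undefined
when nobody survives.  Group summaries mirror the usual claims-study tables:
N, deaths, mean age and length of stay, crude and standardized mortality, and
mean/SD/median/IQR of each cost component.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from strokecost.standardize import ReferenceModel, standardized_mortality

COST_COLUMNS = ("cost_total", "cost_primary", "cost_other_hosp", "cost_outpatient")


class NoSurvivorsError(ZeroDivisionError):
    """ECPS is undefined for a group in which every patient died."""


def compute_ecps(costs, deaths: int) -> float:
    """Effective cost per survivor of one group.

    Parameters
    ----------
    costs : array-like of per-patient total 90-day costs (EUR), length N >= 1.
    deaths : number of patients who died within 90 days, 0 <= deaths <= N.
    """
    c = np.asarray(costs, dtype=float)
    n = c.size
    if n < 1:
        raise ValueError("ECPS needs at least one patient")
    if deaths < 0 or deaths > n:
        raise ValueError(f"deaths must lie in [0, {n}], got {deaths}")
    if deaths == n:
        raise NoSurvivorsError("no survivors: ECPS undefined (division by zero)")
    return float(c.sum() / (n - deaths))


def _cost_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return {
        "mean": float(values.mean()),
        "sd": sd,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def summarize_groups(
    episodes: pd.DataFrame,
    model: ReferenceModel | None = None,
    by: str | Sequence[str] = "intervention",
) -> pd.DataFrame:
    """One summary row per group of episodes.

    ``by`` may be any episode column (or list of columns): intervention,
    provider_type, provider_id, sex, ...  Mortality columns are proportions;
    a display layer applies the rounding conventions (see ``format_summary``).
    """
    keys = [by] if isinstance(by, str) else list(by)
    for key in keys:
        if key not in episodes.columns:
            raise KeyError(f"unknown group key {key!r}")

    rows = []
    for group_value, grp in episodes.groupby(keys[0] if len(keys) == 1 else keys, sort=True):
        n = len(grp)
        deaths = int(grp["died_90d"].sum())
        row: dict = {}
        if len(keys) == 1:
            row[keys[0]] = group_value
        else:
            row.update(dict(zip(keys, group_value)))
        row.update(
            {
                "n": n,
                "deaths": deaths,
                "mean_age": float(grp["age_at_index"].mean()),
                "mean_los": float(grp["los"].mean()),
                "crude_mortality": deaths / n,
            }
        )
        if model is not None:
            row["standardized_mortality"] = standardized_mortality(grp, model).rate
        for col in COST_COLUMNS:
            stats = _cost_stats(grp[col].to_numpy(dtype=float))
            row.update({f"{col}_{k}": v for k, v in stats.items()})
        row["ecps"] = (
            compute_ecps(grp["cost_total"], deaths) if deaths < n else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows)


def format_share(count: int, total: int) -> str:
    """Display convention for cohort shares: one decimal under 10%, else whole
    percent (e.g. 11076/23568 -> '47%', 458/23568 -> '1.9%')."""
    pct = 100.0 * count / total
    if pct < 10.0:
        return f"{pct:.1f}%"
    return f"{pct:.0f}%"


def format_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Rounded view of a summary table: costs to whole EUR, mortality to one
    decimal percent.  Internal values keep full precision."""
    out = summary.copy()
    for col in out.columns:
        if col.startswith("cost_") or col == "ecps":
            out[col] = out[col].round(0).astype("Int64")
        elif col.endswith("mortality"):
            out[col] = (100.0 * out[col]).round(1).astype(str) + "%"
        elif col in ("mean_age", "mean_los"):
            out[col] = out[col].round(1)
    return out
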