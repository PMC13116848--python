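"""End-to-end orchestration: claims -> cohort -> episodes -> standardization
-> summaries -> funnel exports, with a run manifest for reproducibility."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from strokecost import cohort, costing, indicators, io, standardize, synthetic
from strokecost import funnel as funnel_mod

__version__ = "0.1.0"

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: Path = Path("strokecost_out")
    #: simulate claims (with sim_config) or ingest CSVs from input_dir
    simulate: bool = True
    input_dir: Path | None = None
    sim_config: synthetic.SimConfig | None = None
    seed: int = 0
    study_start: date = date(2017, 1, 1)
    study_end: date = date(2020, 10, 2)
    horizon_days: int = 90
    min_volume: int = 30
    age_bands: tuple[float, ...] = standardize.DEFAULT_AGE_BANDS
    funnel_alphas: tuple[float, ...] = funnel_mod.DEFAULT_ALPHAS
    #: p_i estimator for standardization: "stratum" (default) or "logistic"
    expected_estimator: str = "stratum"
    currency_scale: float = 1.0
    group_keys: tuple[str, ...] = ("intervention", "provider_type", "provider_id")

    def validate(self) -> None:
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.min_volume < 1:
            raise ValueError("min_volume must be >= 1")
        if not self.simulate:
            if self.input_dir is None or not Path(self.input_dir).is_dir():
                raise FileNotFoundError(f"input_dir {self.input_dir} does not exist")
        if self.expected_estimator not in ("stratum", "logistic"):
            raise ValueError("expected_estimator must be 'stratum' or 'logistic'")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim_config", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.outdir = Path(cfg.outdir)
        if cfg.input_dir is not None:
            cfg.input_dir = Path(cfg.input_dir)
        for key in ("study_start", "study_end"):
            val = getattr(cfg, key)
            if isinstance(val, str):
                setattr(cfg, key, date.fromisoformat(val))
        if sim_raw:
            base = synthetic.default_sim_config(seed=cfg.seed)
            known = {k: v for k, v in sim_raw.items() if k in base.__dataclass_fields__}
            from dataclasses import replace

            cfg.sim_config = replace(base, **known)
        return cfg


def _pooled_within_sd(episodes: pd.DataFrame, value_col: str, unit_col: str) -> float:
    """Pooled within-unit standard deviation (the sigma0 of cost funnels)."""
    grp = episodes.groupby(unit_col)[value_col]
    counts = grp.count()
    variances = grp.var(ddof=1).fillna(0.0)
    dof = (counts - 1).clip(lower=0)
    if dof.sum() == 0:
        return float(episodes[value_col].std(ddof=0)) or 1.0
    return float(np.sqrt((variances * dof).sum() / dof.sum()))


def build_funnel_tables(episodes: pd.DataFrame, model: standardize.ReferenceModel,
                        alphas=funnel_mod.DEFAULT_ALPHAS):
    """Per-provider funnel points and limit curves for the three families.

    Returns (points, limits) long-format frames.  Families:
    ``mortality_proportion`` (crude mortality vs n), ``mortality_ratio``
    (O/E vs E) and ``cost_mean`` (mean total 90-day cost vs n).
    """
    prov = episodes.groupby("provider_id").agg(
        unit_label=("provider_type", "first"),
        n=("patient_id", "count"),
        deaths=("died_90d", "sum"),
        mean_cost=("cost_total", "mean"),
    )
    expected = standardize.add_expected(episodes, model).groupby("provider_id")["p_expected"].sum()
    prov["expected"] = expected

    theta0 = float(episodes["died_90d"].mean())
    mu0 = float(episodes["cost_total"].mean())
    sigma0 = _pooled_within_sd(episodes, "cost_total", "provider_id")

    n_grid = np.unique(np.round(np.geomspace(1, max(prov["n"].max(), 2), 80)).astype(int))
    e_grid = np.geomspace(max(prov["expected"].min() / 2, 0.1), prov["expected"].max() * 1.1, 80)

    families = {
        "mortality_proportion": (
            funnel_mod.proportion_limits(n_grid, theta0, alphas),
            prov.assign(precision=prov["n"], value=prov["deaths"] / prov["n"]),
        ),
        "mortality_ratio": (
            funnel_mod.ratio_limits(e_grid, alphas),
            prov.assign(precision=prov["expected"], value=prov["deaths"] / prov["expected"]),
        ),
        "cost_mean": (
            funnel_mod.mean_limits(n_grid, mu0, sigma0, alphas),
            prov.assign(precision=prov["n"], value=prov["mean_cost"]),
        ),
    }

    point_frames, limit_frames = [], []
    curves = {}
    for fam, (curve, pts) in families.items():
        flagged = funnel_mod.flag_units(
            pts.reset_index()[["provider_id", "unit_label", "precision", "value"]], curve
        )
        flagged.insert(0, "family", fam)
        point_frames.append(flagged)
        grid = curve.grid.copy()
        grid.insert(0, "family", fam)
        grid["target"] = curve.display_target
        limit_frames.append(grid)
        curves[fam] = curve
    return pd.concat(point_frames, ignore_index=True), pd.concat(limit_frames, ignore_index=True), curves


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write all outputs under ``config.outdir``.

    Returns the run manifest (also written to manifest.json): package version,
    seed, per-stage row counts and exclusion tallies.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # stage 1: claims
    if config.simulate:
        sim = config.sim_config or synthetic.default_sim_config(seed=config.seed)
        tables = synthetic.generate_world(sim)
        io.write_claim_tables(tables, outdir)
        logger.info("simulated %d patients, %d hospital claims", len(tables[0]), len(tables[2]))
    else:
        tables = io.read_claim_tables(config.input_dir)
        if config.currency_scale != 1.0:
            tables = list(tables)
            for i in (2, 3):
                tables[i] = tables[i].assign(cost=tables[i]["cost"] * config.currency_scale)
            tables = tuple(tables)
    patients, providers, hosp_claims, outpatient_claims = tables
    manifest["stages"]["claims"] = {
        "patients": len(patients),
        "providers": len(providers),
        "hosp_claims": len(hosp_claims),
        "outpatient_claims": len(outpatient_claims),
    }

    # stage 2: cohort
    events, rejects = cohort.select_index_events(
        hosp_claims, patients, providers, config.study_start, config.study_end,
        horizon_days=config.horizon_days,
    )
    events, excluded_providers, low_vol_rejects = cohort.apply_volume_filter(
        events, config.min_volume
    )
    rejects = pd.concat([rejects, low_vol_rejects], ignore_index=True)
    io.write_table(events, outdir / "index_events.csv")
    io.write_table(rejects, outdir / "rejects.csv")
    tally = rejects["reason"].value_counts().to_dict() if len(rejects) else {}
    manifest["stages"]["cohort"] = {
        "index_events": len(events),
        "excluded_providers": excluded_providers,
        "exclusions": tally,
    }
    logger.info("cohort: %d index events (%s)", len(events), tally or "no exclusions")

    # stage 3: episodes
    episodes = costing.compute_episode_costs(
        events, hosp_claims, outpatient_claims, patients, config.horizon_days
    )
    io.write_table(episodes, outdir / "episodes.csv")
    manifest["stages"]["episodes"] = {
        "episodes": len(episodes),
        "deaths_90d": int(episodes["died_90d"].sum()),
        "total_cost": float(episodes["cost_total"].sum()),
    }

    # stage 4: standardization
    model = standardize.fit_reference(episodes, config.age_bands)
    if config.expected_estimator == "logistic":
        episodes = episodes.assign(p_expected=standardize.fit_logistic_expected(episodes))
    io.write_table(model.to_frame(), outdir / "reference_model.csv")
    manifest["stages"]["standardization"] = {
        "overall_rate": model.overall_rate,
        "age_bands": [e if np.isfinite(e) else None for e in model.band_edges],
    }

    # stage 5: summaries
    for key in config.group_keys:
        summary = indicators.summarize_groups(episodes, model, by=key)
        io.write_table(summary, outdir / f"summary_by_{key}.csv")
        manifest["stages"][f"summary_by_{key}"] = {"groups": len(summary)}

    # stage 6: funnels
    points, limits, _ = build_funnel_tables(episodes, model, config.funnel_alphas)
    io.write_table(points, outdir / "funnel_points.csv")
    io.write_table(limits, outdir / "funnel_limits.csv")
    manifest["stages"]["funnel"] = {
        "providers": int(points.groupby("family")["provider_id"].count().max()),
        "flagged": int((points["flag"] != funnel_mod.FLAG_INSIDE).sum()),
    }

    manifest["cohort_n"] = len(episodes)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
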