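"""CSV schemas and readers/writers for the claim and result tables.

All dates are ISO-8601 (YYYY-MM-DD); missing death dates are empty cells.
File names follow the pipeline convention: patients.csv, providers.csv,
hosp_claims.csv, outpatient_claims.csv for inputs; index_events.csv,
rejects.csv, episodes.csv, reference_model.csv, summary_*.csv,
funnel_points.csv, funnel_limits.csv for outputs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

DATE_COLUMNS = {
    "patients": ["birth_date", "death_date"],
    "hosp_claims": ["admission_date", "discharge_date"],
    "outpatient_claims": ["service_date"],
    "providers": [],
    "index_events": ["index_date"],
    "episodes": ["index_date"],
}

CLAIM_FILES = ("patients", "providers", "hosp_claims", "outpatient_claims")


def write_table(frame: pd.DataFrame, path: Path | str) -> Path:
    path = Path(path)
    name = path.stem
    out = frame.copy()
    for col in DATE_COLUMNS.get(name, []):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def read_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path)
    for col in DATE_COLUMNS.get(path.stem, []):
        if col in frame.columns:
            frame[col] = pd.to_datetime(frame[col])
    return frame


def write_claim_tables(tables, outdir: Path | str) -> dict[str, Path]:
    """Write (patients, providers, hosp_claims, outpatient_claims) CSVs."""
    outdir = Path(outdir)
    paths = {}
    for name, frame in zip(CLAIM_FILES, tables):
        paths[name] = write_table(frame, outdir / f"{name}.csv")
    return paths


def read_claim_tables(indir: Path | str):
    indir = Path(indir)
    return tuple(read_table(indir / f"{name}.csv") for name in CLAIM_FILES)
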