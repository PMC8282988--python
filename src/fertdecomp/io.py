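"""CSV input/output with a versioned header schema.

Every file written by the package begins with a comment line
``# fertdecomp-schema v1 <table>`` followed by a plain CSV table, so the
files remain readable by any CSV tool (readers here skip ``#`` lines).
Birth histories are stored as space-separated CMCs in the ``bh_cmcs``
column; a ``marriage_cmc`` of -1 marks never-married records.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError

SCHEMA_VERSION = "v1"

_REQUIRED = {
    "women": ["woman_id", "cluster_id", "sample_weight", "v008", "v011",
              "marriage_cmc", "currently_married", "nationality", "bh_cmcs",
              "current_method"],
    "roster": ["member_id", "age_years", "sex", "marital_status",
               "nationality", "hh_weight"],
    "calendar": ["woman_id", "calendar", "termination_type_last"],
    "service_stats": ["year", "method", "commodities_to_clients"],
    "vitals": ["year", "births", "pop_end_year_total", "wra_end_year"],
}


def write_table(df: pd.DataFrame, path, table: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# fertdecomp-schema {SCHEMA_VERSION} {table}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
    return path


def read_table(path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED.get(table, []) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {table} table missing columns {missing}")
    if "bh_cmcs" in df.columns:  # empty histories round-trip as NaN
        df["bh_cmcs"] = df["bh_cmcs"].fillna("").astype(str)
    return df


def write_survey(survey, out_dir) -> dict:
    """Write women/roster (and calendar, if generated) CSVs; returns paths."""
    out = Path(out_dir)
    paths = {
        "women": write_table(survey.women, out / "women.csv", "women"),
        "roster": write_table(survey.roster, out / "roster.csv", "roster"),
        "population": write_table(survey.population, out / "population.csv", "women"),
    }
    if "calendar" in survey.women.columns:
        cal = survey.women[["woman_id", "calendar", "termination_type_last",
                            "premarital_window_months"]]
        paths["calendar"] = write_table(cal, out / "calendar.csv", "calendar")
    return paths
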