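"""Reading and writing the delimited-text cohort and life-table formats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError
from .mortality import LifeTable

COHORT_REQUIRED = [
    "person_id",
    "sex",
    "age",
    "year",
    "codes",
    "adg_score",
    "rurality",
    "income_quintile",
    "los_days",
    "severity",
    "mechanism",
    "death_within_30d",
    "followup_days",
    "discharge_location",
    "record_source",
]

SEVERITY_LABELS = {"mild", "moderate", "severe", "unknown"}
MECHANISM_LABELS = {"falls", "struck", "mvc", "cyclist", "other"}
DISCHARGE_LABELS = {"home", "home_support", "ltc", "ccc", "rehab", "other"}
SOURCE_LABELS = {"acute", "ed"}


def read_cohort(path, code_delimiter: str = "|") -> pd.DataFrame:
    """Schema-validated cohort read.

    Labels are case-normalized ("Unknown" severity is the literal
    category, not a missing value).  Malformed categorical labels are
    reported with their row numbers; missing required columns are fatal.
    """
    df = pd.read_csv(path, dtype={"codes": str, "person_id": str})
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing columns: {missing}")
    df["codes"] = df["codes"].fillna("")
    if "sublocation" not in df.columns:
        df["sublocation"] = ""
    df["sublocation"] = df["sublocation"].fillna("")
    for col in ("severity", "mechanism", "record_source"):
        df[col] = df[col].astype(str).str.strip().str.lower()
    df["discharge_location"] = (
        df["discharge_location"].astype("string").str.strip().str.lower()
    )
    _check_labels(df, "severity", SEVERITY_LABELS)
    _check_labels(df, "mechanism", MECHANISM_LABELS)
    _check_labels(df, "record_source", SOURCE_LABELS)
    _check_labels(df, "discharge_location", DISCHARGE_LABELS, allow_missing=True)
    if df["person_id"].duplicated().any():
        dup = df.loc[df["person_id"].duplicated(), "person_id"].iloc[0]
        raise SchemaError(f"duplicate person_id: {dup}")
    if not df["sex"].isin([0, 1]).all():
        bad = df.index[~df["sex"].isin([0, 1])][0]
        raise SchemaError(f"sex must be 0/1 (row {bad + 2})")
    return df


def _check_labels(df, col, allowed, allow_missing=False):
    vals = df[col]
    mask = ~vals.isin(list(allowed))
    if allow_missing:
        mask &= vals.notna()
    if mask.any():
        rows = (np.flatnonzero(mask.to_numpy()) + 2)[:5]  # 1-based + header
        raise SchemaError(
            f"unknown {col} label(s) {sorted(set(vals[mask].dropna()))} "
            f"at file line(s) {list(rows)}"
        )


def read_lifetable(path) -> LifeTable:
    return LifeTable.read_csv(path)


def write_screen_table(selection: pd.DataFrame, path) -> None:
    cols = [
        "code",
        "or_train",
        "or_valid",
        "p_train",
        "p_valid",
        "p_train_adj",
        "p_valid_adj",
        "selected",
    ]
    selection[cols].to_csv(path, index=False)


def mortality_report(contexts: dict, lrt_rows: list[dict]) -> pd.DataFrame:
    """Rate-ratio table across the three mortality models."""
    rows = []
    for name, ctx in contexts.items():
        res = ctx.result
        for term, coef in res.params.items():
            if term == "intercept":
                continue
            se = res.se(term)
            rows.append(
                {
                    "model": name,
                    "term": term,
                    "rate_ratio": float(np.exp(coef)),
                    "ci_low": float(np.exp(coef - 1.959964 * se)),
                    "ci_high": float(np.exp(coef + 1.959964 * se)),
                }
            )
    table = pd.DataFrame(rows)
    if lrt_rows:
        table = table.merge(pd.DataFrame(lrt_rows), on=["model", "term"], how="left")
    return table
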