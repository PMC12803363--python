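"""Column-level validation of the CSV interchange files."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SchemaReport:
    name: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _require_columns(df: pd.DataFrame, cols: list[str], report: SchemaReport) -> bool:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        report.violations.append(f"missing column(s): {missing}")
        return False
    return True


def _check_numeric(df, col, report, lo=None, hi=None, integer=False, allow_nan=False):
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() & df[col].notna()
    if bad.any():
        report.violations.append(f"{col}: {int(bad.sum())} non-numeric value(s)")
    if not allow_nan and df[col].isna().any():
        report.violations.append(f"{col}: {int(df[col].isna().sum())} empty value(s)")
    ok = vals.dropna()
    if integer and not np.allclose(ok, ok.round()):
        report.violations.append(f"{col}: non-integer value(s)")
    if lo is not None and (ok < lo).any():
        report.violations.append(f"{col}: value(s) below {lo}")
    if hi is not None and (ok > hi).any():
        report.violations.append(f"{col}: value(s) above {hi}")


def validate_measurements(df: pd.DataFrame) -> SchemaReport:
    r = SchemaReport("measurements")
    if not _require_columns(df, ["patient_id", "day", "raw_value", "assay_format"], r):
        return r
    _check_numeric(df, "day", r, integer=True)
    _check_numeric(df, "raw_value", r, lo=np.nextafter(0, 1))
    counts = df.groupby("patient_id").size()
    singles = counts[counts < 2]
    if not singles.empty:
        r.violations.append(f"{len(singles)} patient(s) with fewer than 2 measurements")
    return r


def validate_treatment(df: pd.DataFrame) -> SchemaReport:
    r = SchemaReport("treatment")
    if not _require_columns(df, ["patient_id", "treatment_start_day"], r):
        return r
    _check_numeric(df, "treatment_start_day", r, integer=True)
    if df["patient_id"].duplicated().any():
        r.violations.append("duplicate patient_id")
    return r


def validate_dispensations(df: pd.DataFrame) -> SchemaReport:
    r = SchemaReport("dispensations")
    if not _require_columns(df, ["patient_id", "fill_day", "days_supplied"], r):
        return r
    _check_numeric(df, "fill_day", r, integer=True, lo=0)
    _check_numeric(df, "days_supplied", r, integer=True, lo=1)
    return r


def validate_covariates(df: pd.DataFrame) -> SchemaReport:
    r = SchemaReport("covariates")
    cols = ["patient_id", "age_at_dx", "bmi", "sex", "first_line_treatment"]
    if not _require_columns(df, cols, r):
        return r
    _check_numeric(df, "age_at_dx", r, lo=np.nextafter(18, 19))
    _check_numeric(df, "bmi", r, lo=5, hi=100, allow_nan=True)
    if df["patient_id"].duplicated().any():
        r.violations.append("duplicate patient_id")
    return r


def validate_aligned(df: pd.DataFrame) -> SchemaReport:
    r = SchemaReport("aligned")
    if not _require_columns(df, ["patient_id", "t_index", "value"], r):
        return r
    _check_numeric(df, "t_index", r, integer=True, lo=0)
    _check_numeric(df, "value", r, allow_nan=True)
    if df.duplicated(["patient_id", "t_index"]).any():
        r.violations.append("duplicate (patient_id, t_index) rows")
    return r


def validate_adherence(df: pd.DataFrame) -> SchemaReport:
    r = SchemaReport("adherence")
    if not _require_columns(df, ["patient_id", "t_index", "adherence"], r):
        return r
    _check_numeric(df, "t_index", r, integer=True, lo=0)
    _check_numeric(df, "adherence", r, lo=0.0, hi=1.0)
    if df.duplicated(["patient_id", "t_index"]).any():
        r.violations.append("duplicate (patient_id, t_index) rows")
    return r


VALIDATORS = {
    "measurements": validate_measurements,
    "treatment": validate_treatment,
    "dispensations": validate_dispensations,
    "covariates": validate_covariates,
    "aligned": validate_aligned,
    "adherence": validate_adherence,
}


def validate_file(path, schema_name: str) -> SchemaReport:
    if schema_name not in VALIDATORS:
        raise KeyError(f"unknown schema {schema_name!r}")
    df = pd.read_csv(path)
    return VALIDATORS[schema_name](df)
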