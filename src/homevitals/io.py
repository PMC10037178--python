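"""Readers and writers for the cohort CSV tables.

The on-disk format is deliberately plain: two delimited text files with a
header, ISO-8601 timestamps with an explicit UTC offset, and ISO dates for
the profile table.  ``read_cohort(write_cohort(ds))`` is the identity on
validated datasets up to canonical row order.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import (
    MEASUREMENT_COLUMNS,
    PROFILE_COLUMNS,
    CohortDataset,
    CohortFormatError,
    CohortValidationError,
    RowIssue,
    empty_measurements,
    empty_profiles,
)

_REQUIRED_MEASUREMENT_COLS = ["participant_id", "domain", "value", "timestamp"]
_REQUIRED_PROFILE_COLS = ["participant_id", "subtype"]


def _require_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")


def read_measurements(path: str | Path) -> tuple[pd.DataFrame, list[RowIssue]]:
    """Read a measurement CSV; returns the parsed table plus row diagnostics
    for unparseable values/timestamps (parse-level only; range and
    referential checks happen in :meth:`CohortDataset.validate`)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _REQUIRED_MEASUREMENT_COLS, path)
    if "device_id" not in df.columns:
        df["device_id"] = ""
    if df.empty:
        return empty_measurements(), []
    issues: list[RowIssue] = []
    value = pd.to_numeric(df["value"], errors="coerce")
    for i in value.index[value.isna()]:
        issues.append(RowIssue("measurements", int(i), f"value {df['value'].iat[i]!r} not numeric"))
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    for i in ts.index[ts.isna()]:
        issues.append(
            RowIssue("measurements", int(i), f"timestamp {df['timestamp'].iat[i]!r} not ISO-8601")
        )
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "domain": df["domain"].astype(str),
            "value": value,
            "timestamp": ts,
            "device_id": df["device_id"].astype(str),
        }
    )
    return out, issues


def read_profiles(path: str | Path) -> tuple[pd.DataFrame, list[RowIssue]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, _REQUIRED_PROFILE_COLS, path)
    for col in PROFILE_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    if df.empty:
        return empty_profiles(), []
    issues: list[RowIssue] = []
    age = pd.to_numeric(df["age_years"].replace("", None), errors="coerce")
    smmse_raw = df["smmse"].replace("", None)
    smmse = pd.to_numeric(smmse_raw, errors="coerce")
    for i in smmse.index[smmse.isna() & smmse_raw.notna()]:
        issues.append(RowIssue("profiles", int(i), f"smmse {df['smmse'].iat[i]!r} not an integer"))
    enroll = pd.to_datetime(df["enrollment_date"].replace("", None), errors="coerce")
    withdraw = pd.to_datetime(df["withdrawal_date"].replace("", None), errors="coerce")
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].astype(str),
            "subtype": df["subtype"].astype(str),
            "age_years": age,
            "sex": df["sex"].astype(str),
            "smmse": smmse.round().astype("Int64"),
            "enrollment_date": enroll,
            "withdrawal_date": withdraw,
        }
    )
    return out, issues


def read_cohort(
    measurements_path: str | Path,
    profiles_path: str | Path,
    *,
    errors: str = "raise",
) -> CohortDataset:
    """Read and validate a cohort from its two CSV files.

    Parameters
    ----------
    errors : {"raise", "report"}
        With ``"raise"`` (default) any invalid row aborts with a
        :class:`CohortValidationError` listing every offending row.  With
        ``"report"`` invalid rows are excluded and the diagnostics stored in
        ``dataset.provenance["validation_issues"]``.
    """
    if errors not in {"raise", "report"}:
        raise ValueError("errors must be 'raise' or 'report'")
    measurements, m_issues = read_measurements(measurements_path)
    profiles, p_issues = read_profiles(profiles_path)
    parse_issues = m_issues + p_issues
    if parse_issues and errors == "raise":
        raise CohortValidationError(parse_issues)
    # drop rows that failed parsing before invariant checks
    bad_m = {i.row for i in m_issues}
    bad_p = {i.row for i in p_issues}
    if bad_m:
        measurements = measurements.drop(index=list(bad_m)).reset_index(drop=True)
    if bad_p:
        profiles = profiles.drop(index=list(bad_p)).reset_index(drop=True)
    ds = CohortDataset(
        measurements,
        profiles,
        provenance={"measurements_path": str(measurements_path), "profiles_path": str(profiles_path)},
    )
    inv_issues = ds.validate()
    if inv_issues:
        if errors == "raise":
            raise CohortValidationError(inv_issues)
        drop_rows = [i.row for i in inv_issues if i.table == "measurements"]
        ds.measurements = ds.measurements.drop(index=drop_rows).reset_index(drop=True)
    ds.provenance["validation_issues"] = [str(i) for i in parse_issues + inv_issues]
    return ds.canonical()


def write_cohort(
    dataset: CohortDataset,
    measurements_path: str | Path,
    profiles_path: str | Path,
) -> tuple[Path, Path]:
    """Serialize a cohort to its two CSV files (UTC ISO-8601 timestamps).

    The dataset is written in canonical order so that a write/read round trip
    reproduces it exactly.
    """
    ds = dataset.canonical()
    measurements_path = Path(measurements_path)
    profiles_path = Path(profiles_path)

    m = ds.measurements.copy()
    if len(m):
        m["timestamp"] = m["timestamp"].map(lambda t: t.isoformat())
    m.to_csv(measurements_path, index=False, columns=MEASUREMENT_COLUMNS)

    p = ds.profiles.copy()
    for col in ("enrollment_date", "withdrawal_date"):
        if len(p):
            p[col] = p[col].map(lambda d: "" if pd.isna(d) else pd.Timestamp(d).date().isoformat())
    p.to_csv(profiles_path, index=False, columns=PROFILE_COLUMNS)
    return measurements_path, profiles_path
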