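"""Core data model for sporadic home vital-sign streams.

Measurements are kept in long ("tidy") form, one timestamped value per row,
because each home device reports one or two physiological domains and the
streams are asynchronous.  A cuff reading contributes two rows (SBP and DBP)
sharing a timestamp.  Timestamps are stored timezone-aware in UTC; the study
timezone (see :class:`homevitals.config.StudyConfig`) governs hour-of-day and
calendar-day arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd


class Domain(str, enum.Enum):
    """Physiological measurement domains recorded by the home devices."""

    HR = "HR"          # heart rate, bpm
    SBP = "SBP"        # systolic blood pressure, mm Hg
    DBP = "DBP"        # diastolic blood pressure, mm Hg
    SPO2 = "SPO2"      # peripheral oxygen saturation, %
    TEMP = "TEMP"      # body temperature, deg C
    WEIGHT = "WEIGHT"  # body weight, kg

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Subtype(str, enum.Enum):
    """Dementia subtype groups used for between-group comparisons."""

    AD = "AD"        # Alzheimer disease
    VD = "VD"        # vascular dementia
    ASYN = "ASYN"    # alpha-synuclein-associated (PDD + DLB)

    def __str__(self) -> str:  # pragma: no cover
        return self.value


DOMAIN_UNITS: dict[Domain, str] = {
    Domain.HR: "bpm",
    Domain.SBP: "mm Hg",
    Domain.DBP: "mm Hg",
    Domain.SPO2: "%",
    Domain.TEMP: "degC",
    Domain.WEIGHT: "kg",
}

# Plausible value ranges (lower open, upper open unless flagged inclusive).
# Rows outside these ranges are rejected by validation, not silently dropped.
DOMAIN_RANGES: dict[Domain, tuple[float, float, bool]] = {
    Domain.HR: (0.0, 300.0, False),
    Domain.SBP: (0.0, 350.0, False),
    Domain.DBP: (0.0, 250.0, False),
    Domain.SPO2: (0.0, 100.0, True),   # 100% is attainable
    Domain.TEMP: (25.0, 45.0, False),
    Domain.WEIGHT: (0.0, 400.0, False),
}

#: Device -> domains it records.  The cuff reports two pressures, the pulse
#: oximeter reports saturation and pulse rate; scales and thermometer report
#: a single domain each.
DEVICE_DOMAINS: dict[str, tuple[Domain, ...]] = {
    "bp_monitor": (Domain.SBP, Domain.DBP),
    "pulse_oximeter": (Domain.SPO2, Domain.HR),
    "scales": (Domain.WEIGHT,),
    "thermometer": (Domain.TEMP,),
}

DOMAIN_DEVICE: dict[Domain, str] = {
    dom: dev for dev, doms in DEVICE_DOMAINS.items() for dom in doms
}

MEASUREMENT_COLUMNS = ["participant_id", "domain", "value", "timestamp", "device_id"]
PROFILE_COLUMNS = [
    "participant_id",
    "subtype",
    "age_years",
    "sex",
    "smmse",
    "enrollment_date",
    "withdrawal_date",
]


@dataclass
class RowIssue:
    """A validation diagnostic tied to a specific input row."""

    table: str
    row: int
    message: str

    def __str__(self) -> str:
        return f"{self.table} row {self.row}: {self.message}"


class CohortValidationError(ValueError):
    """Raised when a dataset violates the data-model invariants.

    Carries the full list of :class:`RowIssue` diagnostics so every offending
    row is reported, never silently dropped.
    """

    def __init__(self, issues: list[RowIssue]):
        self.issues = issues
        preview = "; ".join(str(i) for i in issues[:10])
        more = "" if len(issues) <= 10 else f" (+{len(issues) - 10} more)"
        super().__init__(f"{len(issues)} validation issue(s): {preview}{more}")


class CohortFormatError(ValueError):
    """Raised when an input file is structurally malformed (e.g. missing column)."""


def _check_measurement_rows(measurements: pd.DataFrame) -> list[RowIssue]:
    issues: list[RowIssue] = []
    valid_domains = {d.value for d in Domain}
    for i, row in enumerate(measurements.itertuples(index=False)):
        dom = row.domain
        if dom not in valid_domains:
            issues.append(RowIssue("measurements", i, f"unknown domain {dom!r}"))
            continue
        v = row.value
        if not np.isfinite(v) or v <= 0:
            issues.append(
                RowIssue("measurements", i, f"{dom} value {v!r} is not finite and positive")
            )
            continue
        lo, hi, hi_incl = DOMAIN_RANGES[Domain(dom)]
        ok = (v > lo) and (v < hi or (hi_incl and v == hi))
        if not ok:
            bound = f"({lo}, {hi}{']' if hi_incl else ')'}"
            issues.append(
                RowIssue("measurements", i, f"{dom} value {v} outside plausible range {bound}")
            )
        if pd.isna(row.timestamp):
            issues.append(RowIssue("measurements", i, "timestamp missing or unparseable"))
    dup = measurements.duplicated(keep=False)
    for i in np.flatnonzero(dup.to_numpy()):
        issues.append(RowIssue("measurements", int(i), "exact duplicate of another row"))
    return issues


def _check_profile_rows(profiles: pd.DataFrame) -> list[RowIssue]:
    issues: list[RowIssue] = []
    valid = {s.value for s in Subtype}
    seen: set[str] = set()
    for i, row in enumerate(profiles.itertuples(index=False)):
        pid = row.participant_id
        if pid in seen:
            issues.append(RowIssue("profiles", i, f"duplicate participant_id {pid!r}"))
        seen.add(pid)
        if row.subtype not in valid:
            issues.append(RowIssue("profiles", i, f"unknown subtype {row.subtype!r}"))
        smmse = row.smmse
        if not pd.isna(smmse) and not (0 <= smmse <= 30):
            issues.append(RowIssue("profiles", i, f"SMMSE {smmse} outside [0, 30]"))
        if (
            not pd.isna(row.withdrawal_date)
            and not pd.isna(row.enrollment_date)
            and row.withdrawal_date < row.enrollment_date
        ):
            issues.append(RowIssue("profiles", i, "withdrawal_date before enrollment_date"))
    return issues


@dataclass
class CohortDataset:
    """A cohort of long-format measurements plus static participant metadata.

    Attributes
    ----------
    measurements : pandas.DataFrame
        Columns ``participant_id, domain, value, timestamp, device_id`` with
        tz-aware UTC timestamps.
    profiles : pandas.DataFrame
        One row per participant: ``participant_id, subtype, age_years, sex,
        smmse, enrollment_date, withdrawal_date``.  SMMSE may be missing.
    provenance : dict
        Free-form metadata (source, generator seed, ...).
    """

    measurements: pd.DataFrame
    profiles: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def validate(self) -> list[RowIssue]:
        """Return all invariant violations (empty list when valid)."""
        issues = _check_measurement_rows(self.measurements)
        issues += _check_profile_rows(self.profiles)
        known = set(self.profiles["participant_id"])
        orphan_mask = ~self.measurements["participant_id"].isin(known)
        for i in np.flatnonzero(orphan_mask.to_numpy()):
            pid = self.measurements["participant_id"].iat[int(i)]
            issues.append(
                RowIssue("measurements", int(i), f"participant_id {pid!r} absent from profiles")
            )
        return issues

    def assert_valid(self) -> "CohortDataset":
        issues = self.validate()
        if issues:
            raise CohortValidationError(issues)
        return self

    def canonical(self) -> "CohortDataset":
        """Copy with measurements sorted by (participant, domain, timestamp)."""
        m = (
            self.measurements.sort_values(
                ["participant_id", "domain", "timestamp"], kind="mergesort"
            ).reset_index(drop=True)
        )
        p = self.profiles.sort_values("participant_id", kind="mergesort").reset_index(drop=True)
        return CohortDataset(m, p, dict(self.provenance))

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    @property
    def n_participants(self) -> int:
        return len(self.profiles)


def empty_measurements() -> pd.DataFrame:
    """An empty measurement table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "domain": pd.Series(dtype=str),
            "value": pd.Series(dtype=float),
            "timestamp": pd.Series(dtype="datetime64[ns, UTC]"),
            "device_id": pd.Series(dtype=str),
        }
    )


def empty_profiles() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "subtype": pd.Series(dtype=str),
            "age_years": pd.Series(dtype=float),
            "sex": pd.Series(dtype=str),
            "smmse": pd.Series(dtype="Int64"),
            "enrollment_date": pd.Series(dtype="datetime64[ns]"),
            "withdrawal_date": pd.Series(dtype="datetime64[ns]"),
        }
    )


def make_measurements(records: Iterable[tuple]) -> pd.DataFrame:
    """Build a measurement table from ``(pid, domain, value, timestamp[, device])``
    tuples; a convenience used heavily by tests and the simulator."""
    rows = []
    for rec in records:
        pid, dom, value, ts = rec[:4]
        device = rec[4] if len(rec) > 4 else DOMAIN_DEVICE[Domain(dom)]
        rows.append((pid, str(Domain(dom).value), float(value), pd.Timestamp(ts), device))
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    ts = pd.to_datetime(df["timestamp"])
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    df["timestamp"] = ts.dt.tz_convert("UTC")
    return df
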