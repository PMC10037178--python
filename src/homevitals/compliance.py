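"""Adherence and engagement analytics for patient-initiated streams.

Definitions
-----------
days of observation
    Elapsed (fractional) days between a participant's first and last
    recorded measurement.  Used as the denominator for per-day rates.
calendar days
    Count of local calendar dates from the first to the last measurement,
    inclusive.  Used as the denominator for day fractions.
full-set day
    A calendar day on which every *available* device contributed at least
    one measurement (a participant issued only a thermometer has a full-set
    day whenever the thermometer was used).
any-measurement day
    A calendar day with at least one measurement from any device.
weekly counts
    Measurements per consecutive 7-day block anchored at the participant's
    first measurement, including zero-count interior weeks; the per-
    participant engagement slope is the OLS slope of count against week
    index, and the cohort-level test is a two-sided one-sample t-test of
    the slopes against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import DEVICE_DOMAINS, DOMAIN_DEVICE, CohortDataset, Domain
from .stats import one_sample_t

logger = logging.getLogger(__name__)

ALL_DEVICES = tuple(DEVICE_DOMAINS)


@dataclass
class ComplianceSummary:
    """Per-participant adherence metrics."""

    participant_id: str
    days_of_observation: float
    n_calendar_days: int
    frac_full_set_days: float
    frac_any_days: float
    hourly_counts: np.ndarray        # 24 integers, local hour of day
    weekly_counts: np.ndarray
    slope: float                     # measurements/week per week; NaN if <2 weeks

    @property
    def hourly_pct(self) -> np.ndarray:
        total = self.hourly_counts.sum()
        return self.hourly_counts / total if total else np.zeros(24)


def observation_span(stream: pd.DataFrame, tz: str = "UTC") -> tuple[float, int]:
    """(elapsed fractional days, inclusive local calendar-day count) of a stream."""
    if len(stream) == 0:
        raise ValueError("observation span of an empty stream is undefined")
    ts = stream["timestamp"]
    first, last = ts.min(), ts.max()
    elapsed_days = (last - first).total_seconds() / 86400.0
    local = ts.dt.tz_convert(tz)
    n_calendar = (local.max().date() - local.min().date()).days + 1
    return float(elapsed_days), int(n_calendar)


def day_fractions(
    stream: pd.DataFrame,
    tz: str = "UTC",
    available_devices: tuple[str, ...] = ALL_DEVICES,
) -> tuple[float, float]:
    """(fraction of full-set days, fraction of any-measurement days).

    Both fractions use the inclusive calendar-day count as denominator.  A
    day is full-set iff every device in ``available_devices`` contributed;
    unavailable devices are ignored.
    """
    if not available_devices:
        raise ValueError("available_devices must be nonempty")
    _, n_days = observation_span(stream, tz)
    local_date = stream["timestamp"].dt.tz_convert(tz).dt.date
    device = stream["domain"].map(lambda d: DOMAIN_DEVICE[Domain(d)])
    by_day = pd.DataFrame({"date": local_date, "device": device})
    any_days = by_day["date"].nunique()
    needed = set(available_devices)
    per_day_devices = by_day.groupby("date")["device"].agg(set)
    full_days = int(sum(needed <= devs for devs in per_day_devices))
    return full_days / n_days, any_days / n_days


def hourly_histogram(stream: pd.DataFrame, tz: str = "UTC") -> np.ndarray:
    """Count of measurements per local hour of day (length-24 array)."""
    hours = stream["timestamp"].dt.tz_convert(tz).dt.hour
    return np.bincount(hours, minlength=24)


def weekly_counts(stream: pd.DataFrame) -> np.ndarray:
    """Measurements per consecutive 7-day block from the first measurement.

    Interior weeks without measurements contribute zero counts.
    """
    if len(stream) == 0:
        raise ValueError("weekly counts of an empty stream are undefined")
    ts = stream["timestamp"]
    first = ts.min()
    week_idx = ((ts - first).dt.total_seconds() // (7 * 86400)).astype(int)
    return np.bincount(week_idx, minlength=int(week_idx.max()) + 1)


def weekly_slope(stream: pd.DataFrame, fit: str = "interior") -> tuple[np.ndarray, float]:
    """Weekly counts and the OLS slope of count versus week index.

    With ``fit="interior"`` (default) the boundary blocks are excluded from
    the fit: the first block contains the anchoring measurement by
    construction and the final block is right-censored at the last
    measurement, so both carry structural bias that would masquerade as an
    engagement trend.  ``fit="all"`` fits every block.  The slope is NaN
    (with a log record) when fewer than two fit points remain.
    """
    counts = weekly_counts(stream)
    if fit == "interior":
        lo, hi = 1, len(counts) - 1
    elif fit == "all":
        lo, hi = 0, len(counts)
    else:
        raise ValueError("fit must be 'interior' or 'all'")
    y = counts[lo:hi].astype(float)
    if len(y) < 2:
        logger.info("fewer than two fit weeks; slope undefined")
        return counts, float("nan")
    x = np.arange(lo, hi, dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    return counts, slope


def cohort_slope_test(slopes) -> tuple[float, float, int]:
    """Two-sided one-sample t-test of the engagement slopes against zero."""
    slopes = np.asarray(slopes, dtype=float)
    slopes = slopes[np.isfinite(slopes)]
    return one_sample_t(slopes, 0.0)


def summarize_participant(
    stream: pd.DataFrame,
    participant_id: str,
    tz: str = "UTC",
    available_devices: tuple[str, ...] = ALL_DEVICES,
) -> ComplianceSummary:
    elapsed, n_days = observation_span(stream, tz)
    frac_full, frac_any = day_fractions(stream, tz, available_devices)
    counts, slope = weekly_slope(stream)
    return ComplianceSummary(
        participant_id=participant_id,
        days_of_observation=elapsed,
        n_calendar_days=n_days,
        frac_full_set_days=frac_full,
        frac_any_days=frac_any,
        hourly_counts=hourly_histogram(stream, tz),
        weekly_counts=counts,
        slope=slope,
    )


def summarize_cohort(
    dataset: CohortDataset | pd.DataFrame,
    tz: str = "UTC",
    available_devices: tuple[str, ...] = ALL_DEVICES,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Compliance summary table for every participant with measurements.

    Returns
    -------
    summary : DataFrame
        One row per participant with span, day fractions and slope.
    hourly : DataFrame
        Long table (participant_id, hour, count).
    cohort : dict
        Cohort medians and the slope t-test (t, p, df, n_slopes).
    """
    measurements = dataset.measurements if isinstance(dataset, CohortDataset) else dataset
    rows, hourly_rows = [], []
    summaries: list[ComplianceSummary] = []
    for pid, stream in measurements.groupby("participant_id"):
        s = summarize_participant(stream, pid, tz, available_devices)
        summaries.append(s)
        rows.append(
            {
                "participant_id": pid,
                "n_measurements": len(stream),
                "days_of_observation": s.days_of_observation,
                "n_calendar_days": s.n_calendar_days,
                "frac_full_set_days": s.frac_full_set_days,
                "frac_any_days": s.frac_any_days,
                "n_weeks": len(s.weekly_counts),
                "slope": s.slope,
            }
        )
        for hour, count in enumerate(s.hourly_counts):
            hourly_rows.append({"participant_id": pid, "hour": hour, "count": int(count)})
    summary = pd.DataFrame(rows)
    hourly = pd.DataFrame(hourly_rows)
    cohort: dict = {"n_participants": len(summary)}
    if len(summary):
        cohort["median_frac_any_days"] = float(summary["frac_any_days"].median())
        cohort["median_frac_full_set_days"] = float(summary["frac_full_set_days"].median())
        cohort["median_days_of_observation"] = float(summary["days_of_observation"].median())
        finite_slopes = summary["slope"].to_numpy()
        finite_slopes = finite_slopes[np.isfinite(finite_slopes)]
        cohort["n_slopes"] = int(len(finite_slopes))
        if len(finite_slopes) >= 2:
            t, p, df = cohort_slope_test(finite_slopes)
            cohort.update({"slope_t": t, "slope_p": p, "slope_df": df})
    return summary, hourly, cohort
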