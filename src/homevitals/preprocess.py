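"""Data cleaning for device-initiated measurement streams.

Two rules are applied, in a fixed order, before any summary or alerting
analysis:

1. **Duplicate removal** — within each (participant, domain) stream a
   measurement is removed iff it was recorded less than a window (default
   60 s) after the most recent *retained* measurement.  Anchoring on the
   retained row means a burst of device retries collapses to its first
   element, and the rule is idempotent.
2. **Outlier exclusion** — within each (participant, domain) stream, the
   mean and sample SD (n-1 denominator) are computed once over all values,
   candidates included, and rows strictly further than ``k`` SD (default 4)
   from the mean are removed in a single pass.  Streams with fewer than two
   values, or zero SD, pass through untouched.

Every removed row is retained in the :class:`FilterReport` with a reason tag
so counts always reconcile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REASON_DUPLICATE = "duplicate_within_window"
REASON_OUTLIER = "outlier_gt_k_sd"


@dataclass
class FilterReport:
    """Accounting of rows removed by the cleaning rules."""

    n_input: int
    n_removed_duplicates: int = 0
    n_removed_outliers: int = 0
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed_duplicates - self.n_removed_outliers

    def check(self) -> None:
        assert self.n_removed_duplicates + self.n_removed_outliers == len(self.removed)

    @staticmethod
    def combine(first: "FilterReport", second: "FilterReport") -> "FilterReport":
        removed = pd.concat([first.removed, second.removed], ignore_index=True)
        return FilterReport(
            n_input=first.n_input,
            n_removed_duplicates=first.n_removed_duplicates + second.n_removed_duplicates,
            n_removed_outliers=first.n_removed_outliers + second.n_removed_outliers,
            removed=removed,
        )


def _retained_anchor_keep(times_ns: np.ndarray, window_ns: int) -> np.ndarray:
    """Keep mask under the retained-anchor rule: a row is kept iff it falls at
    least ``window_ns`` after the last kept row."""
    keep = np.zeros(times_ns.shape[0], dtype=bool)
    last = None
    for i, t in enumerate(times_ns):
        if last is None or t - last >= window_ns:
            keep[i] = True
            last = t
    return keep


def deduplicate(
    measurements: pd.DataFrame, window_seconds: float = 60.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove repeat measurements recorded within ``window_seconds`` of the
    most recent retained measurement in the same (participant, domain) stream.

    The input need not be sorted; streams are sorted by timestamp internally.
    Returns the retained rows (original row order preserved) and a report.
    """
    if window_seconds < 0:
        raise ValueError("dedup window must be >= 0")
    n = len(measurements)
    if n == 0:
        return measurements.copy(), FilterReport(0, removed=measurements.iloc[0:0].copy())
    window_ns = int(round(window_seconds * 1e9))
    keep = np.ones(n, dtype=bool)
    times = measurements["timestamp"].astype("int64").to_numpy()
    order = np.lexsort(
        (times, measurements["domain"].to_numpy(), measurements["participant_id"].to_numpy())
    )
    grouped = measurements.iloc[order]
    pos = 0
    for _, grp in grouped.groupby(["participant_id", "domain"], sort=False):
        m = len(grp)
        grp_keep = _retained_anchor_keep(times[order[pos : pos + m]], window_ns)
        keep[order[pos : pos + m]] = grp_keep
        pos += m
    removed = measurements.loc[~keep].copy()
    removed["reason"] = REASON_DUPLICATE
    report = FilterReport(n, n_removed_duplicates=int((~keep).sum()), removed=removed.reset_index(drop=True))
    report.check()
    return measurements.loc[keep].copy(), report


def filter_outliers(
    measurements: pd.DataFrame, k_sd: float = 4.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Single-pass within-participant outlier exclusion.

    Mean and sample SD are computed once per (participant, domain) over all
    values (candidates included); rows with ``|value - mean| > k_sd * SD``
    are removed.  No re-iteration: applying the filter twice equals applying
    it once only if the statistics are not recomputed, which is why this is
    a single pass by contract.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be strictly positive")
    n = len(measurements)
    if n == 0:
        return measurements.copy(), FilterReport(0, removed=measurements.iloc[0:0].copy())
    g = measurements.groupby(["participant_id", "domain"])["value"]
    mean = g.transform("mean")
    sd = g.transform("std")  # ddof=1; NaN for singleton streams
    dev = (measurements["value"] - mean).abs()
    # NaN or zero SD -> keep (strict inequality cannot be satisfied)
    remove = (dev > k_sd * sd).fillna(False).to_numpy()
    removed = measurements.loc[remove].copy()
    removed["reason"] = REASON_OUTLIER
    report = FilterReport(n, n_removed_outliers=int(remove.sum()), removed=removed.reset_index(drop=True))
    report.check()
    return measurements.loc[~remove].copy(), report


def preprocess(measurements: pd.DataFrame, config=None) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the cleaning rules in fixed order: dedup, then outlier filter.

    ``config`` is a :class:`homevitals.config.StudyConfig`; either rule can
    be disabled for sensitivity analyses via its switches.
    """
    from .config import StudyConfig

    config = config or StudyConfig()
    report = FilterReport(len(measurements), removed=measurements.iloc[0:0].copy())
    out = measurements
    if config.apply_dedup:
        out, rep1 = deduplicate(out, config.dedup_window_seconds)
        report = FilterReport.combine(report, rep1)
    if config.apply_outlier_filter:
        out, rep2 = filter_outliers(out, config.outlier_sd_k)
        report = FilterReport.combine(report, rep2)
    report.n_input = len(measurements)
    report.check()
    return out.reset_index(drop=True), report
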