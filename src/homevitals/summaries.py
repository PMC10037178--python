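"""Longitudinal physiological summaries.

Per participant: within-subject mean and SD per domain, a hypertension /
hypotension classification from the within-subject blood-pressure means,
and a weight trajectory built from a trailing 5-observation sliding average
with clinically significant change detection (>5% versus a reference
averaged value at least six months earlier).

Cohort level: "grand" summaries — the mean/SD and median/IQR of the
within-subject means, over participants whose domain span exceeds the
eligibility floor (more than 7 days of data by default).  Both summaries
are always reported; a Shapiro-Wilk normality p-value flags which one the
reporting convention (mean/SD for Gaussian, median/IQR otherwise) would
print, so the convention switch is never silent.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import StudyConfig
from .model import CohortDataset, Domain

logger = logging.getLogger(__name__)


class BPClass(str, enum.Enum):
    HYPERTENSIVE = "HYPERTENSIVE"
    HYPOTENSIVE = "HYPOTENSIVE"
    NORMAL = "NORMAL"
    BOTH_FLAGGED = "BOTH_FLAGGED"


@dataclass
class DomainSummary:
    n: int
    mean: float
    sd: float          # NaN when n < 2
    span_days: float
    eligible: bool


@dataclass
class ParticipantPhysioSummary:
    participant_id: str
    domains: dict[Domain, DomainSummary] = field(default_factory=dict)


def summarize_participant(
    stream: pd.DataFrame,
    participant_id: str = "",
    min_days: float = 7.0,
) -> ParticipantPhysioSummary:
    """Within-subject mean/SD per domain on a (preprocessed) stream.

    A domain is eligible for cohort aggregation iff its own observation span
    is strictly greater than ``min_days`` days.
    """
    out = ParticipantPhysioSummary(participant_id=participant_id)
    for dom_name, grp in stream.groupby("domain"):
        values = grp["value"].to_numpy(dtype=float)
        span = (grp["timestamp"].max() - grp["timestamp"].min()).total_seconds() / 86400.0
        out.domains[Domain(dom_name)] = DomainSummary(
            n=len(values),
            mean=float(np.mean(values)),
            sd=float(np.std(values, ddof=1)) if len(values) >= 2 else float("nan"),
            span_days=float(span),
            eligible=bool(span > min_days),
        )
    return out


def classify_bp(summary: ParticipantPhysioSummary, config: StudyConfig | None = None) -> BPClass | None:
    """Classify a participant from within-subject mean SBP and DBP.

    Hypertensive iff mean SBP >= 135 or mean DBP >= 85 (inclusive);
    hypotensive iff mean SBP <= 90 or mean DBP <= 60.  A participant whose
    mixed means satisfy both arms is reported ``BOTH_FLAGGED`` with a
    warning.  Returns ``None`` (logged) when either BP mean is missing.
    """
    config = config or StudyConfig()
    sbp = summary.domains.get(Domain.SBP)
    dbp = summary.domains.get(Domain.DBP)
    if sbp is None or dbp is None:
        logger.info("participant %s: missing BP means, classification skipped", summary.participant_id)
        return None
    hyper = sbp.mean >= config.htn_sbp or dbp.mean >= config.htn_dbp
    hypo = sbp.mean <= config.hotn_sbp or dbp.mean <= config.hotn_dbp
    if hyper and hypo:
        logger.warning("participant %s meets both hyper- and hypotension rules", summary.participant_id)
        return BPClass.BOTH_FLAGGED
    if hyper:
        return BPClass.HYPERTENSIVE
    if hypo:
        return BPClass.HYPOTENSIVE
    return BPClass.NORMAL


@dataclass
class WeightSegment:
    """Window-averaged weight series with flagged clinically significant changes."""

    participant_id: str
    points: pd.DataFrame
    # columns: timestamp, avg_value, ref_timestamp, ref_value, pct_change, flag
    # flag in {"", "LOSS", "GAIN"}

    @property
    def has_loss(self) -> bool:
        return bool((self.points["flag"] == "LOSS").any()) if len(self.points) else False

    @property
    def has_gain(self) -> bool:
        return bool((self.points["flag"] == "GAIN").any()) if len(self.points) else False


def weight_trajectory(
    stream: pd.DataFrame,
    config: StudyConfig | None = None,
    participant_id: str = "",
) -> WeightSegment:
    """Trailing sliding-window weight average with >5%/6-month change flags.

    One averaged point per raw weight from the ``weight_window_n``-th
    observation onward (trailing window: no future data).  Each averaged
    point is compared with the most recent averaged point recorded at least
    ``weight_lookback_days`` earlier; a change strictly greater than
    ``weight_change_pct`` percent in magnitude is flagged LOSS or GAIN.
    Streams shorter than the window, or spanning less than the lookback,
    produce no flags by construction.
    """
    config = config or StudyConfig()
    w = stream[stream["domain"] == Domain.WEIGHT.value].sort_values("timestamp")
    empty = pd.DataFrame(
        columns=["timestamp", "avg_value", "ref_timestamp", "ref_value", "pct_change", "flag"]
    )
    if len(w) < config.weight_window_n:
        logger.info(
            "participant %s: %d weight values < window %d; empty trajectory",
            participant_id, len(w), config.weight_window_n,
        )
        return WeightSegment(participant_id, empty)
    values = w["value"].to_numpy(dtype=float)
    times = w["timestamp"].reset_index(drop=True)
    k = config.weight_window_n
    avg = np.convolve(values, np.ones(k) / k, mode="valid")  # trailing mean
    avg_times = times.iloc[k - 1 :].reset_index(drop=True)
    lookback = pd.Timedelta(days=config.weight_lookback_days)
    rows = []
    for i in range(len(avg)):
        t = avg_times.iloc[i]
        cutoff = t - lookback
        # most recent averaged point at least `lookback` older
        j = int(avg_times.searchsorted(cutoff, side="right")) - 1
        if j < 0:
            rows.append((t, avg[i], pd.NaT, np.nan, np.nan, ""))
            continue
        ref_t, ref_v = avg_times.iloc[j], avg[j]
        pct = (avg[i] - ref_v) / ref_v * 100.0
        flag = ""
        if pct < -config.weight_change_pct:
            flag = "LOSS"
        elif pct > config.weight_change_pct:
            flag = "GAIN"
        rows.append((t, avg[i], ref_t, ref_v, pct, flag))
    points = pd.DataFrame(
        rows, columns=["timestamp", "avg_value", "ref_timestamp", "ref_value", "pct_change", "flag"]
    )
    return WeightSegment(participant_id, points)


def grand_summary(
    summaries: list[ParticipantPhysioSummary],
    min_n_shapiro: int = 3,
) -> pd.DataFrame:
    """Cohort table of within-subject means, one row per domain.

    Reports both mean/SD and median/IQR of the eligible within-subject
    means, plus the Shapiro-Wilk p (NaN when n < 3) and the reporting
    convention it implies.  Quartiles use linear interpolation between
    order statistics.
    """
    rows = []
    for dom in Domain:
        means = np.array(
            [
                s.domains[dom].mean
                for s in summaries
                if dom in s.domains and s.domains[dom].eligible
            ]
        )
        if len(means) == 0:
            continue
        q1, med, q3 = np.percentile(means, [25, 50, 75])
        if len(means) >= min_n_shapiro and np.ptp(means) > 0:
            shapiro_p = float(sps.shapiro(means).pvalue)
        else:
            shapiro_p = float("nan")
        rows.append(
            {
                "domain": dom.value,
                "n_participants": len(means),
                "grand_mean": float(np.mean(means)),
                "grand_sd": float(np.std(means, ddof=1)) if len(means) >= 2 else float("nan"),
                "median": float(med),
                "iqr_low": float(q1),
                "iqr_high": float(q3),
                "shapiro_p": shapiro_p,
                "convention": "mean_sd" if (np.isnan(shapiro_p) or shapiro_p >= 0.05) else "median_iqr",
            }
        )
    return pd.DataFrame(rows)


def summarize_cohort(
    dataset: CohortDataset | pd.DataFrame,
    config: StudyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[ParticipantPhysioSummary]]:
    """Run the longitudinal summaries for every participant.

    Returns (physio_summary, bp_classification, weight_points, summaries):
    long tables suitable for CSV export plus the in-memory summary objects.
    """
    config = config or StudyConfig()
    measurements = dataset.measurements if isinstance(dataset, CohortDataset) else dataset
    physio_rows, bp_rows, weight_frames = [], [], []
    summaries = []
    for pid, stream in measurements.groupby("participant_id"):
        s = summarize_participant(stream, pid, config.min_days_eligible)
        summaries.append(s)
        for dom, ds in s.domains.items():
            physio_rows.append(
                {
                    "participant_id": pid,
                    "domain": dom.value,
                    "n": ds.n,
                    "mean": ds.mean,
                    "sd": ds.sd,
                    "span_days": ds.span_days,
                    "eligible": ds.eligible,
                }
            )
        bp = classify_bp(s, config)
        bp_rows.append({"participant_id": pid, "bp_class": "" if bp is None else bp.value})
        seg = weight_trajectory(stream, config, pid)
        if len(seg.points):
            pts = seg.points.copy()
            pts.insert(0, "participant_id", pid)
            weight_frames.append(pts)
    physio = pd.DataFrame(physio_rows)
    bp_table = pd.DataFrame(bp_rows)
    weight_points = (
        pd.concat(weight_frames, ignore_index=True)
        if weight_frames
        else pd.DataFrame(
            columns=["participant_id", "timestamp", "avg_value", "ref_timestamp", "ref_value", "pct_change", "flag"]
        )
    )
    return physio, bp_table, weight_points, summaries
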