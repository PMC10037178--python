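"""Alert extraction and alert-burden summaries.

Each measurement in a scored domain receives a subscore from the active
:class:`~homevitals.schemes.ScoringScheme`; domains are treated strictly
independently (no cross-domain composite score is ever formed, since
community streams are asynchronous and the full inpatient score cannot be
assembled at home).  An alert is a measurement whose subscore meets a tier
cutoff: tier 1 ("1+", less abnormal) or tier 2 ("2+", more abnormal);
single-tier schemes simply use tier 1.

Alert burden is summarized as alerts per day of observation per participant
(days of observation = elapsed time between first and last measurement),
plus the cohort-level proportion of scored measurements that alert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .model import CohortDataset, Domain
from .schemes import ScoringScheme

ALERT_COLUMNS = [
    "participant_id",
    "domain",
    "value",
    "timestamp",
    "subscore",
    "scheme",
    "tier",
]


def score_measurements(measurements: pd.DataFrame, scheme: ScoringScheme) -> pd.DataFrame:
    """Subscore every measurement in a scored domain.

    Returns the scored-domain rows with an added integer ``subscore`` column;
    rows in unscored domains (DBP, WEIGHT, or domains absent from the
    scheme) are excluded from scoring, never errored, so adding unscored
    measurements can never change the alert set.
    """
    scored = measurements[measurements["domain"].isin([d.value for d in scheme.scored_domains])]
    out = scored.copy()
    sub = np.empty(len(out), dtype=int)
    for dom_name, idx in out.groupby("domain").indices.items():
        band = scheme.bands[Domain(dom_name)]
        sub[idx] = band.subscore_array(out["value"].to_numpy()[idx])
    out["subscore"] = sub
    return out


def score_stream(
    dataset: CohortDataset | pd.DataFrame,
    scheme: ScoringScheme,
    tiers: tuple[int, ...] = (1, 2),
) -> pd.DataFrame:
    """Extract alert events at the given subscore tiers.

    Parameters
    ----------
    dataset : CohortDataset or measurement DataFrame
        Should already be preprocessed (duplicate removal, outlier
        exclusion) — the scorer itself applies no cleaning.
    tiers : tuple of int
        Subscore cutoffs; an event is emitted per (measurement, tier) whose
        subscore >= tier, so the 2+ event set is a subset of the 1+ set.

    Returns
    -------
    pandas.DataFrame
        One row per alert event with columns ``participant_id, domain,
        value, timestamp, subscore, scheme, tier``.
    """
    measurements = dataset.measurements if isinstance(dataset, CohortDataset) else dataset
    scored = score_measurements(measurements, scheme)
    events = []
    for tier in sorted(set(int(t) for t in tiers)):
        if tier < 1:
            raise ValueError("tiers are subscore cutoffs >= 1")
        hit = scored[scored["subscore"] >= tier]
        ev = hit[["participant_id", "domain", "value", "timestamp", "subscore"]].copy()
        ev["scheme"] = scheme.name
        ev["tier"] = tier
        events.append(ev)
    if not events:
        return pd.DataFrame(columns=ALERT_COLUMNS)
    out = pd.concat(events, ignore_index=True)
    return out[ALERT_COLUMNS]


@dataclass
class BurdenSummary:
    """Per-participant and cohort-level alert-burden statistics."""

    scheme: str
    per_participant: pd.DataFrame
    # columns: participant_id, tier, n_scored, n_alerts, days_of_observation,
    #          alerts_per_day
    cohort: pd.DataFrame
    # columns: tier, n_alerts, n_scored, proportion, median_per_day,
    #          iqr_low, iqr_high
    excluded_participants: list[str] = field(default_factory=list)


def burden(
    events: pd.DataFrame,
    scored: pd.DataFrame,
    observation_days: pd.Series,
    scheme_name: str = "",
) -> BurdenSummary:
    """Summarize alert burden per participant-day and cohort-wide.

    Parameters
    ----------
    events : DataFrame
        Alert events from :func:`score_stream`.
    scored : DataFrame
        The scored measurements (denominator for cohort proportions).
    observation_days : Series
        Elapsed days of observation indexed by participant_id; participants
        with zero days are excluded with a warning.
    """
    obs = observation_days.astype(float)
    zero = obs.index[(obs <= 0) | ~np.isfinite(obs)]
    if len(zero):
        warnings.warn(
            f"excluding {len(zero)} participant(s) with zero days of observation from burden rates"
        )
    obs = obs.drop(index=zero)
    tiers = sorted(events["tier"].unique()) if len(events) else [1]
    n_scored_by_pid = scored.groupby("participant_id").size()
    rows = []
    for tier in tiers:
        tier_events = events[events["tier"] == tier] if len(events) else events
        counts = tier_events.groupby("participant_id").size() if len(tier_events) else pd.Series(dtype=int)
        for pid in obs.index:
            n_alerts = int(counts.get(pid, 0))
            rows.append(
                {
                    "participant_id": pid,
                    "tier": tier,
                    "n_scored": int(n_scored_by_pid.get(pid, 0)),
                    "n_alerts": n_alerts,
                    "days_of_observation": float(obs[pid]),
                    "alerts_per_day": n_alerts / float(obs[pid]),
                }
            )
    per_participant = pd.DataFrame(rows)
    cohort_rows = []
    n_scored_total = len(scored)
    for tier in tiers:
        sub = per_participant[per_participant["tier"] == tier]
        n_alerts = int(events[events["tier"] == tier].shape[0]) if len(events) else 0
        rates = sub["alerts_per_day"].to_numpy() if len(sub) else np.array([])
        q1, med, q3 = (
            np.percentile(rates, [25, 50, 75]) if len(rates) else (np.nan, np.nan, np.nan)
        )
        cohort_rows.append(
            {
                "tier": tier,
                "n_alerts": n_alerts,
                "n_scored": n_scored_total,
                "proportion": n_alerts / n_scored_total if n_scored_total else np.nan,
                "median_per_day": med,
                "iqr_low": q1,
                "iqr_high": q3,
            }
        )
    return BurdenSummary(
        scheme=scheme_name,
        per_participant=per_participant,
        cohort=pd.DataFrame(cohort_rows),
        excluded_participants=[str(p) for p in zero],
    )
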