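"""Seeded synthetic cohort generator.

Emulates the statistical structure of a home-monitoring dementia cohort so
that every downstream stage is testable without real data:

* per-participant baselines drawn from between-participant distributions
  whose population means/SDs default to the published cohort summaries
  (HR 69.6 / SD 9.4 bpm; SBP 131.7 / 14.1 and DBP 74.9 / 7.5 mm Hg;
  temperature centred at 36.4 degC; SpO2 at 95.2%; weight at 71.4 kg);
* sporadic adherence: each available device is used independently each day
  with a per-device probability whose default makes the expected fraction
  of days with any measurement about 56%;
* a morning-peaked 24-bin hour-of-day distribution with its mode at
  8-9 AM;
* subtype effects: alpha-synuclein participants get a lower SBP baseline
  and more variable DBP and SpO2;
* a slow random walk for weight (the one domain that genuinely trends);
* right-censoring through a constant daily withdrawal hazard;
* optional injected acute events (fever with tachycardia, bradycardia
  drift, progressive weight loss, a pacemaker-style heart-rate step), each
  recorded in a ground-truth log for detector validation.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so identical configs produce byte-identical cohorts.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    DEVICE_DOMAINS,
    MEASUREMENT_COLUMNS,
    CohortDataset,
    Domain,
    Subtype,
    empty_measurements,
)

_DEVICE_ORDER = tuple(DEVICE_DOMAINS)  # bp_monitor, pulse_oximeter, scales, thermometer


@dataclass(frozen=True)
class DomainModel:
    """Population model for one domain: baseline distribution across
    participants plus day-to-day within-participant noise."""

    mean: float
    between_sd: float
    within_sd: float

    def __post_init__(self) -> None:
        if self.between_sd < 0 or self.within_sd < 0:
            raise ValueError("SDs must be >= 0")


# Population means and between-participant SDs follow the cohort's printed
# grand summaries; within-participant SDs are assumptions chosen to match
# typical day-to-day variability of once-daily home self-measurement.
DEFAULT_BASELINES: dict[Domain, DomainModel] = {
    Domain.HR: DomainModel(69.6, 9.4, 6.0),
    Domain.SBP: DomainModel(131.7, 14.1, 10.0),
    Domain.DBP: DomainModel(74.9, 7.5, 6.0),
    Domain.TEMP: DomainModel(36.4, 0.3, 0.2),
    Domain.SPO2: DomainModel(95.2, 1.5, 1.5),
    Domain.WEIGHT: DomainModel(71.4, 15.8, 0.4),
}

# Values are clipped to physically recordable ranges (device display limits).
_CLIP: dict[Domain, tuple[float, float]] = {
    Domain.HR: (20.0, 250.0),
    Domain.SBP: (50.0, 299.0),
    Domain.DBP: (30.0, 200.0),
    Domain.SPO2: (50.0, 100.0),
    Domain.TEMP: (30.0, 43.0),
    Domain.WEIGHT: (20.0, 350.0),
}

# Age / cognition / sex composition per subtype (baseline-table style).
_DEMOGRAPHICS = {
    Subtype.AD: {"age": (81.5, 7.5), "smmse": (22.8, 4.1), "p_female": 0.49},
    Subtype.VD: {"age": (80.1, 10.2), "smmse": (26.8, 2.9), "p_female": 0.20},
    Subtype.ASYN: {"age": (72.8, 4.8), "smmse": (22.3, 4.7), "p_female": 0.22},
}


def default_hour_weights() -> np.ndarray:
    """Morning-peaked 24-bin hour-of-day distribution, mode at 8-9 AM."""
    w = np.array(
        [
            0.2, 0.2, 0.2, 0.2, 0.2, 0.3,   # 00-05
            1.0, 2.5, 4.0, 3.0, 2.0, 1.8,   # 06-11
            1.5, 1.2, 1.2, 1.2, 1.2, 1.4,   # 12-17
            1.5, 1.5, 1.4, 1.0, 0.6, 0.3,   # 18-23
        ]
    )
    return w / w.sum()


class EventType(str, enum.Enum):
    FEVER_TACHY = "FEVER_TACHY"      # additive temperature + heart-rate rise
    BRADY_DRIFT = "BRADY_DRIFT"      # heart rate ramps down over the window
    WEIGHT_LOSS = "WEIGHT_LOSS"      # progressive % loss per 6 months
    PACING_STEP = "PACING_STEP"      # heart rate pinned to a paced value


DEFAULT_EVENT_MAGNITUDES: dict[EventType, dict[Domain, float]] = {
    EventType.FEVER_TACHY: {Domain.TEMP: 2.0, Domain.HR: 30.0},
    EventType.BRADY_DRIFT: {Domain.HR: -25.0},      # ramp endpoint delta
    EventType.WEIGHT_LOSS: {Domain.WEIGHT: -10.0},  # percent per 182.5 days
    EventType.PACING_STEP: {Domain.HR: 60.0},       # absolute paced rate
}


@dataclass
class EventSpec:
    """Ground-truth description of one injected acute event.

    ``start_day`` is an offset in calendar days from the participant's first
    measurement; the window covers ``duration_days`` days.  ``magnitudes``
    maps affected domains to the event's per-domain parameter, whose
    meaning depends on the type (additive shift, ramp endpoint, percent
    slope per 182.5 days, or absolute set-point).
    """

    participant_id: str
    event_type: EventType
    start_day: int
    duration_days: int
    magnitudes: dict[Domain, float] | None = None

    def resolved_magnitudes(self) -> dict[Domain, float]:
        if self.magnitudes is not None:
            return {Domain(k): float(v) for k, v in self.magnitudes.items()}
        return dict(DEFAULT_EVENT_MAGNITUDES[EventType(self.event_type)])


@dataclass
class RealizedEvent:
    spec: EventSpec
    start_date: pd.Timestamp  # local midnight opening the window
    end_date: pd.Timestamp    # exclusive
    n_rows_affected: int
    deltas: pd.DataFrame      # columns: timestamp, domain, old_value, new_value


@dataclass
class GroundTruthLog:
    events: list[RealizedEvent] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": ev.spec.participant_id,
                "event_type": EventType(ev.spec.event_type).value,
                "start_date": ev.start_date.date().isoformat(),
                "end_date": ev.end_date.date().isoformat(),
                "domains": "|".join(sorted(d.value for d in ev.spec.resolved_magnitudes())),
                "n_rows_affected": ev.n_rows_affected,
            }
            for ev in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "participant_id", "event_type", "start_date", "end_date",
                "domains", "n_rows_affected",
            ],
        )


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n_participants: int = 82
    study_days: int = 365
    subtype_proportions: dict[Subtype, float] = field(
        default_factory=lambda: {Subtype.AD: 68 / 82, Subtype.VD: 5 / 82, Subtype.ASYN: 9 / 82}
    )
    baselines: dict[Domain, DomainModel] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    # Per-device daily use probability.  0.1865 per device makes the chance
    # of at least one measurement on a day 1 - (1 - 0.1865)^4 ~ 0.562.
    device_adherence: dict[str, float] = field(
        default_factory=lambda: {dev: 0.1865 for dev in _DEVICE_ORDER}
    )
    device_available: dict[str, bool] = field(
        default_factory=lambda: {dev: True for dev in _DEVICE_ORDER}
    )
    hour_weights: np.ndarray = field(default_factory=default_hour_weights)
    asyn_sbp_shift: float = -10.0
    asyn_dbp_sd_mult: float = 1.5
    asyn_spo2_sd_mult: float = 1.5
    weight_walk_sd: float = 0.05     # kg/day random-walk step
    withdrawal_hazard: float = 0.0006  # per day
    timezone: str = "Europe/London"
    start_date: str = "2020-01-06"
    events: list[EventSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0 or self.study_days <= 0:
            raise ValueError("n_participants and study_days must be positive")
        total = sum(self.subtype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        for dev, p in self.device_adherence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"adherence probability for {dev} outside [0, 1]")
        if not (0.0 <= self.withdrawal_hazard < 1.0):
            raise ValueError("withdrawal hazard must be in [0, 1)")
        w = np.asarray(self.hour_weights, dtype=float)
        if w.shape != (24,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("hour_weights must be 24 nonnegative weights summing to 1")


def sample_measurement_hour(hour_weights: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an integer hour of day from a normalized 24-bin timing model."""
    w = np.asarray(hour_weights, dtype=float)
    if w.shape != (24,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("timing model must be 24 nonnegative weights summing to 1")
    return int(rng.choice(24, p=w))


def _localize(naive: pd.DatetimeIndex, tz: str) -> pd.DatetimeIndex:
    # ambiguous -> standard time, nonexistent -> shifted forward: both
    # deterministic so seeded cohorts are byte-identical across reruns.
    return naive.tz_localize(tz, ambiguous=False, nonexistent="shift_forward").tz_convert("UTC")


def simulate_cohort(config: SimulationConfig) -> tuple[CohortDataset, GroundTruthLog]:
    """Generate a cohort and the ground-truth log of injected events."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)
    hw = np.asarray(config.hour_weights, dtype=float)

    subtypes = list(config.subtype_proportions)
    props = np.array([config.subtype_proportions[s] for s in subtypes], dtype=float)

    profile_rows = []
    frames: list[pd.DataFrame] = []
    width = len(str(config.n_participants))
    for i in range(config.n_participants):
        pid = f"P{i + 1:0{width}d}"
        subtype = Subtype(subtypes[int(rng.choice(len(subtypes), p=props))])
        demo = _DEMOGRAPHICS[Subtype(subtype)]
        age = float(np.clip(rng.normal(*demo["age"]), 55.0, 100.0))
        smmse = int(np.clip(round(rng.normal(*demo["smmse"])), 0, 30))
        sex = "F" if rng.random() < demo["p_female"] else "M"

        if config.withdrawal_hazard > 0:
            withdraw_day = int(rng.geometric(config.withdrawal_hazard))
        else:
            withdraw_day = config.study_days + 1
        obs_days = min(config.study_days, withdraw_day)
        withdrawn = withdraw_day <= config.study_days

        baseline = {}
        for dom, model in config.baselines.items():
            b = rng.normal(model.mean, model.between_sd)
            if dom is Domain.SBP and subtype is Subtype.ASYN:
                b += config.asyn_sbp_shift
            baseline[dom] = b
        walk = np.cumsum(rng.normal(0.0, config.weight_walk_sd, obs_days))

        for dev in _DEVICE_ORDER:
            if not config.device_available.get(dev, False):
                continue
            p = config.device_adherence.get(dev, 0.0)
            used_days = np.flatnonzero(rng.random(obs_days) < p)
            n = len(used_days)
            if n == 0:
                continue
            hours = rng.choice(24, p=hw, size=n)
            minutes = rng.integers(0, 60, n)
            seconds = rng.integers(0, 60, n)
            naive = pd.DatetimeIndex(
                start
                + pd.to_timedelta(used_days, unit="D")
                + pd.to_timedelta(hours, unit="h")
                + pd.to_timedelta(minutes, unit="m")
                + pd.to_timedelta(seconds, unit="s")
            )
            ts = _localize(naive, config.timezone)
            for dom in DEVICE_DOMAINS[dev]:
                model = config.baselines[dom]
                sd = model.within_sd
                if subtype is Subtype.ASYN:
                    if dom is Domain.DBP:
                        sd *= config.asyn_dbp_sd_mult
                    elif dom is Domain.SPO2:
                        sd *= config.asyn_spo2_sd_mult
                base = baseline[dom] + (walk[used_days] if dom is Domain.WEIGHT else 0.0)
                vals = base + rng.normal(0.0, sd, n)
                lo, hi = _CLIP[dom]
                vals = np.clip(np.round(vals, 1), lo, hi)
                frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "domain": dom.value,
                            "value": vals,
                            "timestamp": ts,
                            "device_id": dev,
                        }
                    )
                )
        profile_rows.append(
            {
                "participant_id": pid,
                "subtype": Subtype(subtype).value,
                "age_years": round(age, 1),
                "sex": sex,
                "smmse": smmse,
                "enrollment_date": start,
                "withdrawal_date": start + pd.Timedelta(days=obs_days) if withdrawn else pd.NaT,
            }
        )

    measurements = (
        pd.concat(frames, ignore_index=True)[MEASUREMENT_COLUMNS]
        if frames
        else empty_measurements()
    )
    profiles = pd.DataFrame(profile_rows)
    profiles["smmse"] = profiles["smmse"].astype("Int64")
    dataset = CohortDataset(
        measurements,
        profiles,
        provenance={
            "source": "homevitals.simulate",
            "seed": config.seed,
            "start_date": config.start_date,
            "timezone": config.timezone,
        },
    ).canonical()

    log = GroundTruthLog()
    for j, spec in enumerate(config.events):
        dataset, realized = inject_event(dataset, spec, seed=config.seed + 1000 + j)
        log.events.append(realized)
    return dataset, log


def inject_event(
    dataset: CohortDataset, spec: EventSpec, seed: int = 0
) -> tuple[CohortDataset, RealizedEvent]:
    """Apply one acute event to a cohort, returning a modified copy.

    Only measurements inside the event's (window x affected domains) are
    altered; every other row is bit-identical to the input.  An event whose
    window misses the participant's measurements entirely yields a warning
    and the unchanged dataset.
    """
    pid = spec.participant_id
    measurements = dataset.measurements
    mine = measurements["participant_id"] == pid
    if not mine.any():
        raise ValueError(f"unknown participant {pid!r}")
    tz = dataset.provenance.get("timezone", "UTC")
    local = measurements.loc[mine, "timestamp"].dt.tz_convert(tz)
    first_date = pd.Timestamp(local.min().date())
    start_date = first_date + pd.Timedelta(days=int(spec.start_day))
    end_date = start_date + pd.Timedelta(days=int(spec.duration_days))
    magnitudes = spec.resolved_magnitudes()

    local_all = measurements["timestamp"].dt.tz_convert(tz).dt.tz_localize(None)
    in_window = (
        mine
        & (local_all >= start_date)
        & (local_all < end_date)
        & measurements["domain"].isin([d.value for d in magnitudes])
    )
    idx = np.flatnonzero(in_window.to_numpy())
    if len(idx) == 0:
        warnings.warn(
            f"event {EventType(spec.event_type).value} for {pid} has no measurements "
            "in its window; dataset unchanged"
        )
        realized = RealizedEvent(spec, start_date, end_date, 0, pd.DataFrame(
            columns=["timestamp", "domain", "old_value", "new_value"]))
        return dataset, realized

    new_measurements = measurements.copy()
    etype = EventType(spec.event_type)
    old = new_measurements["value"].to_numpy(copy=True)
    values = old.copy()
    window_days = float(spec.duration_days)
    days_into = (
        (local_all.iloc[idx] - start_date).dt.total_seconds().to_numpy() / 86400.0
    )
    doms = new_measurements["domain"].iloc[idx].to_numpy()
    for dom, mag in magnitudes.items():
        sel = idx[doms == dom.value]
        if len(sel) == 0:
            continue
        d_in = days_into[doms == dom.value]
        if etype is EventType.FEVER_TACHY:
            values[sel] = values[sel] + mag
        elif etype is EventType.BRADY_DRIFT:
            frac = np.clip((d_in + 1.0) / window_days, 0.0, 1.0)
            values[sel] = values[sel] + frac * mag
        elif etype is EventType.WEIGHT_LOSS:
            values[sel] = values[sel] * (1.0 + (mag / 100.0) * (d_in / 182.5))
        elif etype is EventType.PACING_STEP:
            values[sel] = mag
        lo, hi = _CLIP[dom]
        values[sel] = np.clip(np.round(values[sel], 1), lo, hi)
    new_measurements["value"] = values
    deltas = pd.DataFrame(
        {
            "timestamp": new_measurements["timestamp"].iloc[idx].to_numpy(),
            "domain": doms,
            "old_value": old[idx],
            "new_value": values[idx],
        }
    )
    realized = RealizedEvent(spec, start_date, end_date, len(idx), deltas)
    out = CohortDataset(new_measurements, dataset.profiles.copy(), dict(dataset.provenance))
    return out, realized
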