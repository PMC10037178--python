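"""Study-level configuration.

All analysis thresholds live in :class:`StudyConfig` so that the cleaning
rules (duplicate window, outlier multiplier), the blood-pressure
classification cutoffs and the weight-change detector can be varied for
sensitivity analyses without touching code.  Defaults follow standard
clinical conventions: home hypertension at mean SBP/DBP >= 135/85 mm Hg,
hypotension at <= 90/60 mm Hg, clinically significant weight change at >5%
over at least six months (182.5 days) of a 5-value sliding average.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class StudyConfig:
    """Tunable parameters of the analysis pipeline.

    Parameters
    ----------
    outlier_sd_k : float
        Within-participant outlier cut: values further than ``k`` sample
        standard deviations from that participant's per-domain mean are
        excluded.  Default 4.
    dedup_window_seconds : float
        Repeat measurements recorded within this many seconds of the most
        recent retained measurement (same participant and domain) are
        removed as device retries.  Default 60.
    weight_window_n : int
        Width (in observations) of the trailing sliding-window average
        applied to raw weights.  Default 5.
    weight_change_pct : float
        Percent change in window-averaged weight that is flagged as
        clinically significant.  Default 5 (strictly greater than).
    weight_lookback_days : float
        Minimum age, in days, of the reference averaged weight a current
        value is compared against.  Default 182.5 (six months).
    htn_sbp, htn_dbp : float
        Within-subject mean SBP/DBP at or above which a participant is
        classified hypertensive (either arm suffices).  Defaults 135/85.
    hotn_sbp, hotn_dbp : float
        Mean SBP/DBP at or below which a participant is classified
        hypotensive.  Defaults 90/60.
    min_days_eligible : float
        Domains whose observation span is not strictly greater than this
        many days are excluded from cohort-level physiological summaries.
        Default 7.
    timezone : str
        IANA timezone governing hour-of-day binning and calendar-day
        arithmetic (timestamps themselves are stored in UTC).
    apply_dedup, apply_outlier_filter : bool
        Switches for sensitivity analyses; both cleaning rules are applied
        by default, in the fixed order dedup -> outlier filter.
    """

    outlier_sd_k: float = 4.0
    dedup_window_seconds: float = 60.0
    weight_window_n: int = 5
    weight_change_pct: float = 5.0
    weight_lookback_days: float = 182.5
    htn_sbp: float = 135.0
    htn_dbp: float = 85.0
    hotn_sbp: float = 90.0
    hotn_dbp: float = 60.0
    min_days_eligible: float = 7.0
    timezone: str = "Europe/London"
    apply_dedup: bool = True
    apply_outlier_filter: bool = True

    def __post_init__(self) -> None:
        positive = [
            "outlier_sd_k",
            "weight_window_n",
            "weight_change_pct",
            "weight_lookback_days",
            "htn_sbp",
            "htn_dbp",
            "hotn_sbp",
            "hotn_dbp",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"StudyConfig.{name} must be strictly positive")
        if self.dedup_window_seconds < 0:
            raise ValueError("StudyConfig.dedup_window_seconds must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown StudyConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path
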