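import numpy as np
import pandas as pd
import pytest

from homevitals.model import make_measurements
from homevitals.simulate import SimulationConfig, simulate_cohort

UTC = "UTC"


def ts(spec: str) -> pd.Timestamp:
    """Shorthand for a UTC timestamp."""
    return pd.Timestamp(spec, tz="UTC")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded synthetic cohort reused by read-only tests."""
    dataset, _ = simulate_cohort(SimulationConfig(n_participants=12, study_days=60, seed=7))
    return dataset


@pytest.fixture()
def hr_stream():
    """A simple single-participant heart-rate stream factory."""

    def make(values, start="2021-03-01T08:00:00Z", step_minutes=60 * 24):
        t0 = pd.Timestamp(start)
        return make_measurements(
            [
                ("A", "HR", v, t0 + pd.Timedelta(minutes=step_minutes * i))
                for i, v in enumerate(values)
            ]
        )

    return make


def random_measurements(rng: np.random.Generator, n_rows: int = 200) -> pd.DataFrame:
    """Random (not necessarily physiological) measurement frame for
    property/oracle tests; values stay inside each domain's plausible range."""
    domains = ["HR", "SBP", "DBP", "SPO2", "TEMP", "WEIGHT"]
    lo_hi = {
        "HR": (25, 180), "SBP": (70, 240), "DBP": (40, 130),
        "SPO2": (80, 100), "TEMP": (34.0, 41.0), "WEIGHT": (45, 120),
    }
    recs = []
    t0 = pd.Timestamp("2021-01-01T00:00:00Z")
    pids = [f"R{i}" for i in range(1 + int(rng.integers(1, 6)))]
    for _ in range(n_rows):
        dom = domains[int(rng.integers(len(domains)))]
        lo, hi = lo_hi[dom]
        recs.append(
            (
                pids[int(rng.integers(len(pids)))],
                dom,
                float(np.round(rng.uniform(lo, hi), 1)),
                t0 + pd.Timedelta(seconds=int(rng.integers(0, 90 * 86400))),
            )
        )
    return make_measurements(recs)
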