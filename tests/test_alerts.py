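"""Threshold-band schemes, alert extraction and burden summaries."""

import numpy as np
import pandas as pd
import pytest

from homevitals.alerts import burden, score_stream
from homevitals.model import Domain, make_measurements
from homevitals.schemes import (
    MINDER,
    NEWS2,
    ScoringScheme,
    ThresholdBand,
    UnscoredDomainError,
    load_scheme,
)

T0 = pd.Timestamp("2021-05-01T09:00:00Z")

# Published chart edge cases: (domain, value, expected subscore)
NEWS2_EDGES = [
    ("HR", 40, 3), ("HR", 41, 1), ("HR", 50, 1), ("HR", 51, 0),
    ("HR", 90, 0), ("HR", 91, 1), ("HR", 110, 1), ("HR", 111, 2),
    ("HR", 130, 2), ("HR", 131, 3),
    ("SBP", 90, 3), ("SBP", 91, 2), ("SBP", 100, 2), ("SBP", 101, 1),
    ("SBP", 110, 1), ("SBP", 111, 0), ("SBP", 219, 0), ("SBP", 220, 3),
    ("TEMP", 35.0, 3), ("TEMP", 35.1, 1), ("TEMP", 36.0, 1), ("TEMP", 36.1, 0),
    ("TEMP", 38.0, 0), ("TEMP", 38.1, 1), ("TEMP", 39.0, 1), ("TEMP", 39.1, 2),
    ("SPO2", 91, 3), ("SPO2", 92, 2), ("SPO2", 93, 2), ("SPO2", 94, 1),
    ("SPO2", 95, 1), ("SPO2", 96, 0),
]


class TestSubscore:
    @pytest.mark.parametrize("domain,value,expected", NEWS2_EDGES)
    def test_news2_chart_edges(self, domain, value, expected):
        assert NEWS2.subscore(domain, value) == expected

    def test_mid_normal_values_score_zero(self):
        assert NEWS2.subscore("HR", 70) == 0
        assert NEWS2.subscore("TEMP", 36.8) == 0
        assert NEWS2.subscore("SPO2", 100) == 0

    def test_unscored_domains_error(self):
        for dom in ("DBP", "WEIGHT"):
            with pytest.raises(UnscoredDomainError):
                NEWS2.subscore(dom, 80)

    def test_non_finite_value_error(self):
        with pytest.raises(ValueError):
            NEWS2.subscore("HR", float("nan"))

    @pytest.mark.parametrize("scheme", [NEWS2, MINDER])
    def test_band_totality_on_fine_grid(self, scheme):
        """Every grid value maps to exactly one interval of the explicit
        interval list, and the band lookup agrees with that interval."""
        grids = {
            Domain.HR: np.linspace(1, 299, 100_000),
            Domain.SBP: np.linspace(1, 349, 100_000),
            Domain.TEMP: np.linspace(25.01, 44.99, 100_000),
            Domain.SPO2: np.linspace(0.01, 100, 100_000),
        }
        for dom, band in scheme.bands.items():
            edges = (-np.inf,) + band.upper_edges + (np.inf,)
            grid = grids[dom]
            got = band.subscore_array(grid)
            hits = np.zeros(len(grid), dtype=int)
            expected = np.full(len(grid), -1)
            for i, score in enumerate(band.scores):
                inside = (grid >= edges[i]) & (grid < edges[i + 1])
                hits += inside
                expected[inside] = score
            assert (hits == 1).all()
            assert (got == expected).all()

    def test_band_invariants_enforced(self):
        with pytest.raises(ValueError):
            ThresholdBand(Domain.HR, (50.0, 40.0), (1, 0, 1))
        with pytest.raises(ValueError):
            ThresholdBand(Domain.HR, (50.0,), (1, 2))  # no normal band
        with pytest.raises(UnscoredDomainError):
            ScoringScheme("bad", {Domain.DBP: ThresholdBand(Domain.DBP, (60.0,), (1, 0))})


class TestScoreStream:
    def test_all_normal_stream_has_no_events(self):
        m = make_measurements(
            [("A", "HR", 70, T0), ("A", "SBP", 120, T0), ("A", "TEMP", 36.8, T0), ("A", "SPO2", 98, T0)]
        )
        events = score_stream(m, NEWS2, (1, 2))
        assert len(events) == 0

    def test_single_moderate_fever_is_tier1_only(self):
        m = make_measurements([("A", "TEMP", 38.5, T0)])
        events = score_stream(m, NEWS2, (1, 2))
        assert list(events["tier"]) == [1]
        assert list(events["subscore"]) == [1]

    def test_tier2_subset_of_tier1(self, small_cohort):
        events = score_stream(small_cohort.measurements, NEWS2, (1, 2))
        e1 = events[events["tier"] == 1]
        e2 = events[events["tier"] == 2]
        key = ["participant_id", "domain", "timestamp", "value"]
        merged = e2.merge(e1[key], on=key, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_unscored_domains_never_change_events(self, small_cohort):
        m = small_cohort.measurements
        events_all = score_stream(m, NEWS2)
        events_no_unscored = score_stream(m[~m["domain"].isin(["DBP", "WEIGHT"])], NEWS2)
        pd.testing.assert_frame_equal(
            events_all.reset_index(drop=True), events_no_unscored.reset_index(drop=True)
        )

    def test_matches_per_row_brute_force(self, small_cohort):
        m = small_cohort.measurements
        events = score_stream(m, NEWS2, (1, 2))
        expected = []
        for row in m.itertuples(index=False):
            if row.domain not in ("HR", "SBP", "TEMP", "SPO2"):
                continue
            s = NEWS2.subscore(row.domain, row.value)
            for tier in (1, 2):
                if s >= tier:
                    expected.append((row.participant_id, row.domain, row.value, row.timestamp, s, tier))
        got = sorted(
            zip(events["participant_id"], events["domain"], events["value"],
                events["timestamp"], events["subscore"], events["tier"])
        )
        assert got == sorted(expected)


class TestBurden:
    def test_rate_arithmetic(self):
        events = pd.DataFrame(
            {
                "participant_id": ["A"] * 10,
                "domain": "HR",
                "value": 120.0,
                "timestamp": T0,
                "subscore": 2,
                "scheme": "NEWS2",
                "tier": 1,
            }
        )
        scored = pd.DataFrame({"participant_id": ["A"] * 40})
        obs = pd.Series({"A": 50.0})
        b = burden(events, scored, obs, "NEWS2")
        row = b.per_participant.iloc[0]
        assert row["alerts_per_day"] == pytest.approx(0.2)
        assert b.cohort.iloc[0]["proportion"] == pytest.approx(10 / 40)

    def test_cohort_median_of_rates(self):
        events = pd.concat(
            [
                pd.DataFrame(
                    {
                        "participant_id": [pid] * n,
                        "domain": "HR", "value": 120.0, "timestamp": T0,
                        "subscore": 2, "scheme": "NEWS2", "tier": 1,
                    }
                )
                for pid, n in (("A", 1), ("B", 2), ("C", 3))
            ],
            ignore_index=True,
        )
        scored = pd.DataFrame({"participant_id": ["A", "B", "C"] * 4})
        obs = pd.Series({"A": 10.0, "B": 10.0, "C": 10.0})
        b = burden(events, scored, obs, "NEWS2")
        assert b.cohort.iloc[0]["median_per_day"] == pytest.approx(0.2)

    def test_zero_observation_excluded_with_warning(self):
        events = pd.DataFrame(columns=["participant_id", "domain", "value", "timestamp", "subscore", "scheme", "tier"])
        scored = pd.DataFrame({"participant_id": ["A", "B"]})
        obs = pd.Series({"A": 5.0, "B": 0.0})
        with pytest.warns(UserWarning, match="zero days"):
            b = burden(events, scored, obs, "NEWS2")
        assert b.excluded_participants == ["B"]
        assert set(b.per_participant["participant_id"]) == {"A"}

    def test_known_abnormal_fraction_recovered(self):
        """5% of heart rates pushed beyond the 1+ edge -> cohort proportion
        ~0.05 within a binomial tolerance."""
        rng = np.random.default_rng(2024)
        n = 4000
        abnormal = rng.random(n) < 0.05
        values = np.where(abnormal, 120.0, 70.0)
        m = make_measurements(
            [
                ("A", "HR", v, T0 + pd.Timedelta(minutes=2 * i))
                for i, v in enumerate(values)
            ]
        )
        events = score_stream(m, NEWS2, (1,))
        prop = len(events) / n
        assert prop == pytest.approx(0.05, abs=0.01)


class TestSchemeLoading:
    def test_builtin_names(self):
        assert load_scheme("news2") is NEWS2
        assert load_scheme("minder") is MINDER

    def test_unknown_scheme_errors(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            load_scheme("not-a-scheme")

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "scheme.yaml"
        path.write_text(
            "name: clinic\nbands:\n  HR:\n    - [50, 1]\n    - [110, 0]\n    - [null, 2]\n"
        )
        scheme = load_scheme(path)
        assert scheme.name == "clinic"
        assert scheme.subscore("HR", 45) == 1
        assert scheme.subscore("HR", 70) == 0
        assert scheme.subscore("HR", 115) == 2
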