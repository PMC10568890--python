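"""CRCI: capping, numerator windows, arm summaries, relative differences."""

import math

import numpy as np
import pandas as pd
import pytest

import helpers
from chww_uptake.cohort import build_views
from chww_uptake.crci import (
    arm_summary,
    count_received,
    household_crci,
    household_scores,
    relative_difference,
)
from chww_uptake.simulate import SimConfig, generate_population


class TestHouseholdCrci:
    @pytest.mark.parametrize("eligible,received,expected", [
        (5, 1, 0.2),
        (3, 4, 1.0),   # over-complete ratio capped
        (4, 0, 0.0),
        (1, 1, 1.0),
    ])
    def test_ratio_and_capping(self, eligible, received, expected):
        assert household_crci(eligible, received) == pytest.approx(expected)

    def test_zero_denominator_undefined(self):
        assert household_crci(0, 0) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            household_crci(-1, 0)
        with pytest.raises(ValueError):
            household_crci(3, -2)

    def test_monotone_in_received(self):
        values = [household_crci(6, r) for r in range(0, 10)]
        assert values == sorted(values)
        assert max(values) <= 1.0


class TestCountReceived:
    def events(self, rows):
        frame = pd.DataFrame(rows, columns=["patient_id", "service_code", "event_date"])
        frame["event_date"] = pd.to_datetime(frame["event_date"])
        return frame

    def test_uptake_window_boundaries(self, registry):
        ev = self.events([
            ("A", "covid_booster", "2022-03-15"),   # inside window
            ("B", "covid_booster", "2021-06-30"),   # before intervention start
            ("C", "covid_booster", "2022-05-01"),   # after uptake end
        ])
        got = count_received(pd.DataFrame(), ev, registry)
        assert list(got.patient_id) == ["A"]

    def test_influenza_uses_seasonal_window(self, registry):
        ev = self.events([
            ("A", "influenza", "2022-04-15"),   # within the 3-month lag but out of season
            ("B", "influenza", "2022-03-15"),
            ("C", "influenza", "2021-08-15"),   # pre-season
        ])
        got = count_received(pd.DataFrame(), ev, registry)
        assert list(got.patient_id) == ["B"]

    def test_duplicate_same_service_counts_once(self, registry):
        ev = self.events([
            ("A", "covid2", "2021-08-01"),
            ("A", "covid2", "2021-09-01"),
            ("A", "covid1", "2021-08-01"),
        ])
        got = count_received(pd.DataFrame(), ev, registry)
        assert len(got) == 2

    def test_unknown_service_code_ignored_with_warning(self, registry, caplog):
        ev = self.events([("A", "chiropody", "2021-08-01")])
        with caplog.at_level("WARNING"):
            got = count_received(pd.DataFrame(), ev, registry)
        assert len(got) == 0
        assert "chiropody" in caplog.text


class TestArmSummary:
    def frame(self, values, arm="intervention", category="overall"):
        return pd.DataFrame({
            "household_code": [f"H{i}" for i in range(len(values))],
            "arm": arm, "category": category, "n_eligible": 1, "n_received": 0,
            "crci": values, "capped": False,
        })

    def test_constant_cell(self):
        s = arm_summary(self.frame([0.5] * 10), "intervention", "overall")
        assert s.n_households == 10
        assert s.rounded() == (0.50, 0.00)

    def test_two_extreme_households_sample_sd(self):
        s = arm_summary(self.frame([0.0, 1.0]), "intervention", "overall")
        assert s.mean_crci == pytest.approx(0.5)
        assert s.sd_crci == pytest.approx(math.sqrt(0.5))  # n-1 convention
        assert s.rounded() == (0.50, 0.71)

    def test_undefined_households_excluded(self):
        s = arm_summary(self.frame([0.4, math.nan, 0.6]), "intervention", "overall")
        assert s.n_households == 2
        assert s.mean_crci == pytest.approx(0.5)

    def test_empty_cell_absent(self):
        assert arm_summary(self.frame([]), "control", "overall") is None


class TestRelativeDifference:
    @pytest.mark.parametrize("vi,vc,decimals,expected", [
        (0.21, 0.15, 2, 40),
        (16, 12, 0, 33),
        (35, 12, 0, 192),
        (0.205, 0.146, 2, 40),   # display rounding happens first
    ])
    def test_displayed_mode_reader_arithmetic(self, vi, vc, decimals, expected):
        assert relative_difference(vi, vc, "displayed", decimals) == expected

    def test_raw_mode_identity_and_zero(self):
        assert relative_difference(0.3, 0.3, "raw") == 0
        assert relative_difference(0.21, 0.15, "raw") == pytest.approx(40.0)

    def test_zero_control_undefined(self):
        assert relative_difference(0.2, 0.0, "raw") is None

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(1, 1, "percentish")


class TestHouseholdScores:
    def test_overall_equals_sum_of_categories(self, registry, small_sim, small_views):
        _, (_, events, _) = small_sim
        scores = household_scores(small_views["immunisations"], events, registry)
        wide = scores.pivot(index="household_code", columns="category",
                            values=["n_eligible", "n_received"])
        for col in ("n_eligible", "n_received"):
            total = wide[col]["immunisations"] + wide[col]["screening_hc"]
            assert (total == wide[col]["overall"]).all()

    def test_capped_households_match_oracle_recount(self, registry):
        """Planted missing-eligibility records produce exactly the capped set."""
        high = {code: 0.95 for code in SimConfig().baseline_uptake}
        cfg = SimConfig(n_households=800, baseline_uptake=high,
                        intervention_multiplier=1.0, p_missing_eligibility=0.25,
                        p_deducted=0.0, seed=13)
        patients, events, _ = generate_population(cfg, include_consultations=False)
        views = build_views(patients, registry)
        scores = household_scores(views["immunisations"], events, registry)
        overall = scores[scores.category == "overall"].set_index("household_code")

        # independent recount: brute-force eligibility and raw event tallies
        linked = views["immunisations"].patients
        eligible = {}
        received = {}
        valid_windows = {s.service_code: s.uptake_window for s in registry}
        for _, row in linked.iterrows():
            eligible[row.household_code] = eligible.get(row.household_code, 0) + \
                len(helpers.brute_force_eligible(row.to_dict()))
        hh_of = linked.set_index("patient_id")["household_code"]
        seen = set()
        for _, ev in events.iterrows():
            lo, hi = valid_windows[ev.service_code]
            if not (pd.Timestamp(lo) <= ev.event_date <= pd.Timestamp(hi)):
                continue
            key = (ev.patient_id, ev.service_code)
            if key in seen:
                continue
            seen.add(key)
            h = hh_of[ev.patient_id]
            received[h] = received.get(h, 0) + 1
        oracle_capped = {h for h, r in received.items() if r > eligible.get(h, 0) > 0}
        assert oracle_capped, "the planted corruption should cap some households"
        assert set(overall.index[overall.capped]) == oracle_capped
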