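"""Eligibility rule engine: registry contents, rule semantics, denominators."""

import datetime as dt

import pandas as pd
import pytest

import helpers
from chww_uptake.eligibility import (
    build_registry,
    eligible_matrix,
    household_denominator,
    is_eligible,
    registry_from_frame,
    registry_index,
    registry_to_frame,
)

D = dt.date


def patient(born, sex="male", **kw):
    base = {
        "birth_date": born, "sex": sex, "at_risk_flu": False, "hc_exclusion": False,
        "last_cervical_screen": None, "last_bowel_screen": None,
        "last_breast_screen": None, "last_health_check": None,
    }
    base.update(kw)
    return base


class TestRegistry:
    def test_contains_21_services(self, registry):
        assert len(registry) == 21
        assert len({s.service_code for s in registry}) == 21

    def test_exactly_three_universal_covid_services(self, registry):
        universal = [s.service_code for s in registry if s.eligible_all]
        assert sorted(universal) == ["covid1", "covid2", "covid_booster"]

    def test_exactly_three_female_restricted_services(self, registry):
        female = {s.service_code for s in registry if s.sex_restriction == "female"}
        assert female == {"breast", "cervical_25_49", "cervical_50_64"}

    def test_cervical_50_64_rule_as_printed(self, registry):
        spec = registry_index(registry)["cervical_50_64"]
        assert spec.birth_window == (D(1957, 7, 1), D(1972, 1, 31))
        assert spec.recurrence_cutoff == D(2017, 7, 1)

    def test_influenza_has_seasonal_uptake_window(self, registry):
        spec = registry_index(registry)["influenza"]
        assert spec.uptake_window == (D(2021, 9, 1), D(2022, 3, 31))
        assert spec.at_risk_extension

    def test_roundtrip_through_rules_file(self, registry):
        frame = registry_to_frame(registry)
        assert registry_from_frame(frame) == registry


class TestIsEligible:
    @pytest.mark.parametrize("code,pat,expected", [
        # closed birth windows, boundary-exact
        ("shingles", patient(D(1945, 5, 1)), True),
        ("shingles", patient(D(1942, 6, 30)), False),
        ("shingles", patient(D(1942, 7, 1)), True),
        ("shingles", patient(D(1952, 2, 1)), False),
        # COVID: everyone analysed, including a newborn
        ("covid_booster", patient(D(2021, 9, 1)), True),
        ("covid1", patient(D(1930, 1, 1)), True),
        # recurrence cutoff: screened on/after cutoff removes eligibility
        ("cervical_25_49", patient(D(1980, 1, 1), "female",
                                   last_cervical_screen=D(2020, 2, 1)), False),
        ("cervical_25_49", patient(D(1980, 1, 1), "female",
                                   last_cervical_screen=D(2018, 6, 1)), True),
        ("cervical_25_49", patient(D(1980, 1, 1), "male"), False),
        # "before July 2019" is strictly before the 1st
        ("cervical_25_49", patient(D(1980, 1, 1), "female",
                                   last_cervical_screen=D(2019, 7, 1)), False),
        ("cervical_25_49", patient(D(1980, 1, 1), "female",
                                   last_cervical_screen=D(2019, 6, 30)), True),
        # health check exclusions (e.g. diabetes)
        ("health_check", patient(D(1971, 1, 1), hc_exclusion=True), False),
        ("health_check", patient(D(1971, 1, 1)), True),
        # influenza: child band, elderly band, at-risk any age
        ("influenza", patient(D(2010, 5, 5)), True),
        ("influenza", patient(D(1950, 5, 5)), True),
        ("influenza", patient(D(1985, 5, 5)), False),
        ("influenza", patient(D(1985, 5, 5), at_risk_flu=True), True),
    ])
    def test_printed_rule_examples(self, registry, code, pat, expected):
        assert is_eligible(pat, registry_index(registry)[code]) is expected

    def test_missing_birth_date_rejected(self, registry):
        with pytest.raises(ValueError, match="birth date"):
            is_eligible(patient(None), registry[0])

    def test_pure_function_repeated_calls_agree(self, registry):
        pat = patient(D(1950, 3, 3), "female")
        spec = registry_index(registry)["breast"]
        assert all(is_eligible(pat, spec) == is_eligible(pat, spec) for _ in range(5))

    def test_cervical_bands_mutually_exclusive(self, registry):
        idx = registry_index(registry)
        day = D(1940, 1, 1)
        while day < D(2005, 1, 1):
            pat = patient(day, "female")
            both = (is_eligible(pat, idx["cervical_25_49"])
                    and is_eligible(pat, idx["cervical_50_64"]))
            assert not both, day
            day += dt.timedelta(days=13)


class TestHouseholdDenominator:
    def test_single_72_year_old_man(self, registry):
        # born 1949: shingles + PPV + 3x COVID + influenza (65+), bowel + health check
        members = pd.DataFrame([patient(D(1949, 5, 1), "male")])
        counts = household_denominator(members, registry)
        assert counts["immunisations"] == 6
        assert counts["screening_hc"] == 2
        assert counts["overall"] == 8

    def test_newborn_includes_covid_and_infant_schedule(self, registry):
        members = pd.DataFrame([patient(D(2021, 9, 1))])
        counts = household_denominator(members, registry)
        # covid x3 + dtap_ipv_hib_hepb + pcv1 + rotavirus
        assert counts["immunisations"] == 6
        assert counts["screening_hc"] == 0

    def test_empty_household_is_all_zero(self, registry):
        members = pd.DataFrame(columns=["birth_date", "sex", "at_risk_flu", "hc_exclusion",
                                        "last_cervical_screen", "last_bowel_screen",
                                        "last_breast_screen", "last_health_check"])
        assert household_denominator(members, registry) == {
            "immunisations": 0, "screening_hc": 0, "overall": 0}

    def test_conservation_over_households(self, registry, small_sim):
        """Summing per-household denominators equals patient-wise totals."""
        _, (patients, _, _) = small_sim
        elig = eligible_matrix(patients, registry)
        total_patientwise = int(elig.to_numpy().sum())
        total_households = sum(
            household_denominator(group, registry)["overall"]
            for _, group in patients.groupby("address_key")
        )
        assert total_households == total_patientwise


def test_matrix_matches_bruteforce_oracle(registry, small_sim):
    """Vectorised eligibility agrees with an independent scalar re-application."""
    _, (patients, _, _) = small_sim
    matrix = eligible_matrix(patients, registry)
    for i, row in patients.iterrows():
        expected = helpers.brute_force_eligible(row.to_dict())
        got = set(matrix.columns[matrix.loc[i]])
        assert got == expected, f"patient {row.patient_id}"


def test_matrix_skips_missing_birth_date_with_warning(registry, caplog):
    frame = pd.DataFrame([patient(D(1950, 1, 1)), patient(None)])
    frame["birth_date"] = pd.to_datetime(frame["birth_date"])
    with caplog.at_level("WARNING"):
        matrix = eligible_matrix(frame, registry)
    assert "missing birth date" in caplog.text
    assert matrix.loc[1].sum() == 0 and matrix.loc[0].sum() > 0
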