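"""Household linkage, analysis views, occupancy tables, export reading."""

import datetime as dt

import pandas as pd
import pytest

from chww_uptake.cohort import (
    build_views,
    link_households,
    normalize_address,
    occupancy_table,
    read_export,
)
from chww_uptake.simulate import write_export


def make_patients(rows):
    defaults = {
        "sex": "male", "at_risk_flu": False, "hc_exclusion": False,
        "deducted": False, "deduction_date": pd.NaT, "visited": False,
        "last_cervical_screen": pd.NaT, "last_bowel_screen": pd.NaT,
        "last_breast_screen": pd.NaT, "last_health_check": pd.NaT,
    }
    frame = pd.DataFrame([{**defaults, **r} for r in rows])
    frame["birth_date"] = pd.to_datetime(frame["birth_date"])
    return frame


class TestLinkage:
    def test_case_whitespace_punctuation_normalised(self):
        variants = ["12, Estate Court", "12 ESTATE COURT", "  12  estate   court "]
        assert len({normalize_address(a) for a in variants}) == 1

    def test_same_address_one_household(self):
        patients = make_patients([
            {"patient_id": "A", "address_key": "Flat 1", "birth_date": "1980-01-01"},
            {"patient_id": "B", "address_key": "FLAT 1", "birth_date": "2010-01-01"},
            {"patient_id": "C", "address_key": "Flat 2", "birth_date": "1990-01-01"},
        ])
        households, linked = link_households(patients)
        assert len(households) == 2
        assert linked.set_index("patient_id")["household_code"]["A"] == \
               linked.set_index("patient_id")["household_code"]["B"]

    def test_codes_stable_under_row_order(self, small_sim):
        _, (patients, _, _) = small_sim
        _, linked_a = link_households(patients)
        shuffled = patients.sample(frac=1, random_state=0).reset_index(drop=True)
        _, linked_b = link_households(shuffled)
        a = linked_a.set_index("patient_id")["household_code"]
        b = linked_b.set_index("patient_id")["household_code"]
        assert a.sort_index().equals(b.sort_index())

    def test_single_patient_single_household(self):
        patients = make_patients([
            {"patient_id": "A", "address_key": "Flat 9", "birth_date": "1980-01-01"}])
        households, _ = link_households(patients)
        assert len(households) == 1
        assert households.occupancy.iloc[0] == 1
        assert households.occupancy_bin.iloc[0] == "1"

    def test_blank_address_quarantined(self, caplog):
        patients = make_patients([
            {"patient_id": "A", "address_key": "Flat 1", "birth_date": "1980-01-01"},
            {"patient_id": "B", "address_key": "   ", "birth_date": "1985-01-01"},
        ])
        with caplog.at_level("WARNING"):
            households, linked = link_households(patients)
        assert "blank address" in caplog.text
        assert len(linked) == 1 and len(households) == 1

    def test_arm_from_visited_flag(self):
        patients = make_patients([
            {"patient_id": "A", "address_key": "F1", "birth_date": "1980-01-01",
             "visited": True},
            {"patient_id": "B", "address_key": "F2", "birth_date": "1980-01-01"},
        ])
        households, _ = link_households(patients)
        arms = households.set_index("address_key")["arm"]
        assert arms["F1"] == "intervention" and arms["F2"] == "control"


class TestViews:
    def test_screening_view_drops_ineligible_households(self, registry):
        patients = make_patients([
            # household with a screening-eligible woman
            {"patient_id": "A", "address_key": "F1", "birth_date": "1980-06-01",
             "sex": "female"},
            # household of one toddler: immunisations only
            {"patient_id": "B", "address_key": "F2", "birth_date": "2020-12-01"},
        ])
        views = build_views(patients, registry)
        assert views["immunisations"].n_households == 2
        assert views["screening_hc"].n_households == 1
        assert views["screening_hc"].households.address_key.iloc[0] == "F1"

    def test_screening_view_is_subset(self, registry, small_views):
        overall = set(small_views["immunisations"].households.household_code)
        screening = set(small_views["screening_hc"].households.household_code)
        assert screening <= overall

    def test_sensitivity_differs_only_by_deducted(self, registry, small_sim):
        _, (patients, _, _) = small_sim
        main = build_views(patients, registry, sensitivity=False)
        sens = build_views(patients, registry, sensitivity=True)
        kept = set(sens["immunisations"].patients.patient_id)
        dropped = set(main["immunisations"].patients.patient_id) - kept
        flags = patients.set_index("patient_id")["deducted"]
        assert all(flags[p] for p in dropped)
        assert not any(flags[p] for p in kept)

    def test_all_deducted_gives_empty_views(self, registry):
        patients = make_patients([
            {"patient_id": "A", "address_key": "F1", "birth_date": "1980-01-01",
             "deducted": True}])
        views = build_views(patients, registry, sensitivity=True)
        assert views["immunisations"].n_households == 0
        assert views["screening_hc"].n_households == 0


class TestOccupancyTable:
    def test_bins_partition_household_totals(self, small_views):
        table = occupancy_table(small_views["immunisations"]).set_index("occupancy_bin")
        for arm in ("intervention", "control"):
            assert table.loc["total", arm] == table.drop("total")[arm].sum()
        assert table.loc["total"].sum() == small_views["immunisations"].n_households

    def test_single_household_view(self, registry):
        patients = make_patients([
            {"patient_id": "A", "address_key": "F1", "birth_date": "1980-01-01"}])
        views = build_views(patients, registry)
        table = occupancy_table(views["immunisations"]).set_index("occupancy_bin")
        assert table.loc["1", "control"] == 1
        assert table.loc["total", "control"] == 1


class TestReadExport:
    def test_bad_date_row_rejected_with_diagnostic(self, small_sim, tmp_path, caplog):
        _, tables = small_sim
        write_export(tables, tmp_path)
        path = tmp_path / "service_events.csv"
        lines = path.read_text().splitlines()
        parts = lines[1].split(",")
        lines[1] = ",".join(parts[:-1] + ["not-a-date"])
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING"):
            _, events, _ = read_export(tmp_path)
        assert len(events) == len(tables[1]) - 1
        assert "rejected row 2" in caplog.text

    def test_missing_column_is_schema_error(self, small_sim, tmp_path):
        _, tables = small_sim
        write_export(tables, tmp_path)
        frame = pd.read_csv(tmp_path / "patients.csv")
        frame.drop(columns=["sex"]).to_csv(tmp_path / "patients.csv", index=False)
        with pytest.raises(ValueError, match="sex"):
            read_export(tmp_path)

    def test_missing_file_reported(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_export(tmp_path)
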