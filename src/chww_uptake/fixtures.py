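"""Published summary counts from the Westminster CHWW pilot, as fixtures.

The pilot's patient-level export is not public, but its published summary
tables are fully specified counts: per-service eligible/received tallies by
arm, household occupancy distributions, arm CRCI summaries and the
consultation totals for the difference-in-difference.  These are packaged
as plain-text tables so every downstream statistic can be recomputed
without any data access.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import NamedTuple

import pandas as pd

#: analysis-population totals (patients) per arm
POPULATION_TOTALS = {
    "immunisations": {"intervention": 608, "control": 1643},
    "screening_hc": {"intervention": 178, "control": 483},
}

#: household totals per arm and view
HOUSEHOLD_TOTALS = {
    "immunisations": {"intervention": 160, "control": 502},
    "screening_hc": {"intervention": 120, "control": 304},
}

N_PATIENTS = 2251
N_HOUSEHOLDS = 662
N_SCREENING_EXCLUDED = 238

#: narrative uptake percents quoted only in prose (sensitivity analysis)
SENSITIVITY_HEALTH_CHECK_PERCENTS = {"intervention": 41, "control": 20}


class ArmCounts(NamedTuple):
    eligible: int
    received: int


@dataclass(frozen=True)
class ServiceCounts:
    service_code: str
    label: str
    population: str
    intervention: ArmCounts
    control: ArmCounts
    printed_p_eligibility: str
    printed_p_uptake: str


class BinCounts(NamedTuple):
    bins: dict  # occupancy bin -> household count

    @property
    def total(self) -> int:
        return sum(self.bins.values())


@dataclass(frozen=True)
class OccupancyCounts:
    intervention: BinCounts
    control: BinCounts
    printed_p: dict


class PeriodCell(NamedTuple):
    households: int
    consultations: int


@dataclass(frozen=True)
class PeriodCounts:
    intervention: PeriodCell
    control: PeriodCell


@dataclass(frozen=True)
class Table5:
    before: PeriodCounts
    during: PeriodCounts


@dataclass(frozen=True)
class Table3:
    immunisations: OccupancyCounts
    screening_hc: OccupancyCounts


class PaperFixtures:
    """Structured access to the packaged summary tables.

    ``fx["COVID-19 (2nd dose)"]`` (or ``fx["covid2"]``) returns that
    service's per-arm (eligible, received) counts; ``fx.table3`` /
    ``fx.table4`` / ``fx.table5`` hold the occupancy, CRCI-summary and
    consultation tables.
    """

    def __init__(self, table2: pd.DataFrame, table3: Table3, table4: pd.DataFrame,
                 table5: Table5):
        self.table2 = table2
        self.table3 = table3
        self.table4 = table4
        self.table5 = table5
        self._services: dict[str, ServiceCounts] = {}
        for row in table2.to_dict("records"):
            sc = ServiceCounts(
                service_code=row["service_code"],
                label=row["label"],
                population=row["population"],
                intervention=ArmCounts(int(row["intervention_eligible"]),
                                       int(row["intervention_received"])),
                control=ArmCounts(int(row["control_eligible"]), int(row["control_received"])),
                printed_p_eligibility=str(row["printed_p_eligibility"]),
                printed_p_uptake=str(row["printed_p_uptake"]),
            )
            self._services[sc.service_code] = sc
            self._services[sc.label] = sc

    def __getitem__(self, key: str) -> ServiceCounts:
        return self._services[key]

    def services(self) -> list[ServiceCounts]:
        seen, out = set(), []
        for sc in self._services.values():
            if sc.service_code not in seen:
                seen.add(sc.service_code)
                out.append(sc)
        return out

    def crci_mean(self, analysis: str, category: str, arm: str) -> float:
        t = self.table4
        row = t[(t.analysis == analysis) & (t.category == category) & (t.arm == arm)]
        return float(row.mean_crci.iloc[0])


def _read(name: str) -> pd.DataFrame:
    with resources.files("chww_uptake.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype=str).convert_dtypes()


def load_paper_fixtures() -> PaperFixtures:
    """Load every packaged printed count as structured records."""
    t2 = _read("table2_service_counts.csv")
    for c in ["intervention_eligible", "control_eligible", "intervention_received",
              "control_received"]:
        t2[c] = t2[c].astype(int)

    t3 = _read("table3_occupancy.csv")
    def occ(view: str) -> OccupancyCounts:
        sub = t3[t3.view == view]
        return OccupancyCounts(
            intervention=BinCounts(dict(zip(sub.occupancy_bin, sub.intervention.astype(int)))),
            control=BinCounts(dict(zip(sub.occupancy_bin, sub.control.astype(int)))),
            printed_p=dict(zip(sub.occupancy_bin, sub.printed_p)),
        )
    table3 = Table3(immunisations=occ("immunisations"), screening_hc=occ("screening_hc"))

    t4 = _read("table4_crci.csv")
    t4["mean_crci"] = t4["mean_crci"].astype(float)
    t4["sd_crci"] = t4["sd_crci"].astype(float)

    t5 = _read("table5_consultations.csv")
    for c in ["n_households", "n_patients", "n_consultations"]:
        t5[c] = t5[c].astype(int)
    def cell(period: str, arm: str) -> PeriodCell:
        row = t5[(t5.period == period) & (t5.arm == arm)].iloc[0]
        return PeriodCell(int(row.n_households), int(row.n_consultations))
    table5 = Table5(
        before=PeriodCounts(cell("before", "intervention"), cell("before", "control")),
        during=PeriodCounts(cell("during", "intervention"), cell("during", "control")),
    )
    return PaperFixtures(t2, table3, t4, table5)
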