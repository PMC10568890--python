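"""GP-consultation volumes and the difference-in-difference summary.

The secondary outcome compares unscheduled GP consultation volume in the
ten months before the pilot started (Sep 2020 – Jun 2021) with the first
ten months of the pilot (Jul 2021 – Apr 2022), per arm: totals, per-
household averages, percent changes, and the between-arm difference of
those changes.  Consultations count when delivered by a GP-type clinician
role and not flagged as a scheduled review.

The consultation cohort contains patients actively registered at analysis
time (not deducted); membership is resolved independently per period, so a
household registered only from mid-pilot contributes to the during-period
denominator only.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from ._rounding import round_half_up

#: clinician roles counted for the secondary outcome
INCLUDED_ROLES = frozenset({
    "Locum", "GP Partner", "GP Registrar", "GP Retainer", "GP Sole Practitioner",
    "GP Surgery", "GP Trainee", "GP/HV", "GP CMO", "GP Associate", "GP Assistant",
    "General Medical Practitioner", "Clinical Practitioner Access Role",
})


@dataclass(frozen=True)
class PeriodDefinition:
    label: str
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"period {self.label}: start must precede end")


PERIODS = {
    "before": PeriodDefinition("before", dt.date(2020, 9, 1), dt.date(2021, 6, 30)),
    "during": PeriodDefinition("during", dt.date(2021, 7, 1), dt.date(2022, 4, 30)),
}


@dataclass(frozen=True)
class ConsultationSummary:
    arm: str
    period: str
    n_households: int
    n_consultations: int

    @property
    def avg_per_household(self) -> float | None:
        if self.n_households == 0:
            return None
        return round_half_up(self.n_consultations / self.n_households, 2)


def filter_consultations(records: pd.DataFrame,
                         included_roles=INCLUDED_ROLES,
                         exclude_scheduled: bool = True) -> pd.DataFrame:
    """Keep records with an included clinician role, dropping scheduled reviews."""
    if not included_roles:
        raise ValueError("included_roles must be nonempty")
    keep = records["role_code"].isin(set(included_roles))
    if exclude_scheduled:
        keep &= ~records["scheduled_review"].astype(bool)
    return records[keep].reset_index(drop=True)


def period_cohort(patients: pd.DataFrame, period: PeriodDefinition) -> pd.DataFrame:
    """Patients active in a period: registered (born) by its end, not deducted."""
    active = ~patients["deducted"].astype(bool)
    active &= pd.to_datetime(patients["birth_date"]) <= pd.Timestamp(period.end)
    return patients[active]


def summarise(records: pd.DataFrame, patients: pd.DataFrame,
              period: PeriodDefinition) -> dict[str, ConsultationSummary]:
    """Totals and per-household averages per arm for one period.

    ``records`` should already be role/scheduled-filtered; ``patients``
    must carry ``household_code`` (linked) and the visited flag.
    """
    cohort = period_cohort(patients, period)
    dates = pd.to_datetime(records["date"])
    in_period = (dates >= pd.Timestamp(period.start)) & (dates <= pd.Timestamp(period.end))
    kept = records[in_period & records["patient_id"].isin(set(cohort["patient_id"]))]
    counts = kept["patient_id"].map(
        cohort.set_index("patient_id")["visited"]).map(
        {True: "intervention", False: "control"}).value_counts()
    hh = cohort.groupby("household_code")["visited"].any().map(
        {True: "intervention", False: "control"}).value_counts()
    return {
        arm: ConsultationSummary(arm, period.label,
                                 int(hh.get(arm, 0)), int(counts.get(arm, 0)))
        for arm in ("intervention", "control")
    }


def percent_change(before: float, during: float, convention: str = "raw",
                   ) -> float | None:
    """Percent change from before to during, rounded half-up to 2 dp.

    ``displayed`` first rounds both inputs to 2 dp — the arithmetic on a
    printed per-household average.  None when the baseline is zero.
    """
    if convention not in ("raw", "displayed"):
        raise ValueError(f"unknown convention {convention!r}")
    b, d = float(before), float(during)
    if convention == "displayed":
        b, d = round_half_up(b, 2), round_half_up(d, 2)
    if b == 0:
        return None
    return round_half_up(100.0 * (d - b) / b, 2)


@dataclass(frozen=True)
class DiDReport:
    """Arm-wise percent changes and their difference, totals and averages."""

    complete: bool
    total_change: dict          # arm -> percent change in consultation totals
    avg_change: dict            # arm -> percent change in per-household averages
    did_total: float | None     # intervention minus control, percentage points
    did_avg: float | None


def did_summary(summaries: dict[tuple[str, str], ConsultationSummary]) -> DiDReport:
    """Difference-in-difference over the four (arm, period) cells.

    Totals use raw counts; per-household averages use the displayed (2 dp)
    convention.  An absent or empty cell makes the report incomplete.
    """
    cells = {}
    for arm in ("intervention", "control"):
        for period in ("before", "during"):
            s = summaries.get((arm, period))
            if s is None or s.n_households == 0:
                return DiDReport(False, {}, {}, None, None)
            cells[(arm, period)] = s
    total_change, avg_change = {}, {}
    for arm in ("intervention", "control"):
        b, d = cells[(arm, "before")], cells[(arm, "during")]
        total_change[arm] = percent_change(b.n_consultations, d.n_consultations, "raw")
        avg_change[arm] = percent_change(
            b.n_consultations / b.n_households, d.n_consultations / d.n_households,
            "displayed")
    return DiDReport(
        True, total_change, avg_change,
        round_half_up(total_change["intervention"] - total_change["control"], 2),
        round_half_up(avg_change["intervention"] - avg_change["control"], 2),
    )


def table5_frame(summaries: dict[tuple[str, str], ConsultationSummary]) -> pd.DataFrame:
    """Consultation summary shaped like the published before/during table."""
    did = did_summary(summaries)
    rows = []
    for period in ("before", "during"):
        row = {"period": period}
        for arm in ("intervention", "control"):
            s = summaries[(arm, period)]
            row[f"{arm}_consultations"] = s.n_consultations
            row[f"{arm}_households"] = s.n_households
            row[f"{arm}_avg_per_household"] = s.avg_per_household
        rows.append(row)
    if did.complete:
        rows.append({
            "period": "% change",
            "intervention_consultations": did.total_change["intervention"],
            "control_consultations": did.total_change["control"],
            "intervention_avg_per_household": did.avg_change["intervention"],
            "control_avg_per_household": did.avg_change["control"],
        })
    return pd.DataFrame(rows)


def summaries_from_counts(counts: dict[tuple[str, str], tuple[int, int]],
                          ) -> dict[tuple[str, str], ConsultationSummary]:
    """Build summaries from printed (households, consultations) cells."""
    return {
        (arm, period): ConsultationSummary(arm, period, households, consultations)
        for (arm, period), (households, consultations) in counts.items()
    }
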