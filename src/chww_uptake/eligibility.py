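"""Service-eligibility rule engine.

Decides, for every registered patient and every preventative service offered
during the pilot window (16 immunisations including the three COVID-19 dose
services, four cancer-screening bands and the NHS Health Check), whether the
patient was eligible during the intervention period, and aggregates eligible
person-services into household denominators.

Rules are expressed as closed birth-date windows exactly as a GP audit
states them, plus sex restrictions, recurrence cutoffs ("last screening
before <month year>", read as strictly before the 1st of that month),
clinical exclusion flags (NHS Health Check only) and the influenza at-risk
extension.  Eligibility is a pure function of the patient record and the
service spec.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: raw service categories
IMMUNISATION = "immunisation"
SCREENING = "screening"
HEALTH_CHECK = "health_check"

#: analysis categories used for CRCI denominators/numerators
CAT_IMMUNISATIONS = "immunisations"
CAT_SCREENING_HC = "screening_hc"
CAT_OVERALL = "overall"

#: raw category -> analysis category
ANALYSIS_CATEGORY = {
    IMMUNISATION: CAT_IMMUNISATIONS,
    SCREENING: CAT_SCREENING_HC,
    HEALTH_CHECK: CAT_SCREENING_HC,
}

DateInterval = tuple[dt.date | None, dt.date]


@dataclass(frozen=True)
class StudyWindow:
    """Intervention period plus the three-month uptake lag.

    The pilot ran July 2021 – January 2022; receipts count up to the end of
    April 2022 so households had a realistic window to act on a referral.
    """

    intervention_start: dt.date = dt.date(2021, 7, 1)
    intervention_end: dt.date = dt.date(2022, 1, 31)
    uptake_end: dt.date = dt.date(2022, 4, 30)

    def __post_init__(self) -> None:
        if not (self.intervention_start < self.intervention_end <= self.uptake_end):
            raise ValueError(
                "require intervention_start < intervention_end <= uptake_end, got "
                f"{self.intervention_start}, {self.intervention_end}, {self.uptake_end}"
            )

    @property
    def uptake_window(self) -> tuple[dt.date, dt.date]:
        return (self.intervention_start, self.uptake_end)


#: influenza receipts only count within the vaccination season
FLU_SEASON = (dt.date(2021, 9, 1), dt.date(2022, 3, 31))


@dataclass(frozen=True)
class ServiceSpec:
    """One service's eligibility rule and uptake window.

    ``birth_window`` is a closed interval ``[born_from, born_to]``; a None
    lower bound means open below ("born before ...").  ``eligible_all`` marks
    the three COVID-19 dose services, for which every analysed patient counts
    as eligible.  Influenza carries a second birth window
    (``birth_window_alt``, the 65+ band) and the at-risk extension.
    """

    service_code: str
    label: str
    category: str
    uptake_window: tuple[dt.date, dt.date]
    sex_restriction: str | None = None
    birth_window: DateInterval | None = None
    birth_window_alt: DateInterval | None = None
    eligible_all: bool = False
    recurrence_cutoff: dt.date | None = None
    recurrence_field: str | None = None
    exclusion_flags: frozenset[str] = field(default_factory=frozenset)
    at_risk_extension: bool = False

    def __post_init__(self) -> None:
        if self.category not in ANALYSIS_CATEGORY:
            raise ValueError(f"{self.service_code}: unknown category {self.category!r}")
        if self.eligible_all and self.birth_window is not None:
            raise ValueError(f"{self.service_code}: eligible_all excludes a birth window")
        if not self.eligible_all and self.birth_window is None:
            raise ValueError(f"{self.service_code}: needs a birth window or eligible_all")
        if self.uptake_window[0] > self.uptake_window[1]:
            raise ValueError(f"{self.service_code}: uptake window start after end")
        if (self.recurrence_cutoff is None) != (self.recurrence_field is None):
            raise ValueError(
                f"{self.service_code}: recurrence cutoff and field must come together"
            )

    @property
    def analysis_category(self) -> str:
        return ANALYSIS_CATEGORY[self.category]


def build_registry(window: StudyWindow | None = None) -> tuple[ServiceSpec, ...]:
    """The 21 service rules active during the pilot.

    Birth-date bounds are the audit's printed criteria.  Multi-dose infant
    rows (3rd dose DTaP/IPV/Hib/HepB, 2nd dose rotavirus, numbered MMR/PCV
    doses) use dose-specific service codes, so numerator matching by code
    counts exactly the stated dose.
    """
    window = window or StudyWindow()
    up = window.uptake_window
    d = dt.date

    def imm(code, label, **kw):
        return ServiceSpec(code, label, IMMUNISATION, uptake_window=kw.pop("uptake_window", up), **kw)

    specs = (
        imm("covid1", "COVID-19 (1st dose)", eligible_all=True),
        imm("covid2", "COVID-19 (2nd dose)", eligible_all=True),
        imm("covid_booster", "COVID-19 (booster)", eligible_all=True),
        imm("shingles", "Shingles", birth_window=(d(1942, 7, 1), d(1952, 1, 31))),
        imm(
            "dtap_ipv_hib_hepb",
            "DTaP/IPV/Hib/HepB (3rd dose)",
            birth_window=(d(2021, 3, 1), d(2022, 1, 31)),
        ),
        imm("dtap_ipv", "DTaP/IPV", birth_window=(d(2016, 7, 1), d(2018, 10, 1))),
        imm("hib_menc", "Hib/MenC", birth_window=(d(2018, 3, 1), d(2021, 1, 31))),
        imm("hpv", "HPV", birth_window=(d(2008, 7, 1), d(2010, 1, 31))),
        imm(
            "influenza",
            "Influenza",
            birth_window=(d(2005, 9, 1), d(2020, 3, 31)),
            birth_window_alt=(None, d(1957, 3, 31)),
            at_risk_extension=True,
            uptake_window=FLU_SEASON,
        ),
        imm("menb3", "MenB (3rd dose)", birth_window=(d(2018, 3, 1), d(2021, 1, 31))),
        imm("mmr1", "MMR (1st dose)", birth_window=(d(2016, 6, 30), d(2021, 1, 31))),
        imm("mmr2", "MMR (2nd dose)", birth_window=(d(2016, 6, 30), d(2021, 1, 31))),
        imm("pcv1", "PCV (1st dose)", birth_window=(d(2021, 4, 1), d(2022, 1, 31))),
        imm("pcv2", "PCV (2nd dose)", birth_window=(d(2020, 6, 30), d(2021, 1, 31))),
        imm("ppv", "PPV", birth_window=(None, d(1957, 4, 30))),
        imm("rotavirus", "Rotavirus (2nd dose)", birth_window=(d(2021, 4, 1), d(2022, 1, 31))),
        ServiceSpec(
            "bowel",
            "Bowel cancer screening",
            SCREENING,
            uptake_window=up,
            birth_window=(d(1947, 7, 1), d(1962, 1, 31)),
            recurrence_cutoff=d(2020, 7, 1),
            recurrence_field="last_bowel_screen",
        ),
        ServiceSpec(
            "breast",
            "Breast cancer screening",
            SCREENING,
            uptake_window=up,
            sex_restriction="female",
            birth_window=(d(1950, 7, 1), d(1972, 1, 31)),
            recurrence_cutoff=d(2019, 7, 1),
            recurrence_field="last_breast_screen",
        ),
        ServiceSpec(
            "cervical_25_49",
            "Cervical cancer screening (25-49)",
            SCREENING,
            uptake_window=up,
            sex_restriction="female",
            birth_window=(d(1972, 7, 1), d(1997, 1, 31)),
            recurrence_cutoff=d(2019, 7, 1),
            recurrence_field="last_cervical_screen",
        ),
        ServiceSpec(
            "cervical_50_64",
            "Cervical cancer screening (50-64)",
            SCREENING,
            uptake_window=up,
            sex_restriction="female",
            birth_window=(d(1957, 7, 1), d(1972, 1, 31)),
            recurrence_cutoff=d(2017, 7, 1),
            recurrence_field="last_cervical_screen",
        ),
        ServiceSpec(
            "health_check",
            "NHS Health Check",
            HEALTH_CHECK,
            uptake_window=up,
            birth_window=(d(1947, 7, 1), d(1982, 1, 31)),
            recurrence_cutoff=d(2017, 7, 1),
            recurrence_field="last_health_check",
            exclusion_flags=frozenset({"hc_exclusion"}),
        ),
    )
    assert len(specs) == 21
    return specs


def registry_index(registry) -> dict[str, ServiceSpec]:
    return {s.service_code: s for s in registry}


def _in_window(born: dt.date, window: DateInterval | None) -> bool:
    if window is None:
        return False
    lo, hi = window
    return (lo is None or born >= lo) and born <= hi


def is_eligible(patient, spec: ServiceSpec) -> bool:
    """Eligibility of one patient for one service (pure, scalar).

    ``patient`` is any mapping or object with the patient-record fields
    (``birth_date``, ``sex``, ``at_risk_flu``, ``hc_exclusion`` and the
    ``last_*`` history dates).  Raises ValueError on a missing birth date.
    """
    get = patient.get if hasattr(patient, "get") else lambda k, d=None: getattr(patient, k, d)
    born = _as_date(get("birth_date"))
    if born is None:
        raise ValueError("patient has no birth date")
    if spec.sex_restriction is not None and get("sex") != spec.sex_restriction:
        return False
    age_ok = (
        spec.eligible_all
        or _in_window(born, spec.birth_window)
        or _in_window(born, spec.birth_window_alt)
        or (spec.at_risk_extension and bool(get("at_risk_flu", False)))
    )
    if not age_ok:
        return False
    if spec.recurrence_cutoff is not None:
        last = _as_date(get(spec.recurrence_field))
        if last is not None and last >= spec.recurrence_cutoff:
            return False
    for flag in spec.exclusion_flags:
        if bool(get(flag, False)):
            return False
    return True


def _as_date(v) -> dt.date | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NaT:
        return None
    if isinstance(v, pd.Timestamp):
        return v.date()
    if isinstance(v, dt.datetime):
        return v.date()
    if isinstance(v, dt.date):
        return v
    if isinstance(v, str):
        return dt.date.fromisoformat(v) if v else None
    raise TypeError(f"cannot interpret {v!r} as a date")


def eligible_matrix(patients: pd.DataFrame, registry) -> pd.DataFrame:
    """Boolean patients x services eligibility matrix (vectorised).

    Rows with a missing birth date are skipped (all False) with a logged
    warning, mirroring how a malformed audit row would be handled.
    """
    born = pd.to_datetime(patients["birth_date"])
    missing = born.isna()
    if missing.any():
        logger.warning("skipping %d patient(s) with missing birth date", int(missing.sum()))
    out = {}
    for spec in registry:
        if spec.eligible_all:
            ok = pd.Series(True, index=patients.index)
        else:
            ok = _window_mask(born, spec.birth_window)
            if spec.birth_window_alt is not None:
                ok |= _window_mask(born, spec.birth_window_alt)
            if spec.at_risk_extension:
                ok |= patients["at_risk_flu"].astype(bool)
        if spec.sex_restriction is not None:
            ok &= patients["sex"] == spec.sex_restriction
        if spec.recurrence_cutoff is not None:
            last = pd.to_datetime(patients[spec.recurrence_field])
            ok &= ~(last >= pd.Timestamp(spec.recurrence_cutoff))
        for flag in spec.exclusion_flags:
            ok &= ~patients[flag].astype(bool)
        out[spec.service_code] = ok & ~missing
    return pd.DataFrame(out, index=patients.index)


def _window_mask(born: pd.Series, window: DateInterval | None) -> pd.Series:
    if window is None:
        return pd.Series(False, index=born.index)
    lo, hi = window
    ok = born <= pd.Timestamp(hi)
    if lo is not None:
        ok &= born >= pd.Timestamp(lo)
    return ok.fillna(False)


def household_denominator(patients: pd.DataFrame, registry) -> dict[str, int]:
    """Eligible person-services for one household, per analysis category.

    A member eligible for k services contributes k.  An empty household
    yields zeros.
    """
    counts = {CAT_IMMUNISATIONS: 0, CAT_SCREENING_HC: 0, CAT_OVERALL: 0}
    if len(patients) == 0:
        return counts
    elig = eligible_matrix(patients, registry)
    for spec in registry:
        n = int(elig[spec.service_code].sum())
        counts[spec.analysis_category] += n
        counts[CAT_OVERALL] += n
    return counts


# -- plain-text registry round-trip ---------------------------------------

_REGISTRY_COLUMNS = [
    "service_code", "label", "category", "sex_restriction",
    "born_from", "born_to", "alt_born_from", "alt_born_to",
    "eligible_all", "at_risk_extension",
    "recurrence_cutoff", "recurrence_field", "exclusion_flags",
    "uptake_start", "uptake_end",
]


def registry_to_frame(registry) -> pd.DataFrame:
    """Serialise the active rules to an auditable one-row-per-service table."""
    rows = []
    for s in registry:
        bw = s.birth_window or (None, None)
        aw = s.birth_window_alt or (None, None)
        rows.append({
            "service_code": s.service_code,
            "label": s.label,
            "category": s.category,
            "sex_restriction": s.sex_restriction or "",
            "born_from": bw[0].isoformat() if bw[0] else "",
            "born_to": bw[1].isoformat() if bw[1] else "",
            "alt_born_from": aw[0].isoformat() if aw[0] else "",
            "alt_born_to": aw[1].isoformat() if aw[1] else "",
            "eligible_all": s.eligible_all,
            "at_risk_extension": s.at_risk_extension,
            "recurrence_cutoff": s.recurrence_cutoff.isoformat() if s.recurrence_cutoff else "",
            "recurrence_field": s.recurrence_field or "",
            "exclusion_flags": ";".join(sorted(s.exclusion_flags)),
            "uptake_start": s.uptake_window[0].isoformat(),
            "uptake_end": s.uptake_window[1].isoformat(),
        })
    return pd.DataFrame(rows, columns=_REGISTRY_COLUMNS)


def registry_from_frame(frame: pd.DataFrame) -> tuple[ServiceSpec, ...]:
    def opt_date(v):
        return dt.date.fromisoformat(v) if isinstance(v, str) and v else None

    specs = []
    for row in frame.fillna("").to_dict("records"):
        bw = (opt_date(row["born_from"]), opt_date(row["born_to"]))
        aw = (opt_date(row["alt_born_from"]), opt_date(row["alt_born_to"]))
        specs.append(ServiceSpec(
            service_code=row["service_code"],
            label=row["label"],
            category=row["category"],
            uptake_window=(dt.date.fromisoformat(row["uptake_start"]),
                           dt.date.fromisoformat(row["uptake_end"])),
            sex_restriction=row["sex_restriction"] or None,
            birth_window=None if bw[1] is None else bw,
            birth_window_alt=None if aw[1] is None else aw,
            eligible_all=_as_bool(row["eligible_all"]),
            at_risk_extension=_as_bool(row["at_risk_extension"]),
            recurrence_cutoff=opt_date(row["recurrence_cutoff"]),
            recurrence_field=row["recurrence_field"] or None,
            exclusion_flags=frozenset(f for f in str(row["exclusion_flags"]).split(";") if f),
        ))
    return tuple(specs)


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes"}
    return bool(v)
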