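"""Cohort construction: read the export, link households, carve views.

Households are "everyone living at the same address": addresses are
normalised (case-fold, punctuation stripped, whitespace collapsed) and each
distinct normalised address becomes one household with a stable alphanumeric
code.  The arm is intervention iff any member's visited flag is set.

Views:

* ``immunisations`` — all linked households (everyone is eligible for at
  least the COVID-19 dose services);
* ``screening_hc`` — only households with at least one member eligible for
  a cancer screening or the NHS Health Check, since ineligible households
  cannot contribute to that category's uptake.

The sensitivity variant removes deducted ("ghost") patients before any view
is built; households emptied by the removal are dropped.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .eligibility import SCREENING, HEALTH_CHECK, eligible_matrix
from .simulate import CONSULTATION_COLUMNS, EVENT_COLUMNS, PATIENT_COLUMNS

logger = logging.getLogger(__name__)

OCCUPANCY_BINS = ["1", "2", "3", "4", "5+"]

_PUNCT = re.compile(f"[{re.escape(string.punctuation)}]")
_WS = re.compile(r"\s+")


def normalize_address(address: str) -> str:
    """Canonical household key: case-folded, punctuation-free, single-spaced."""
    s = _PUNCT.sub(" ", str(address).casefold())
    return _WS.sub(" ", s).strip()


@dataclass
class CohortView:
    """A named analysis population: households plus their members."""

    name: str
    households: pd.DataFrame  # household_code, address_key, arm, occupancy, occupancy_bin
    patients: pd.DataFrame    # patient columns + household_code

    @property
    def n_households(self) -> int:
        return len(self.households)


# -- reading the export ----------------------------------------------------

_SCHEMAS = {
    "patients": PATIENT_COLUMNS,
    "service_events": EVENT_COLUMNS,
    "consultations": CONSULTATION_COLUMNS,
}
_BOOL_COLS = {
    "patients": ["at_risk_flu", "hc_exclusion", "deducted", "visited"],
    "service_events": [],
    "consultations": ["scheduled_review"],
}
_DATE_COLS = {
    "patients": ["birth_date", "deduction_date", "last_cervical_screen",
                 "last_bowel_screen", "last_breast_screen", "last_health_check"],
    "service_events": ["event_date"],
    "consultations": ["date"],
}
_REQUIRED_DATES = {"patients": ["birth_date"], "service_events": ["event_date"],
                   "consultations": ["date"]}


def read_export(directory) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read patients/service_events/consultations CSVs into typed tables.

    Raises on a missing file or column; rows whose required dates do not
    parse are rejected with row-numbered warnings.
    """
    directory = Path(directory)
    out = []
    for name, columns in _SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"expected export file {path}")
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = [c for c in columns if c not in frame.columns]
        if missing:
            raise ValueError(f"{path.name}: missing column(s) {missing}")
        frame = frame[columns]
        for col in _BOOL_COLS[name]:
            frame[col] = frame[col].str.strip().str.lower().isin({"true", "1", "yes"})
        for col in _DATE_COLS[name]:
            frame[col] = pd.to_datetime(frame[col].replace("", pd.NaT),
                                        format="%Y-%m-%d", errors="coerce")
        bad = pd.Series(False, index=frame.index)
        for col in _REQUIRED_DATES[name]:
            bad |= frame[col].isna()
        if bad.any():
            for i in frame.index[bad]:
                logger.warning("%s: rejected row %d (unparseable date)", path.name, i + 2)
            frame = frame[~bad].reset_index(drop=True)
        out.append(frame)
    return tuple(out)


# -- household linkage -----------------------------------------------------

def link_households(patients: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group patients into households by normalised address.

    Returns ``(households, patients_linked)``; patients gain a
    ``household_code`` column.  Codes are assigned in sorted normalised-
    address order, so they are stable across runs on identical input.
    Patients with a blank address are quarantined with a warning.
    """
    patients = patients.copy()
    norm = patients["address_key"].map(normalize_address)
    blank = norm == ""
    if blank.any():
        logger.warning("quarantined %d patient(s) with blank address", int(blank.sum()))
        patients = patients[~blank].reset_index(drop=True)
        norm = norm[~blank].reset_index(drop=True)
    codes = {addr: f"H{i:05d}" for i, addr in enumerate(sorted(norm.unique()))}
    patients["household_code"] = norm.map(codes)

    grouped = patients.groupby("household_code", sort=True)
    occ = grouped.size()
    arm = grouped["visited"].any().map({True: "intervention", False: "control"})
    households = pd.DataFrame({
        "household_code": occ.index,
        "address_key": grouped["address_key"].first(),
        "arm": arm,
        "occupancy": occ.to_numpy(),
    }).reset_index(drop=True)
    households["occupancy_bin"] = np.where(
        households["occupancy"] >= 5, "5+", households["occupancy"].astype(str))
    return households, patients


def build_views(patients: pd.DataFrame, registry, sensitivity: bool = False,
                ) -> dict[str, CohortView]:
    """Build the immunisations and screening_hc analysis views.

    ``sensitivity=True`` removes deducted patients before linkage, dropping
    households emptied thereby.
    """
    if sensitivity:
        patients = patients[~patients["deducted"].astype(bool)].reset_index(drop=True)
    households, linked = link_households(patients)

    views = {"immunisations": CohortView("immunisations", households, linked)}

    elig = eligible_matrix(linked, registry)
    scr_codes = [s.service_code for s in registry if s.category in (SCREENING, HEALTH_CHECK)]
    has_scr = elig[scr_codes].any(axis=1)
    keep_households = set(linked.loc[has_scr, "household_code"])
    scr_patients = linked[linked["household_code"].isin(keep_households)].reset_index(drop=True)
    scr_households = households[households["household_code"].isin(keep_households)]
    views["screening_hc"] = CohortView(
        "screening_hc", scr_households.reset_index(drop=True), scr_patients)
    return views


def occupancy_table(view: CohortView) -> pd.DataFrame:
    """Per-arm household counts by occupancy bin, with totals."""
    counts = (view.households
              .groupby(["occupancy_bin", "arm"]).size().unstack(fill_value=0)
              .reindex(index=OCCUPANCY_BINS, fill_value=0)
              .reindex(columns=["intervention", "control"], fill_value=0))
    counts.loc["total"] = counts.sum()
    counts.index.name = "occupancy_bin"
    return counts.reset_index()
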