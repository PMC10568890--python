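"""Composite Referral Completion Indicator (CRCI).

Per household, the CRCI is the proportion of preventative services its
members received out of those they were eligible for during the
intervention period:

    CRCI_h = min(1, received_h / eligible_h)

The denominator sums eligible person-services (a member eligible for k
services contributes k).  The numerator counts distinct in-window service
receipts by members of the household — duplicates of the same service for
the same patient count once, influenza counts only within its seasonal
window, and receipts are matched to the rule registry by service code, not
gated on computed eligibility: missing eligibility evidence in a real audit
is exactly what makes raw ratios exceed 1, which the indicator caps.

Households with no eligible service in a category are excluded from that
category's summary (the ratio is undefined).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rounding import round_half_up
from .cohort import CohortView
from .eligibility import (
    ANALYSIS_CATEGORY,
    CAT_IMMUNISATIONS,
    CAT_OVERALL,
    CAT_SCREENING_HC,
    eligible_matrix,
    registry_index,
)

logger = logging.getLogger(__name__)

CATEGORIES = [CAT_IMMUNISATIONS, CAT_SCREENING_HC, CAT_OVERALL]


def household_crci(n_eligible: int, n_received: int) -> float | None:
    """Capped completion ratio; None when the denominator is zero."""
    if n_eligible < 0 or n_received < 0:
        raise ValueError(f"counts must be non-negative, got ({n_eligible}, {n_received})")
    if n_eligible == 0:
        return None
    return min(1.0, n_received / n_eligible)


def count_received(patients: pd.DataFrame, events: pd.DataFrame, registry,
                   ) -> pd.DataFrame:
    """Distinct in-window receipts per patient and service.

    Keeps one row per (patient, service) whose event date lies inside that
    service's uptake window; events with unknown service codes are logged
    and ignored.  When ``patients`` carries a ``patient_id`` column, only
    that population's events count.
    """
    index = registry_index(registry)
    if "patient_id" in patients.columns:
        events = events[events["patient_id"].isin(set(patients["patient_id"]))]
    if len(events) == 0:
        return events.iloc[0:0][["patient_id", "service_code"]].copy()
    unknown = ~events["service_code"].isin(index)
    if unknown.any():
        for code in events.loc[unknown, "service_code"].unique():
            logger.warning("ignoring events with unknown service code %r", code)
        events = events[~unknown]
    starts = events["service_code"].map({c: pd.Timestamp(s.uptake_window[0])
                                         for c, s in index.items()})
    ends = events["service_code"].map({c: pd.Timestamp(s.uptake_window[1])
                                       for c, s in index.items()})
    dates = pd.to_datetime(events["event_date"])
    in_window = (dates >= starts) & (dates <= ends)
    kept = events[in_window]
    return kept.drop_duplicates(["patient_id", "service_code"])[["patient_id", "service_code"]]


def household_scores(view: CohortView, events: pd.DataFrame, registry) -> pd.DataFrame:
    """Per-household eligible/received tallies and CRCI for each category.

    Returns one row per (household, category) with columns
    ``household_code, arm, category, n_eligible, n_received, crci, capped``;
    ``crci`` is NaN where the household has no eligible service in the
    category.
    """
    patients = view.patients
    index = registry_index(registry)
    cat_of = {c: s.analysis_category for c, s in index.items()}

    elig = eligible_matrix(patients, registry)
    elig_long = pd.DataFrame({
        "household_code": np.repeat(patients["household_code"].to_numpy(), len(index)),
        "category": np.tile([cat_of[c] for c in elig.columns], len(patients)),
        "eligible": elig.to_numpy().ravel().astype(int),
    })
    denom = (elig_long.groupby(["household_code", "category"])["eligible"].sum()
             .unstack(fill_value=0))

    received = count_received(patients, events, registry)
    received = received[received["patient_id"].isin(set(patients["patient_id"]))]
    if len(received):
        rec = received.merge(patients[["patient_id", "household_code"]], on="patient_id")
        rec["category"] = rec["service_code"].map(cat_of)
        numer = (rec.groupby(["household_code", "category"]).size().unstack(fill_value=0))
    else:
        numer = pd.DataFrame()

    hh = view.households[["household_code", "arm"]]
    frames = []
    cells = {}
    for cat in (CAT_IMMUNISATIONS, CAT_SCREENING_HC):
        e = (denom[cat] if cat in denom else pd.Series(dtype=int)).reindex(
            hh["household_code"], fill_value=0).to_numpy()
        r = (numer[cat] if cat in numer else pd.Series(dtype=int)).reindex(
            hh["household_code"], fill_value=0).to_numpy()
        cells[cat] = (e, r)
    cells[CAT_OVERALL] = (cells[CAT_IMMUNISATIONS][0] + cells[CAT_SCREENING_HC][0],
                          cells[CAT_IMMUNISATIONS][1] + cells[CAT_SCREENING_HC][1])
    for cat, (e, r) in cells.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            crci = np.minimum(1.0, r / e)
        frames.append(pd.DataFrame({
            "household_code": hh["household_code"].to_numpy(),
            "arm": hh["arm"].to_numpy(),
            "category": cat,
            "n_eligible": e.astype(int),
            "n_received": r.astype(int),
            "crci": np.where(e > 0, crci, math.nan),
            "capped": (e > 0) & (r > e),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ArmSummary:
    arm: str
    category: str
    n_households: int
    mean_crci: float
    sd_crci: float

    def rounded(self, decimals: int = 2) -> tuple[float, float]:
        return (round_half_up(self.mean_crci, decimals), round_half_up(self.sd_crci, decimals))


def arm_summary(scores: pd.DataFrame, arm: str, category: str) -> ArmSummary | None:
    """Mean and sample SD of defined household CRCIs in one arm x category cell.

    Returns None for an empty cell.  SD uses the n-1 denominator (the usual
    statistical-package convention); a single household reports SD 0.
    """
    cell = scores[(scores["arm"] == arm) & (scores["category"] == category)]
    vals = cell["crci"].dropna()
    if len(vals) == 0:
        return None
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return ArmSummary(arm, category, int(len(vals)), float(vals.mean()), sd)


def table4_summary(views: dict, events: pd.DataFrame, registry) -> pd.DataFrame:
    """Arm x category CRCI summary table (the per-pilot headline table).

    Immunisations and overall are computed on the full household set;
    screening + Health Check on the screening-eligible household subset.
    """
    score_imm = household_scores(views["immunisations"], events, registry)
    score_scr = household_scores(views["screening_hc"], events, registry)
    rows = []
    for category, scores in ((CAT_IMMUNISATIONS, score_imm),
                             (CAT_SCREENING_HC, score_scr),
                             (CAT_OVERALL, score_imm)):
        for arm in ("intervention", "control"):
            s = arm_summary(scores, arm, category)
            if s is None:
                continue
            mean, sd = s.rounded()
            rows.append({"category": category, "arm": arm, "n_households": s.n_households,
                         "mean_crci": mean, "sd_crci": sd,
                         "mean_crci_raw": s.mean_crci, "sd_crci_raw": s.sd_crci})
    return pd.DataFrame(rows)


def relative_difference(value_intervention: float, value_control: float,
                        mode: str = "raw", decimals: int = 2) -> float | None:
    """Percent excess of the intervention value over control.

    ``displayed`` mode first rounds both inputs half-up to ``decimals``
    places (2 for CRCI proportions, 0 for integer percents) and rounds the
    result to the nearest integer percent — the arithmetic a reader performs
    on a printed table.  Returns None when the control value is zero.
    """
    if mode not in ("raw", "displayed"):
        raise ValueError(f"unknown mode {mode!r}")
    vi, vc = float(value_intervention), float(value_control)
    if mode == "displayed":
        vi = round_half_up(vi, decimals)
        vc = round_half_up(vc, decimals)
    if vc == 0:
        return None
    out = 100.0 * (vi - vc) / vc
    return round_half_up(out, 0) if mode == "displayed" else out
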