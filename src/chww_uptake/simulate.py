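"""Synthetic pseudonymised GP-export generator.

Emulates the audit export a GP system produces for a household-outreach
pilot: a patient register (birth dates, sex, clinical flags, household
address, intervention-arm flag, screening history), dated service-receipt
events, and consultation records — with the statistical structure the
analysis assumes:

* households drawn from a configurable occupancy distribution
  (defaults match the pilot's combined occupancy table, mean ~3.4);
* per-service uptake probabilities with a relative-risk multiplier in
  visited (intervention) households;
* within-household correlation of uptake induced by a shared per-household
  beta-distributed uptake probability, whose intra-class correlation equals
  the configured ICC (beta-Bernoulli mixture);
* gamma-Poisson (negative binomial) consultation counts per person-period,
  with a multiplicative during-period effect in the intervention arm;
* "ghost patients": deducted patients keep their record but accrue no
  events after a deduction date drawn uniformly in the calendar range;
* optional missing-eligibility corruption that keeps a receipt event while
  rewriting the patient's screening history so they appear ineligible —
  the mechanism behind raw household ratios exceeding 1.

All randomness flows from one root ``numpy.random.default_rng(seed)``
generator; draws occur in a fixed order, so one seed fixes the export
byte-for-byte.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .eligibility import (
    SCREENING,
    HEALTH_CHECK,
    StudyWindow,
    build_registry,
    eligible_matrix,
)

CALENDAR_START = pd.Timestamp("2020-09-01")
CALENDAR_END = pd.Timestamp("2022-04-30")
REF_DATE = pd.Timestamp("2021-07-01")  # age reference: intervention start

PATIENT_COLUMNS = [
    "patient_id", "address_key", "birth_date", "sex", "at_risk_flu",
    "hc_exclusion", "deducted", "deduction_date", "visited",
    "last_cervical_screen", "last_bowel_screen", "last_breast_screen",
    "last_health_check",
]
EVENT_COLUMNS = ["patient_id", "service_code", "event_date"]
CONSULTATION_COLUMNS = ["patient_id", "date", "role_code", "scheduled_review"]

#: clinician roles whose consultations count for the secondary outcome
GP_ROLES = ["GP Partner", "Locum", "GP Registrar", "General Medical Practitioner", "GP Trainee"]
#: an excluded role present in real exports
NON_GP_ROLE = "Practice Nurse"

#: control-arm per-service uptake probabilities (within the uptake window)
DEFAULT_BASELINE_UPTAKE = {
    "covid1": 0.06, "covid2": 0.12, "covid_booster": 0.23, "shingles": 0.06,
    "dtap_ipv_hib_hepb": 0.02, "dtap_ipv": 0.17, "hib_menc": 0.11, "hpv": 0.02,
    "influenza": 0.15, "menb3": 0.11, "mmr1": 0.07, "mmr2": 0.01,
    "pcv1": 0.71, "pcv2": 0.60, "ppv": 0.01, "rotavirus": 0.71,
    "bowel": 0.33, "breast": 0.01, "cervical_25_49": 0.09,
    "cervical_50_64": 0.10, "health_check": 0.12,
}

#: occupancy distribution over {1,2,3,4,5+}: pooled pilot households
DEFAULT_OCCUPANCY_PROBS = (164 / 662, 141 / 662, 92 / 662, 86 / 662, 179 / 662)


class AgeSexModel(BaseModel):
    """Demographic mixture for birth dates, sex and clinical flags.

    ``age_bands`` are (lo, hi, weight) in years at the intervention start;
    a negative lower bound lets babies be born during the intervention
    period.  Band weights approximate the eligible fractions of an inner-
    city estate register (≈15% aged 65+, ~5% under five).
    """

    age_bands: list[tuple[float, float, float]] = [
        (-0.58, 0.0, 0.010),   # born during the pilot
        (0.0, 2.0, 0.015),
        (2.0, 5.0, 0.030),
        (5.0, 12.0, 0.070),
        (12.0, 17.0, 0.050),
        (17.0, 40.0, 0.420),
        (40.0, 60.0, 0.210),
        (60.0, 65.0, 0.045),
        (65.0, 80.0, 0.110),
        (80.0, 95.0, 0.040),
    ]
    p_female: float = Field(0.5, ge=0, le=1)
    p_at_risk_flu: float = Field(0.08, ge=0, le=1)
    p_hc_exclusion: float = Field(0.35, ge=0, le=1)
    #: screening/health-check history: recent (post-cutoff, removes
    #: eligibility) vs old (pre-cutoff) prior events
    p_recent_screen: float = Field(0.45, ge=0, le=1)
    p_old_screen: float = Field(0.30, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self):
        w = [b[2] for b in self.age_bands]
        if any(x < 0 for x in w) or sum(w) <= 0:
            raise ValueError("age_bands: weights must be non-negative with positive sum")
        if any(b[0] >= b[1] for b in self.age_bands):
            raise ValueError("age_bands: each band needs lo < hi")
        if self.p_recent_screen + self.p_old_screen > 1:
            raise ValueError("p_recent_screen + p_old_screen must not exceed 1")
        return self


class SimConfig(BaseModel):
    """Generator configuration; defaults are the pilot's study conditions."""

    n_households: int = Field(662, gt=0)
    occupancy_probs: tuple[float, float, float, float, float] = DEFAULT_OCCUPANCY_PROBS
    occupancy_tail_mean: float = Field(1.62, ge=0)  # extra members beyond 5 in the 5+ bin
    age_sex_model: AgeSexModel = AgeSexModel()
    p_visited: float = Field(160 / 662, ge=0, le=1)
    baseline_uptake: dict[str, float] = DEFAULT_BASELINE_UPTAKE
    intervention_multiplier: float = Field(1.4, gt=0)
    icc: float = Field(0.05, ge=0, lt=1)
    consult_rate: float = Field(4.3, ge=0)       # included consultations / person / 10 months
    consult_dispersion: float = Field(0.8, gt=0)  # gamma shape; variance of frailty = 1/shape
    arm_period_effect: float = Field(0.95, gt=0)  # intervention x during multiplier
    p_excluded_consultation: float = Field(0.3, ge=0)  # extra nurse/scheduled records, x consult_rate
    p_deducted: float = Field(0.05, ge=0, le=1)
    p_missing_eligibility: float = Field(0.0, ge=0, le=1)
    seed: int = 0

    @field_validator("occupancy_probs")
    @classmethod
    def _probs_sum(cls, v):
        if any(p < 0 or p > 1 for p in v):
            raise ValueError("occupancy_probs: entries must lie in [0,1]")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"occupancy_probs: must sum to 1, got {sum(v)!r}")
        return v

    @field_validator("baseline_uptake")
    @classmethod
    def _uptake_range(cls, v):
        for code, p in v.items():
            if not 0 <= p <= 1:
                raise ValueError(f"baseline_uptake[{code}]: probability {p} outside [0,1]")
        return v


def generate_population(
    config: SimConfig,
    include_consultations: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw (patients, service_events, consultations) for one simulated pilot.

    Identical config and seed give byte-identical tables.  Uptake events are
    drawn only for (patient, service) pairs eligible under the rule registry,
    so with ``p_missing_eligibility = 0`` no household's raw received/eligible
    ratio can exceed 1.
    """
    rng = np.random.default_rng(config.seed)
    registry = build_registry(StudyWindow())
    asm = config.age_sex_model

    # households ----------------------------------------------------------
    n_h = config.n_households
    bins = rng.choice(5, size=n_h, p=np.asarray(config.occupancy_probs))
    sizes = bins + 1
    tail = bins == 4
    sizes = sizes + np.where(tail, rng.poisson(config.occupancy_tail_mean, size=n_h), 0)
    visited_h = rng.random(n_h) < config.p_visited

    hh = np.repeat(np.arange(n_h), sizes)
    n = hh.size

    # demographics --------------------------------------------------------
    bands = asm.age_bands
    w = np.array([b[2] for b in bands], dtype=float)
    bi = rng.choice(len(bands), size=n, p=w / w.sum())
    lo = np.array([b[0] for b in bands])[bi]
    hi = np.array([b[1] for b in bands])[bi]
    age_years = lo + rng.random(n) * (hi - lo)
    birth = (REF_DATE - pd.to_timedelta(np.round(age_years * 365.25), unit="D")).normalize()
    birth = birth.where(birth <= pd.Timestamp("2022-01-31"), pd.Timestamp("2022-01-31"))

    sex = np.where(rng.random(n) < asm.p_female, "female", "male")
    at_risk_flu = rng.random(n) < asm.p_at_risk_flu
    hc_exclusion = rng.random(n) < asm.p_hc_exclusion
    deducted = rng.random(n) < config.p_deducted
    span_days = (CALENDAR_END - CALENDAR_START).days
    ded_date = CALENDAR_START + pd.to_timedelta(
        np.floor(rng.random(n) * (span_days + 1)), unit="D")
    deduction_date = pd.DatetimeIndex(np.where(deducted, ded_date, np.datetime64("NaT")))

    patients = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "address_key": [f"Flat {h + 1}, Estate Court" for h in hh],
        "birth_date": birth,
        "sex": sex,
        "at_risk_flu": at_risk_flu,
        "hc_exclusion": hc_exclusion,
        "deducted": deducted,
        "deduction_date": deduction_date,
        "visited": visited_h[hh],
        "last_cervical_screen": pd.NaT,
        "last_bowel_screen": pd.NaT,
        "last_breast_screen": pd.NaT,
        "last_health_check": pd.NaT,
    })

    # screening / health-check history (pre-study last-event dates) -------
    for spec in registry:
        if spec.recurrence_cutoff is None:
            continue
        mask = _history_candidates(patients, spec)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            # keep the draw order stable regardless of candidate count
            continue
        u = rng.random(idx.size)
        cutoff = pd.Timestamp(spec.recurrence_cutoff)
        recent = u < asm.p_recent_screen
        old = (u >= asm.p_recent_screen) & (u < asm.p_recent_screen + asm.p_old_screen)
        dates = rng.random(idx.size)
        col = patients.columns.get_loc(spec.recurrence_field)
        recent_span = max((pd.Timestamp("2021-06-30") - cutoff).days, 1)
        vals = patients[spec.recurrence_field].to_numpy(copy=True)
        vals[idx[recent]] = (cutoff + pd.to_timedelta(
            np.floor(dates[recent] * recent_span), unit="D")).to_numpy()
        vals[idx[old]] = (cutoff - pd.to_timedelta(
            1 + np.floor(dates[old] * (3 * 365 - 1)), unit="D")).to_numpy()
        patients.isetitem(col, pd.DatetimeIndex(vals))

    # uptake events -------------------------------------------------------
    elig = eligible_matrix(patients, registry)
    events = []
    for spec in registry:
        p0 = config.baseline_uptake.get(spec.service_code, 0.0)
        p_arm = np.where(visited_h, np.minimum(p0 * config.intervention_multiplier, 1.0), p0)
        if config.icc > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                a = p_arm * (1 - config.icc) / config.icc
                b = (1 - p_arm) * (1 - config.icc) / config.icc
            pi = np.where((p_arm > 0) & (p_arm < 1), rng.beta(np.maximum(a, 1e-12),
                                                              np.maximum(b, 1e-12)), p_arm)
        else:
            rng.beta(1.0, 1.0, size=n_h)  # burn a draw: stream layout independent of icc
            pi = p_arm
        take = (rng.random(n) < pi[hh]) & elig[spec.service_code].to_numpy()
        u = rng.random(n)
        if not take.any():
            continue
        w_start = pd.Timestamp(spec.uptake_window[0])
        w_end = pd.Timestamp(spec.uptake_window[1])
        bd = birth[take] + pd.Timedelta(days=1)
        lo_dates = pd.DatetimeIndex(bd.where(bd >= w_start, w_start))
        span = (w_end - lo_dates).days.to_numpy()
        offs = np.floor(u[take] * (span + 1)).astype(int)
        when = pd.DatetimeIndex(lo_dates) + pd.to_timedelta(offs, unit="D")
        events.append(pd.DataFrame({
            "patient_id": patients.loc[take, "patient_id"].to_numpy(),
            "service_code": spec.service_code,
            "event_date": when,
        }))
    if events:
        events = pd.concat(events, ignore_index=True)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
        events["event_date"] = pd.to_datetime(events["event_date"])

    # ghost patients: no events on/after deduction
    if len(events):
        ded = patients.set_index("patient_id")["deduction_date"]
        cut = events["patient_id"].map(ded)
        events = events[~(cut.notna() & (events["event_date"] >= cut))].reset_index(drop=True)

    # missing-eligibility corruption --------------------------------------
    if config.p_missing_eligibility > 0 and len(events):
        recur = {s.service_code: s for s in registry if s.recurrence_cutoff is not None}
        cand = events["service_code"].isin(recur).to_numpy()
        hit = cand & (rng.random(len(events)) < config.p_missing_eligibility)
        pid_pos = {p: i for i, p in enumerate(patients["patient_id"])}
        for _, ev in events[hit].iterrows():
            spec = recur[ev.service_code]
            cutoff = pd.Timestamp(spec.recurrence_cutoff)
            recent_span = max((pd.Timestamp("2021-06-30") - cutoff).days, 1)
            when = cutoff + pd.Timedelta(days=float(np.floor(rng.random() * recent_span)))
            patients.loc[pid_pos[ev.patient_id], spec.recurrence_field] = when

    events = events.sort_values(EVENT_COLUMNS, kind="mergesort").reset_index(drop=True)

    # consultations -------------------------------------------------------
    if include_consultations:
        consultations = _draw_consultations(rng, config, patients, visited_h[hh])
    else:
        consultations = pd.DataFrame(columns=CONSULTATION_COLUMNS)
        consultations["date"] = pd.to_datetime(consultations["date"])
        consultations["scheduled_review"] = consultations["scheduled_review"].astype(bool)

    return patients, events, consultations


def _history_candidates(patients: pd.DataFrame, spec) -> pd.Series:
    born = patients["birth_date"]
    lo, hi = spec.birth_window
    ok = born <= pd.Timestamp(hi)
    if lo is not None:
        ok &= born >= pd.Timestamp(lo)
    if spec.sex_restriction is not None:
        ok &= patients["sex"] == spec.sex_restriction
    return ok


def _draw_consultations(rng, config: SimConfig, patients: pd.DataFrame,
                        visited: np.ndarray) -> pd.DataFrame:
    from .consultations import PERIODS  # period definitions live with the DiD module

    n = len(patients)
    frailty = rng.gamma(config.consult_dispersion, 1.0 / config.consult_dispersion, size=n)
    birth = pd.DatetimeIndex(patients["birth_date"])
    ded = pd.DatetimeIndex(patients["deduction_date"])
    rows = []
    for period in PERIODS.values():
        start, end = pd.Timestamp(period.start), pd.Timestamp(period.end)
        days = (end - start).days + 1
        bd = birth + pd.Timedelta(days=1)
        lo = pd.DatetimeIndex(bd.where(bd >= start, start))
        hi = pd.DatetimeIndex(np.where(ded.notna(), (ded - pd.Timedelta(days=1)).to_numpy(),
                                       end.to_numpy()))
        hi = pd.DatetimeIndex(hi.where(hi <= end, end))
        exposure = ((hi - lo).days.to_numpy() + 1).clip(min=0) / days
        effect = np.where(visited & (period.label == "during"), config.arm_period_effect, 1.0)
        for role_pool, rate_mult, scheduled in (
            (GP_ROLES, 1.0, False),                      # countable GP contacts
            (GP_ROLES, config.p_excluded_consultation / 2, True),   # scheduled reviews
            ([NON_GP_ROLE], config.p_excluded_consultation / 2, False),  # non-GP roles
        ):
            lam = config.consult_rate * rate_mult * frailty * exposure * effect
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total == 0:
                rng.random(0)
                continue
            rep = np.repeat(np.arange(n), counts)
            span = np.repeat(((hi - lo).days.to_numpy() + 1).clip(min=1), counts)
            offs = np.floor(rng.random(total) * span).astype(int)
            when = pd.DatetimeIndex(np.repeat(lo.to_numpy(), counts)) + pd.to_timedelta(offs, unit="D")
            roles = np.asarray(role_pool)[rng.integers(0, len(role_pool), size=total)]
            rows.append(pd.DataFrame({
                "patient_id": patients["patient_id"].to_numpy()[rep],
                "date": when,
                "role_code": roles,
                "scheduled_review": scheduled,
            }))
    if not rows:
        out = pd.DataFrame(columns=CONSULTATION_COLUMNS)
        out["date"] = pd.to_datetime(out["date"])
        out["scheduled_review"] = out["scheduled_review"].astype(bool)
        return out
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(CONSULTATION_COLUMNS[:3], kind="mergesort").reset_index(drop=True)


# -- CSV export ------------------------------------------------------------

_DATE_COLS = {
    "patients": ["birth_date", "deduction_date", "last_cervical_screen",
                 "last_bowel_screen", "last_breast_screen", "last_health_check"],
    "service_events": ["event_date"],
    "consultations": ["date"],
}


def write_export(tables, directory) -> dict[str, Path]:
    """Write the three export CSVs (ISO-8601 dates) to ``directory``.

    ``tables`` is the (patients, service_events, consultations) triple from
    :func:`generate_population`.  Round-trips losslessly through
    :func:`chww_uptake.cohort.read_export`.
    """
    patients, events, consultations = tables
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    named = {
        "patients": patients.reindex(columns=PATIENT_COLUMNS),
        "service_events": events.reindex(columns=EVENT_COLUMNS),
        "consultations": consultations.reindex(columns=CONSULTATION_COLUMNS),
    }
    paths = {}
    for name, frame in named.items():
        out = frame.copy()
        for col in _DATE_COLS[name]:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
        path = directory / f"{name}.csv"
        out.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths
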