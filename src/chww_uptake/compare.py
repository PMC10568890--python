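"""Arm comparisons: 2x2 Pearson chi-squared tests and proportion displays.

Each per-service row compares the arms on either eligibility (eligible vs
not, over the service's analysis population) or uptake (received vs not,
among the eligible), with the 1-df Pearson statistic and no continuity
correction — the default cross-tabulation test of the major statistics
packages, and the convention needed to reproduce published audit p-values.
A test is invalid (displayed "-") when an expected cell count is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from ._rounding import percent, round_half_up
from .cohort import OCCUPANCY_BINS
from .crci import count_received
from .eligibility import CAT_IMMUNISATIONS, eligible_matrix, registry_index


@dataclass(frozen=True)
class TwoByTwo:
    """Counts (a, b) for arm 1 and (c, d) for arm 2, positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"counts must be non-negative: {self}")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    valid: bool


def pearson_chi2(table: TwoByTwo) -> TestResult:
    """Pearson chi-squared on 1 df, no continuity correction.

    Invalid when any expected count is exactly zero (a zero margin), in
    which case statistic and p are NaN.
    """
    obs = table.as_array()
    n = obs.sum()
    if n == 0:
        return TestResult(float("nan"), float("nan"), False)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected == 0).any():
        return TestResult(float("nan"), float("nan"), False)
    stat, p, _, _ = chi2_contingency(obs, correction=False)
    return TestResult(float(stat), float(p), True)


def uptake_percent(received: int, eligible: int) -> int | None:
    """Integer half-up percent of eligible who received; None if none eligible."""
    p = percent(received, eligible)
    return None if p is None else int(p)


def format_p(result: TestResult, small: float = 0.01) -> str:
    """Two-decimal display: "-" when invalid, "<0.01" below the threshold."""
    if not result.valid:
        return "-"
    p = round_half_up(result.p_value, 2)
    if p < small:
        return f"<{small:.2f}"
    return f"{p:.2f}"


@dataclass(frozen=True)
class ServiceComparison:
    service_code: str
    which: str  # eligibility | uptake
    table: TwoByTwo
    result: TestResult
    intervention_percent: int | None
    control_percent: int | None


def compare_service(service_code: str, views: dict, events: pd.DataFrame,
                    registry, which: str = "uptake") -> ServiceComparison:
    """Build and test the 2x2 arm comparison for one service.

    Eligibility rows compare eligible counts against the analysis-population
    totals (the full register for immunisations, the screening-eligible
    subpopulation for screenings and the Health Check); uptake rows compare
    receipts among the eligible.
    """
    spec = registry_index(registry)[service_code]
    view = views["immunisations" if spec.analysis_category == CAT_IMMUNISATIONS
                 else "screening_hc"]
    patients = view.patients
    elig = eligible_matrix(patients, registry)[service_code]
    by_arm = {}
    for arm in ("intervention", "control"):
        in_arm = patients["visited"] if arm == "intervention" else ~patients["visited"]
        n_pop = int(in_arm.sum())
        n_elig = int((elig & in_arm).sum())
        if which == "eligibility":
            by_arm[arm] = (n_elig, n_pop - n_elig, n_pop)
        elif which == "uptake":
            received = count_received(patients[in_arm & elig], events, registry)
            n_rec = int((received["service_code"] == service_code).sum())
            by_arm[arm] = (n_rec, n_elig - n_rec, n_elig)
        else:
            raise ValueError(f"unknown comparison {which!r}")
    return comparison_from_counts(service_code, which, by_arm)


def comparison_from_counts(service_code: str, which: str, by_arm: dict,
                           ) -> ServiceComparison:
    """Assemble a ServiceComparison from (positive, negative, denominator) cells."""
    (a, b, _), (c, d, _) = by_arm["intervention"], by_arm["control"]
    table = TwoByTwo(a, b, c, d)
    result = pearson_chi2(table)
    pi = uptake_percent(a, by_arm["intervention"][2])
    pc = uptake_percent(c, by_arm["control"][2])
    return ServiceComparison(service_code, which, table, result, pi, pc)


def service_table(views: dict, events: pd.DataFrame, registry) -> pd.DataFrame:
    """Per-service comparison table (eligibility and uptake columns).

    The shape of a published audit's service table: per arm, eligible counts
    with percent of the analysis population and receipt counts with percent
    of the eligible, plus both chi-squared p-values.
    """
    rows = []
    for spec in registry:
        ce = compare_service(spec.service_code, views, events, registry, "eligibility")
        cu = compare_service(spec.service_code, views, events, registry, "uptake")
        rows.append({
            "service_code": spec.service_code,
            "label": spec.label,
            "category": spec.analysis_category,
            "intervention_eligible": ce.table.a,
            "intervention_eligible_pct": ce.intervention_percent,
            "control_eligible": ce.table.c,
            "control_eligible_pct": ce.control_percent,
            "p_eligibility": format_p(ce.result),
            "intervention_received": cu.table.a,
            "intervention_received_pct": cu.intervention_percent,
            "control_received": cu.table.c,
            "control_received_pct": cu.control_percent,
            "p_uptake": format_p(cu.result),
        })
    return pd.DataFrame(rows)


def occupancy_comparison(view) -> pd.DataFrame:
    """Per-occupancy-bin arm comparison (household counts and chi-squared p)."""
    counts = (view.households.groupby(["occupancy_bin", "arm"]).size()
              .unstack(fill_value=0)
              .reindex(index=OCCUPANCY_BINS, fill_value=0)
              .reindex(columns=["intervention", "control"], fill_value=0))
    tot_i, tot_c = int(counts["intervention"].sum()), int(counts["control"].sum())
    rows = []
    for b in OCCUPANCY_BINS:
        ni, nc = int(counts.at[b, "intervention"]), int(counts.at[b, "control"])
        res = pearson_chi2(TwoByTwo(ni, tot_i - ni, nc, tot_c - nc))
        rows.append({
            "occupancy_bin": b,
            "intervention": ni, "intervention_pct": uptake_percent(ni, tot_i),
            "control": nc, "control_pct": uptake_percent(nc, tot_c),
            "p_value": format_p(res),
        })
    rows.append({"occupancy_bin": "total", "intervention": tot_i, "intervention_pct": 100,
                 "control": tot_c, "control_pct": 100, "p_value": "-"})
    return pd.DataFrame(rows)
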