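"""Sample-size and power for a household-clustered uptake study.

A scaled CHWW study allocates whole CHWW patches (≈100 households each), so
the household CRCI is clustered within patches and the usual two-sample
requirement inflates by the design effect

    DEFF = 1 + (m - 1) * ICC,

with m the cluster size and ICC the intra-cluster correlation of household
outcomes.  ``required_households`` applies the normal-approximation
two-sample comparison of means to the CRCI difference; ``simulated_power``
replays the full synthetic pipeline and counts rejections of the
household-level arm comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .crci import household_scores
from .eligibility import CAT_OVERALL, build_registry
from .cohort import build_views
from .simulate import SimConfig, generate_population


def design_effect(cluster_size: int, icc: float) -> float:
    """Variance inflation 1 + (m - 1) * ICC for cluster allocation."""
    if not 0 <= icc < 1:
        raise ValueError(f"icc must lie in [0, 1), got {icc}")
    if cluster_size < 1:
        raise ValueError(f"cluster_size must be >= 1, got {cluster_size}")
    return 1.0 + (cluster_size - 1) * icc


@dataclass(frozen=True)
class DesignScenario:
    """Planning assumptions for a future cluster-allocated study.

    ``effect_size`` is the relative CRCI lift in the intervention arm
    (0.30 = 30%); ``crci_sd`` the between-household SD of the CRCI;
    ``households_per_chw`` the cluster size.
    """

    icc: float
    effect_size: float = 0.30
    alpha: float = 0.05
    power: float = 0.90
    baseline_crci: float = 0.15
    crci_sd: float = 0.17
    households_per_chw: int = 100
    mean_occupancy: float = 3.4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.power < 1:
            raise ValueError(f"power must lie in (0, 1), got {self.power}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be non-negative, got {self.effect_size}")
        if self.baseline_crci <= 0 or self.crci_sd <= 0:
            raise ValueError("baseline_crci and crci_sd must be positive")


def required_households(scenario: DesignScenario) -> float:
    """Households per arm for the target power, inflated by the design effect.

    Normal-approximation two-sample means:
        n = 2 (z_{1-alpha/2} + z_{power})^2 sd^2 / delta^2 * DEFF,
    delta = effect_size * baseline_crci.  Rounded up; infinite at zero effect.
    """
    if scenario.effect_size == 0:
        return math.inf
    delta = scenario.effect_size * scenario.baseline_crci
    z = stats.norm.ppf(1 - scenario.alpha / 2) + stats.norm.ppf(scenario.power)
    n_unclustered = 2 * (z ** 2) * (scenario.crci_sd ** 2) / (delta ** 2)
    return math.ceil(n_unclustered * design_effect(scenario.households_per_chw, scenario.icc))


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_households: int


def simulated_power(scenario: DesignScenario, sim_config: SimConfig | None = None,
                    n_reps: int = 200, seed: int = 0) -> PowerEstimate:
    """Empirical power of the household-level arm comparison.

    Each replicate generates a synthetic pilot with the scenario's effect
    (uptake multiplier 1 + effect_size, household ICC as configured),
    computes the overall household CRCI and applies a Welch t-test between
    arms at the scenario's alpha.  Returns the rejection fraction with a
    95% Wilson interval.
    """
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100 for a stable estimate, got {n_reps}")
    base = sim_config or SimConfig(n_households=300, p_visited=0.5)
    base = base.model_copy(update={
        "intervention_multiplier": 1.0 + scenario.effect_size,
        "icc": scenario.icc,
    })
    registry = build_registry()
    root = np.random.default_rng(seed)
    rejections = 0
    saw_variance = False
    for rep in range(n_reps):
        cfg = base.model_copy(update={"seed": int(root.integers(0, 2**31 - 1))})
        patients, events, _ = generate_population(cfg, include_consultations=False)
        views = build_views(patients, registry)
        scores = household_scores(views["immunisations"], events, registry)
        overall = scores[scores["category"] == CAT_OVERALL]
        xi = overall.loc[overall["arm"] == "intervention", "crci"].dropna()
        xc = overall.loc[overall["arm"] == "control", "crci"].dropna()
        if len(xi) < 2 or len(xc) < 2:
            continue
        if xi.std() > 0 or xc.std() > 0:
            saw_variance = True
            _, p = stats.ttest_ind(xi, xc, equal_var=False)
            if p < scenario.alpha:
                rejections += 1
    if not saw_variance:
        raise RuntimeError("degenerate generator: household CRCI has zero variance")
    phat = rejections / n_reps
    lo, hi = _wilson(rejections, n_reps)
    return PowerEstimate(phat, lo, hi, n_reps, base.n_households)


def _wilson(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def scenario_table(iccs=(0.01, 0.02, 0.05), **kwargs):
    """Required households per arm across candidate ICCs."""
    rows = []
    for icc in iccs:
        sc = DesignScenario(icc=icc, **kwargs)
        rows.append({
            "icc": icc,
            "design_effect": design_effect(sc.households_per_chw, icc),
            "households_per_arm": required_households(sc),
        })
    return rows
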