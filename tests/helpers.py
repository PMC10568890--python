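"""Independent oracles used by the test suite.

Everything here is deliberately written from the printed rules and standard
formulas, not by calling the package's own code paths, so agreement between
the two is evidence rather than tautology.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

D = dt.date


def _d(v):
    if v is None or v is pd.NaT or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, pd.Timestamp):
        return v.date()
    return v


def brute_force_eligible(patient: dict) -> set[str]:
    """Rule-by-rule re-application of the printed eligibility criteria.

    Plain scalar ifs over date literals; returns the set of service codes
    the patient is eligible for.
    """
    born = _d(patient["birth_date"])
    sex = patient["sex"]
    out = set()

    # COVID-19: all analysed individuals assumed eligible for all 3 doses
    out |= {"covid1", "covid2", "covid_booster"}

    if D(1942, 7, 1) <= born <= D(1952, 1, 31):
        out.add("shingles")
    if D(2021, 3, 1) <= born <= D(2022, 1, 31):
        out.add("dtap_ipv_hib_hepb")
    if D(2016, 7, 1) <= born <= D(2018, 10, 1):
        out.add("dtap_ipv")
    if D(2018, 3, 1) <= born <= D(2021, 1, 31):
        out.add("hib_menc")
        out.add("menb3")
    if D(2008, 7, 1) <= born <= D(2010, 1, 31):
        out.add("hpv")
    if (D(2005, 9, 1) <= born <= D(2020, 3, 31)) or born <= D(1957, 3, 31) \
            or patient.get("at_risk_flu", False):
        out.add("influenza")
    if D(2016, 6, 30) <= born <= D(2021, 1, 31):
        out.add("mmr1")
        out.add("mmr2")
    if D(2021, 4, 1) <= born <= D(2022, 1, 31):
        out.add("pcv1")
        out.add("rotavirus")
    if D(2020, 6, 30) <= born <= D(2021, 1, 31):
        out.add("pcv2")
    if born <= D(1957, 4, 30):
        out.add("ppv")

    if D(1947, 7, 1) <= born <= D(1962, 1, 31):
        last = _d(patient.get("last_bowel_screen"))
        if last is None or last < D(2020, 7, 1):
            out.add("bowel")
    if sex == "female" and D(1950, 7, 1) <= born <= D(1972, 1, 31):
        last = _d(patient.get("last_breast_screen"))
        if last is None or last < D(2019, 7, 1):
            out.add("breast")
    if sex == "female" and D(1972, 7, 1) <= born <= D(1997, 1, 31):
        last = _d(patient.get("last_cervical_screen"))
        if last is None or last < D(2019, 7, 1):
            out.add("cervical_25_49")
    if sex == "female" and D(1957, 7, 1) <= born <= D(1972, 1, 31):
        last = _d(patient.get("last_cervical_screen"))
        if last is None or last < D(2017, 7, 1):
            out.add("cervical_50_64")
    if D(1947, 7, 1) <= born <= D(1982, 1, 31) and not patient.get("hc_exclusion", False):
        last = _d(patient.get("last_health_check"))
        if last is None or last < D(2017, 7, 1):
            out.add("health_check")
    return out


def margin_form_statistic(a: int, b: int, c: int, d: int) -> float:
    """n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)): the 2x2 Pearson identity."""
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return float("nan")
    return n * (a * d - b * c) ** 2 / den


def _pearson_stat(a, b, c, d):
    t = np.array([[a, b], [c, d]], dtype=float)
    n = t.sum()
    e = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (t - e) ** 2 / e
    return np.nansum(np.where(e > 0, contrib, 0.0))


def enumeration_tail(a: int, b: int, c: int, d: int) -> float:
    """Exact conditional tail P(X^2 >= observed) by full enumeration.

    Enumerates every 2x2 table with the observed margins (equivalently,
    every permutation of arm labels), weighting by the hypergeometric
    probability.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    s_obs = _pearson_stat(a, b, c, d)
    p = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        s = _pearson_stat(x, r1 - x, c1 - x, r2 - (c1 - x))
        if s >= s_obs - 1e-9:
            p += hypergeom.pmf(x, n, r1, c1)
    return float(p)


def random_table(rng: np.random.Generator, max_total: int = 30,
                 min_margin: int = 1) -> tuple[int, int, int, int]:
    """A random non-degenerate 2x2 table with grand total <= max_total."""
    while True:
        n = int(rng.integers(4, max_total + 1))
        cuts = np.sort(rng.choice(np.arange(1, n), size=3, replace=False))
        a, b, c, d = int(cuts[0]), int(cuts[1] - cuts[0]), int(cuts[2] - cuts[1]), int(n - cuts[2])
        if min(a + b, c + d, a + c, b + d) >= min_margin:
            return a, b, c, d


def anova_icc(values: pd.Series, groups: pd.Series) -> float:
    """One-way ANOVA intra-class correlation estimator (unequal group sizes)."""
    df = pd.DataFrame({"y": values.astype(float), "g": groups})
    grouped = df.groupby("g")["y"]
    k = grouped.size()
    n, big_k = len(df), len(k)
    grand = df["y"].mean()
    msb = float((k * (grouped.mean() - grand) ** 2).sum() / (big_k - 1))
    ssw = float(((df["y"] - grouped.transform("mean")) ** 2).sum())
    msw = ssw / (n - big_k)
    n0 = (n - float((k ** 2).sum()) / n) / (big_k - 1)
    return (msb - msw) / (msb + (n0 - 1) * msw)
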