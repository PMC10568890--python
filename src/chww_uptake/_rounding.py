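"""Half-up rounding used for all displayed values.

GP-audit tables print integer percents and 2-dp proportions rounded half
away from zero (e.g. 46.67 -> 47, -7.395 -> -7.40), which differs from
Python's banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places, ties going away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 0) -> float | None:
    """``100 * numerator / denominator`` rounded half-up; None for a zero denominator."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * numerator / denominator, decimals)
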