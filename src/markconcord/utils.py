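"""Small shared helpers: rounding and percentage conventions used in reports."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), unlike Python's banker's rounding.

    Report tables print percentages in the half-up convention (13.295 -> 13.30),
    so rounding must not depend on binary-float tie behaviour.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)
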