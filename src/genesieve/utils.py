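"""Shared numeric helpers.

All percentages reported anywhere in the package go through
:func:`pct` so that rounding (one decimal, half-up) is identical across
recall reports, agreement statistics and filtering summaries.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round ``value`` to ``ndigits`` decimals with ties going away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage ``numerator / denominator * 100`` rounded half-up.

    Exact decimal arithmetic is used for integer inputs so printed
    figures such as 27/32 -> 84.4 do not depend on binary float
    representation.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    if isinstance(numerator, int) and isinstance(denominator, int):
        frac = Decimal(numerator) / Decimal(denominator) * 100
    else:
        frac = Decimal(repr(numerator)) / Decimal(repr(denominator)) * 100
    quantum = Decimal(1).scaleb(-ndigits)
    return float(frac.quantize(quantum, rounding=ROUND_HALF_UP))
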