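"""Percent formatting: one decimal, round half up, everywhere."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round to ``ndigits`` decimals with ties away from zero.

    Python's builtin ``round`` uses banker's rounding; reported percentages
    follow the half-up convention instead (98.45 -> 98.5).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
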