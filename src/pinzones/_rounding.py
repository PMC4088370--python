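"""Half-away-from-zero rounding used for all printed percentages and degrees."""

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round ``value`` to ``ndigits`` decimals, ties going away from zero.

    Python's builtin ``round`` uses banker's rounding; report tables here use
    the convention most readers expect (0.05 -> 0.1, -0.05 -> -0.1).
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """100 * count / total, rounded half away from zero; 0.0 when total is 0."""
    if total == 0:
        return 0.0
    return round_half_away(100.0 * count / total, ndigits)
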