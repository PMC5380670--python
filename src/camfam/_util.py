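"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round ``value`` half-up to ``ndigits`` decimals.

    Reported percentages use commercial (half-up) rounding rather than
    Python's banker's rounding, so 98.655 -> 98.66 and 5.335 -> 5.34.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(value: float) -> str:
    """Serialize a percentage with exactly two decimals, half-up."""
    q = Decimal("0.01")
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
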