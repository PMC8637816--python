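"""Decimal rounding helpers for display-precision emulation.

Spreadsheet-style reports round intermediate quantities at display
precision before combining them; reproducing such tables digit-for-digit
requires decimal (not binary float) rounding, including truncation toward
zero, which `round()` cannot express.
"""

from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "truncate"]


def _quantum(ndigits: int) -> Decimal:
    return Decimal(1).scaleb(-ndigits)


def round_half_up(x: float, ndigits: int) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero."""
    return float(Decimal(repr(x)).quantize(_quantum(ndigits), rounding=ROUND_HALF_UP))


def truncate(x: float, ndigits: int) -> float:
    """Truncate toward zero at ``ndigits`` decimals (no rounding)."""
    return float(Decimal(repr(x)).quantize(_quantum(ndigits), rounding=ROUND_DOWN))
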