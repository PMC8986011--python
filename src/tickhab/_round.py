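"""Display-precision helpers: round half away from zero, truncate toward zero."""

from __future__ import annotations

import decimal

__all__ = ["round_half_away", "truncate"]


def _quantum(ndigits: int) -> decimal.Decimal:
    return decimal.Decimal(1).scaleb(-ndigits)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Matches common spreadsheet/table rounding (0.25 -> 0.3, -0.25 -> -0.3),
    unlike Python's banker's rounding.
    """
    d = decimal.Decimal(repr(float(x)))
    return float(d.quantize(_quantum(ndigits), rounding=decimal.ROUND_HALF_UP))


def truncate(x: float, ndigits: int = 0) -> float:
    """Drop decimals beyond ``ndigits`` (round toward zero)."""
    d = decimal.Decimal(repr(float(x)))
    return float(d.quantize(_quantum(ndigits), rounding=decimal.ROUND_DOWN))
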