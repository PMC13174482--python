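"""Small shared helpers."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def pct(numerator: float, denominator: float) -> float:
    """Percentage numerator/denominator*100, or 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    return 100.0 * numerator / denominator


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at the given precision (report formatting)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(numerator: float, denominator: float, ndigits: int = 2) -> str:
    return f"{round_half_up(pct(numerator, denominator), ndigits):.{ndigits}f}%"
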