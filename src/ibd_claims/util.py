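"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at *ndigits* decimals (printed-table rule)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int) -> float:
    """Percentage ``100 * numerator / denominator``, table-rounded.

    Rounds half-up through a one-extra-decimal intermediate, the
    convention the published tables follow (126/616 prints as 20.46, via
    20.455; single-stage rounding would give 20.45 — every printed cell is
    consistent with the staged rule).
    """
    if denominator == 0:
        return float("nan")
    staged = round_half_up(100.0 * numerator / denominator, ndigits + 1)
    return round_half_up(staged, ndigits)
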