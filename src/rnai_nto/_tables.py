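"""Shared percentage formatting for the report-table summarizers.

The published report style prints per-row percentages rounded half-up to
two decimals.  Two rendering styles exist side by side: the default always
keeps two decimals ("0.00%"); the legacy style drops the decimal part for
integer-valued percentages ("0%", "100%"), matching the mixed style of the
match-length table.  Empty rows render percentages as an en-dash.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

EMPTY_CELL = "–"  # en-dash used for empty bins


def pct_value(n: int, total: int) -> float:
    """100*n/total rounded half-up to two decimals (exact decimal arithmetic)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if n < 0 or n > total:
        raise ValueError(f"count {n} outside [0, {total}]")
    q = (Decimal(100 * n) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


def pct_string(n: int, total: int, legacy: bool = False) -> str:
    """Render a percentage as printed in the report tables, with '%' sign."""
    v = (Decimal(100 * n) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    if legacy and v == v.to_integral_value():
        return f"{int(v)}%"
    return f"{v}%"


def count_pct(n: int, total: int, legacy: bool = False) -> str:
    """Render 'count (pct%)' cells, e.g. '71 (0.25%)'."""
    return f"{n} ({pct_string(n, total, legacy=legacy)})"
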