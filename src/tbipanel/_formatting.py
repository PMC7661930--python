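"""Centralised reporting-layer rounding (half-up, one decimal by default).

Rounding is applied only when numbers are formatted for tables, never inside
computations, so table snapshots are stable across platforms.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "fmt_pct", "fmt_ci"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at `ndigits` decimals (0.05 -> 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def fmt_pct(x: float, ndigits: int = 1) -> str:
    """Format a percentage for report tables."""
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def fmt_ci(lo: float, hi: float, ndigits: int = 1) -> str:
    return f"({fmt_pct(lo, ndigits)}–{fmt_pct(hi, ndigits)})"
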