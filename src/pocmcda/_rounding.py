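"""Display rounding.

All pipeline arithmetic is carried out at full floating-point precision;
rounding happens only when numbers are rendered.  The convention is
round-half-up (0.005 -> 0.01), which matches how the workshop scoring
matrices in this field are typically printed, and differs from Python's
built-in banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up"]


def round_half_up(value: float, dp: int = 2) -> float:
    """Round ``value`` to ``dp`` decimal places, ties away from zero upward.

    Uses ``repr`` of the float so that values like 2.675 (stored as
    2.67499...) still round the way a human reading the decimal would
    expect.
    """
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
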