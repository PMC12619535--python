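"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as printed summary tables do.

    Python's built-in ``round`` uses banker's rounding (0.25 -> 0.2); published
    tables round 0.25 -> 0.3, so reported values go through this helper.
    Internal computation always stays at full precision.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
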