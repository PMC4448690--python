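"""Small shared helpers."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed report tables).

    Python's builtin ``round`` is banker's rounding; report percentages such as
    "68.7%" follow half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
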