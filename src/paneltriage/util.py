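"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal


def round_half_even(x: float, ndigits: int = 1) -> float:
    """Round-half-to-even at a decimal precision (table formatting).

    Uses decimal arithmetic so that values like 10.05 round predictably on
    their printed representation rather than on binary artefacts.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))
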