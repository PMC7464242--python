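"""Small shared helpers."""

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, platform-independently.

    Reported tables round half-up (89 for 88.89%, 7.11 for 7.111...);
    Python's built-in round is banker's rounding, which differs at exact
    ties, so reporting goes through Decimal.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
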