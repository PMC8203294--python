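"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


class ConfigurationError(ValueError):
    """A simulation or analysis configuration violates its invariants."""


class InputError(ValueError):
    """An input table or file violates the documented schema."""


def round_half_up(x: float, digits: int = 0) -> float:
    """Round with ties going away from zero at the .5 boundary.

    Python's builtin ``round`` uses banker's rounding, which maps 0.5 to 0;
    printed percentages in pathology-style reporting conventionally round
    71.5 -> 72, so the half-up rule is applied explicitly.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
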