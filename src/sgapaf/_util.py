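"""Small shared helpers: rounding, percentages, common exceptions."""

from __future__ import annotations

import math


class DataError(ValueError):
    """Raised when input records violate a structural precondition."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used in reported tables).

    Python's built-in ``round`` is banker's rounding; report tables here use
    the half-up convention (5.25 -> 5.3 at one decimal).
    """
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def percentage(part: float, whole: float, ndigits: int = 1) -> float:
    """``part`` as a percentage of ``whole``, rounded half-up.

    Raises :class:`ZeroDivisionError`-free ``DataError`` on an empty
    denominator: an undefined percentage must never be silently reported as 0.
    """
    if whole == 0:
        raise DataError("percentage undefined: denominator is zero")
    return round_half_up(100.0 * part / whole, ndigits)
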