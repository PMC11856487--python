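"""Exact rounding helpers.

Allele sizes and their differences are reported to one decimal with ties
rounded half away from zero.  Fixture sizes carry at most one decimal, so
differences are exact multiples of 0.1; doing the bookkeeping in integer
tenths (with ``Fraction`` for means) avoids float ties landing on the wrong
side (e.g. a mean of exactly -3.25 must print as -3.3).
"""

from __future__ import annotations

from fractions import Fraction
from math import floor


def round_half_away(x: float | Fraction, ndigits: int = 0) -> float:
    """Round to ``ndigits`` decimals, ties away from zero."""
    q = Fraction(x).limit_denominator(10**9) if isinstance(x, float) else Fraction(x)
    scale = Fraction(10) ** ndigits
    scaled = q * scale
    sign = 1 if scaled >= 0 else -1
    rounded = sign * floor(abs(scaled) + Fraction(1, 2))
    return float(Fraction(rounded, 1) / scale)


def tenths(x: float) -> int:
    """Nearest integer number of tenths (for values measured to 0.1 bp)."""
    return round(x * 10)


def mean_tenths(values: list[int]) -> Fraction:
    """Exact mean of integer-tenths values, in tenths."""
    return Fraction(sum(values), len(values))


def round_tenths(value: Fraction) -> float:
    """Round a tenths-scale Fraction to the nearest tenth, half away from zero."""
    sign = 1 if value >= 0 else -1
    return sign * floor(abs(value) + Fraction(1, 2)) / 10.0
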