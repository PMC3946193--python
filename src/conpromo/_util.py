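"""Shared helpers: rounding and nucleotide utilities."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def check_alphabet(seq: str) -> None:
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-nucleotide symbols: {sorted(bad)}")


def round_half_up(x: float | Fraction, ndigits: int = 0) -> float:
    """Round with ties away from zero, the convention used for reported means
    and percentages (``round`` in Python rounds half to even, which would turn
    e.g. 0.5 into 0)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 0) -> float:
    """Exact rational percentage, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(Fraction(numerator, denominator) * 100, ndigits)
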