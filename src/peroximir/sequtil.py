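"""Small sequence helpers shared across the pipeline.

All sequences are stored internally in the DNA alphabet (T, not U);
reports that mimic published miRNA tables may render U instead.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Normalize an RNA/DNA string to upper-case DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render a DNA string in the RNA alphabet (T -> U), for reports."""
    return seq.upper().replace("T", "U")


def is_watson_crick(a: str, b: str) -> bool:
    """True if DNA bases a and b form a Watson-Crick pair."""
    return (a + b) in ("AT", "TA", "GC", "CG")


def is_wobble(a: str, b: str) -> bool:
    """True if bases a and b form a G:U wobble pair (DNA notation G:T)."""
    return (a + b) in ("GT", "TG")


def pairs(a: str, b: str) -> bool:
    """True if the two bases can pair at all (Watson-Crick or wobble)."""
    return is_watson_crick(a, b) or is_wobble(a, b)


def fmt_pct(numerator: float, denominator: float, ndigits: int = 2) -> str:
    """Percentage formatted to fixed decimals, half-away-from-zero.

    Published sRNA bookkeeping rounds 0.977552 -> "97.76"; Python's
    bankers' rounding would sometimes disagree, so the half-up rule is
    applied explicitly. A zero denominator yields "0.00".
    """
    if denominator == 0:
        value = 0.0
    else:
        value = 100.0 * numerator / denominator
    return f"{round_half_away(value, ndigits):.{ndigits}f}"


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round half away from zero at the given number of decimals."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
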