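"""Small shared helpers: rounding convention and sequence ops."""

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero to `ndigits` decimals.

    Percentages, coverages and densities across the survey are reported to
    one decimal under this convention (banker's rounding would disagree on
    exact .x5 values).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]
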