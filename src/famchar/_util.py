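"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("XBZJUO")
DNA_LETTERS = frozenset("ACGT")
GAP = "-"

#: Sentinel residue substituted for ambiguity codes in permissive mode.
#: Excluded from every downstream score.
AMBIGUOUS_SENTINEL = "X"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention used by the summary tables).

    Python's built-in ``round`` uses banker's rounding, which disagrees with
    printed percentages like 13.685 -> 13.68; this helper matches the tables.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def percent(count: int, total: int, ndigits: int = 2) -> float:
    """``100 * count / total`` rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total, ndigits)
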