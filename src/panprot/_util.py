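"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as printed reports do.

    Python's built-in ``round`` uses banker's rounding; tabular reports in
    comparative-genomics papers round half up, so percentages and densities
    go through this helper before being reported.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def check_protein(seq: str, *, what: str = "sequence") -> str:
    """Validate a protein sequence over the 20 standard residues."""
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - _AA_SET
    if bad:
        raise ValueError(
            f"{what} contains non-standard residues: {''.join(sorted(bad))}"
        )
    return seq
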