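"""Small RNA-alphabet helpers shared across modules."""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T->U. Does not validate."""
    return seq.upper().replace("T", "U")


def validate_rna(seq: str, *, context: str = "sequence") -> str:
    """Normalize to RNA and raise ValueError on non-ACGU characters."""
    seq = normalize_rna(seq)
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"{context}: invalid characters {sorted(bad)} (alphabet is A/C/G/U)"
        )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (5'->3' in, 5'->3' out)."""
    return seq.translate(_COMPLEMENT)[::-1]
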