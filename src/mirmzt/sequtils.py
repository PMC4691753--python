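"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

DNA_ALPHABET = frozenset("ACGTN")


def to_dna(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T); validate alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGTUN characters in sequence: {sorted(bad)!r}")
    return s


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result in DNA alphabet)."""
    return seq.upper().replace("U", "T").translate(_COMPLEMENT)[::-1]
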