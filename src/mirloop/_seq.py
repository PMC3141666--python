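"""Small sequence utilities shared across the package.

Internally all small-RNA sequences are uppercase RNA (U, not T); genome
sequences are uppercase DNA.  Conversions happen at module boundaries.
"""

from __future__ import annotations

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

# Watson-Crick pairs plus the G:U wobble, on the RNA alphabet.
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return to_dna(seq).translate(_DNA_COMPLEMENT)[::-1]


def is_wc(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS


def is_gu(a: str, b: str) -> bool:
    return (a, b) in GU_PAIRS


def pairs(a: str, b: str, allow_gu: bool = True) -> bool:
    """Whether two RNA bases can base-pair."""
    return (a, b) in WC_PAIRS or (allow_gu and (a, b) in GU_PAIRS)


def pair_weight(a: str, b: str) -> int:
    """Stem-stability proxy weight of one base pair: G-C=3, A-U=2, G-U=1."""
    if (a, b) in GU_PAIRS:
        return 1
    if (a, b) in WC_PAIRS:
        return 3 if "G" in (a, b) else 2
    return 0
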