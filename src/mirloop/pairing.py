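"""Pairing strings: per-position classification of a miRNA/site duplex.

The notation follows the convention of plant target-prediction reports:
``|`` Watson-Crick pair, ``:`` G:U wobble, ``-`` mismatch.  The site is
given 3'->5', i.e. already aligned position-wise with the miRNA read
5'->3' (an ungapped antiparallel duplex).
"""

from __future__ import annotations

from ._seq import is_gu, is_wc, to_rna

PAIRING_SYMBOLS = frozenset("|:-")


def render_pairing(mirna: str, target_site: str) -> str:
    """Classify each position of an ungapped miRNA/site duplex.

    ``target_site`` is the site read 3'->5' so that position k of the
    miRNA faces position k of the site.  A-U and G-C give ``|``, G-U
    (either orientation) gives ``:``, anything else ``-``.
    """
    m = to_rna(mirna)
    s = to_rna(target_site)
    if len(m) != len(s):
        raise ValueError(
            f"miRNA and site must have equal length (got {len(m)} vs {len(s)})"
        )
    out = []
    for a, b in zip(m, s):
        if is_wc(a, b):
            out.append("|")
        elif is_gu(a, b):
            out.append(":")
        else:
            out.append("-")
    return "".join(out)


def score_pairing_string(
    pairing: str,
    mismatch_weight: float = 1.0,
    gu_weight: float = 0.5,
) -> float:
    """Weighted penalty of a pairing string: mismatches plus wobbles.

    With the default weights (mismatch = 1, G:U = 0.5) this is the
    total score used to accept predicted target sites.
    """
    foreign = set(pairing) - PAIRING_SYMBOLS
    if foreign:
        raise ValueError(f"foreign pairing symbols: {sorted(foreign)}")
    return mismatch_weight * pairing.count("-") + gu_weight * pairing.count(":")
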