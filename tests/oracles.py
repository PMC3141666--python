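"""Independent brute-force oracles used only by the tests.

These deliberately avoid the dynamic-programming formulations used by
the package: local alignment is an explicit enumeration of alignment
paths with a bounded number of gaps, and folding enumerates every
non-crossing pairing of a short sequence.
"""

from __future__ import annotations

from mirloop._seq import pair_weight


def brute_force_local_score(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    max_gaps: int = 2,
) -> int:
    """Best local alignment score over all alignments with <= max_gaps gaps.

    Enumerates every alignment path from every start pair, scoring every
    prefix (an alignment may stop anywhere).
    """
    n, m = len(query), len(subject)
    best = 0

    def rec(i: int, j: int, score: int, gaps: int) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < n and j < m:
            rec(i + 1, j + 1, score + (match if query[i] == subject[j] else mismatch), gaps)
        if gaps < max_gaps:
            if i < n:
                rec(i + 1, j, score + gap, gaps + 1)
            if j < m:
                rec(i, j + 1, score + gap, gaps + 1)

    for i in range(n):
        for j in range(m):
            rec(i, j, 0, 0)
    return best


def enumerate_pairings(seq: str, min_loop: int = 3):
    """Yield every non-crossing pairing (list of index pairs) of ``seq``."""

    def rec(i: int, j: int):
        if i >= j:
            yield []
            return
        # i unpaired
        yield from rec(i + 1, j)
        for k in range(i + min_loop + 1, j):
            if pair_weight(seq[i], seq[k]) > 0:
                for left in rec(i + 1, k):
                    for right in rec(k + 1, j):
                        yield [(i, k)] + left + right

    yield from rec(0, len(seq))


def best_pairing_score(seq: str, min_loop: int = 3) -> int:
    """Exhaustive maximum weighted pair score over all non-crossing pairings."""
    best = 0
    for pairing in enumerate_pairings(seq, min_loop):
        score = sum(pair_weight(seq[i], seq[j]) for i, j in pairing)
        if score > best:
            best = score
    return best
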