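"""Smith-Waterman local alignment.

Used to place the reverse complement of a sequenced tag (the candidate
miRNA* arm) inside the genomic flanks of the tag.  Scoring is plain
sequence identity with a linear gap penalty; G:U wobble is deliberately
not rewarded here — wobble handling belongs to the duplex evaluation of
the folded hairpin, not to locating the star arm.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import to_rna


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment between ``query`` and ``subject``.

    Coordinates are 0-based half-open on the original (ungapped)
    sequences.  ``aligned_query``/``aligned_subject`` are equal-length
    strings with ``-`` gap characters.
    """

    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str
    score: int

    @property
    def is_empty(self) -> bool:
        return self.score <= 0

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError("aligned strings must have equal length")


EMPTY_ALIGNMENT = LocalAlignment(0, 0, 0, 0, "", "", 0)


def smith_waterman(
    query: str,
    subject: str,
    scoring: tuple[int, int, int] = (1, -1, -2),
) -> LocalAlignment:
    """Maximal-scoring local alignment of ``query`` against ``subject``.

    Parameters
    ----------
    query, subject:
        Non-empty sequences; RNA and DNA are treated as equivalent
        (T and U interchangeable), case-insensitive.
    scoring:
        ``(match, mismatch, gap)`` with a linear gap penalty.

    Ties on the optimal score are broken by the smallest subject start,
    then the smallest query start.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    match, mismatch, gap = scoring
    q = to_rna(query)
    s = to_rna(subject)
    n, m = len(q), len(s)

    # H[i][j]: best local score ending at q[:i], s[:j]
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        Hi, Hp = H[i], H[i - 1]
        for j in range(1, m + 1):
            diag = Hp[j - 1] + (match if qi == s[j - 1] else mismatch)
            v = diag
            up = Hp[j] + gap
            if up > v:
                v = up
            left = Hi[j - 1] + gap
            if left > v:
                v = left
            if v < 0:
                v = 0
            Hi[j] = v
            if v > best:
                best = v
    if best == 0:
        return EMPTY_ALIGNMENT

    # Candidate end cells at the optimal score; traceback each and keep the
    # alignment with the smallest (subject_start, query_start).
    winner = None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i][j] != best:
                continue
            aln = _traceback(q, s, H, i, j, match, mismatch, gap)
            key = (aln.subject_start, aln.query_start)
            if winner is None or key < winner[0]:
                winner = (key, aln)
    assert winner is not None
    return winner[1]


def _traceback(q, s, H, i, j, match, mismatch, gap) -> LocalAlignment:
    aq, as_ = [], []
    end_i, end_j = i, j
    while i > 0 and j > 0 and H[i][j] > 0:
        sub = match if q[i - 1] == s[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + sub:
            aq.append(q[i - 1])
            as_.append(s[j - 1])
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] + gap:
            aq.append(q[i - 1])
            as_.append("-")
            i -= 1
        else:
            aq.append("-")
            as_.append(s[j - 1])
            j -= 1
    return LocalAlignment(
        query_start=i,
        query_end=end_i,
        subject_start=j,
        subject_end=end_j,
        aligned_query="".join(reversed(aq)),
        aligned_subject="".join(reversed(as_)),
        score=H[end_i][end_j],
    )


# Aligned strings are rendered on the normalized uppercase-RNA alphabet, so
# stripping gaps from them recovers to_rna(query)[qs:qe] / to_rna(subject)[ss:se].
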