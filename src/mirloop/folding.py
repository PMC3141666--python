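"""RNA secondary structure by weighted base-pair maximization.

A Nussinov-style dynamic program maximizing a stem-stability proxy
(G-C = 3, A-U = 2, G-U = 1) under the usual non-crossing and minimum
hairpin-loop constraints.  The optimal score is a *proxy* for stem
stability and is deliberately not comparable to thermodynamic free
energies from nearest-neighbour folders; for validating miRNA hairpins
only the pairing pattern of the duplex matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from ._seq import RNA_ALPHABET, pair_weight, to_rna

_NEG = -(10**6)


@dataclass(frozen=True)
class FoldStructure:
    """A pseudoknot-free secondary structure of one sequence."""

    sequence: str
    pairs: tuple[tuple[int, int], ...]  # (i, j) with i < j, 0-based
    score: int                          # summed pair weights

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    @cached_property
    def dot_bracket(self) -> str:
        chars = ["."] * len(self.sequence)
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    @cached_property
    def partner(self) -> dict[int, int]:
        """Position -> paired position, for both members of each pair."""
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Closing pairs (i, j) that enclose no other pair (terminal loops)."""
        loops = []
        for i, j in self.pairs:
            if not any(i < a and b < j for a, b in self.pairs if (a, b) != (i, j)):
                loops.append((i, j))
        return sorted(loops)


def fold_hairpin(sequence: str, min_loop: int = 3) -> FoldStructure:
    """Fold ``sequence`` by weighted base-pair maximization.

    Every pair (i, j) is separated by at least ``min_loop`` unpaired
    positions (j - i > min_loop).  Traceback is deterministic: when the
    optimum is ambiguous the 5'-most position is paired with the
    smallest admissible partner.

    Raises
    ------
    ValueError
        For characters outside ACGU/acgut or a sequence too short to
        close a single loop.
    """
    seq = to_rna(sequence)
    if not set(seq) <= RNA_ALPHABET:
        bad = sorted(set(seq) - RNA_ALPHABET)
        raise ValueError(f"non-ACGU characters in sequence: {bad}")
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError(f"sequence length {n} below minimum {min_loop + 2}")

    # Pair-weight matrix; 0 encodes "cannot pair".
    W = np.zeros((n, n), dtype=np.int64)
    alphabet = "ACGU"
    lut = {(a, b): pair_weight(a, b) for a in alphabet for b in alphabet}
    for i in range(n):
        ai = seq[i]
        W[i, :] = [lut[(ai, b)] for b in seq]
    Wm = np.where(W > 0, W, _NEG)

    # dp[i][j]: best score for the half-open interval seq[i:j]
    dp = np.zeros((n + 2, n + 1), dtype=np.int64)
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = dp[i + 1, j]
            ks = np.arange(i + min_loop + 1, j)
            if ks.size:
                vals = Wm[i, ks] + dp[i + 1, ks] + dp[ks + 1, j]
                m = vals.max()
                if m > best:
                    best = m
            dp[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 2:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j):
            if W[i, k] > 0 and W[i, k] + dp[i + 1, k] + dp[k + 1, j] == target:
                pairs.append((i, k))
                stack.append((k + 1, j))
                stack.append((i + 1, k))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    pairs.sort()
    return FoldStructure(sequence=seq, pairs=tuple(pairs), score=int(dp[0, n]))
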