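"""Hairpin precursor discovery around mapped tags.

For every genomic hit of a tag the pipeline extracts 200 bp of flank on
each side, aligns the reverse complement of the tag (rc-tag) into the
flanks with Smith-Waterman to locate the candidate miRNA* arm, folds the
region delimited by the tag and rc-tag alignments, and accepts the locus
as a miRNA precursor when the mature/star duplex satisfies three
criteria: (i) mature and star lie entirely within opposite stem arms,
outside the terminal loop; (ii) at most four mature positions are
unpaired or mispaired against the star arm (G:U counts as paired);
(iii) at most one asymmetric bulge of at most two bases interrupts the
duplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from ._seq import is_gu, revcomp_rna, to_rna
from .alignment import LocalAlignment, smith_waterman
from .config import DEFAULT_CONFIG, PipelineConfig
from .folding import FoldStructure, fold_hairpin
from .io import Feature, label_context
from .mapping import GenomeHit, GenomeIndex
from .tags import Tag

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FlankWindow:
    """Tag with genomic flanks, oriented so the tag reads 5'->3'.

    For minus-strand hits the window is the reverse complement of the
    plus-strand slice; ``to_genomic`` maps window intervals back to
    1-based inclusive plus-strand coordinates.
    """

    sequence: str          # uppercase RNA, tag orientation
    chrom: str
    strand: str
    genome_start: int      # 1-based inclusive bounds of the slice
    genome_end: int
    tag_offset: int        # 0-based offset of the tag in `sequence`
    tag_length: int
    truncated_upstream: bool
    truncated_downstream: bool

    def to_genomic(self, lo: int, hi: int) -> tuple[int, int]:
        """Window half-open interval [lo, hi) -> genomic (start, end)."""
        if self.strand == "+":
            return self.genome_start + lo, self.genome_start + hi - 1
        return self.genome_end - hi + 1, self.genome_end - lo


@dataclass(frozen=True)
class StarPlacement:
    """Accepted rc-tag alignment: the candidate star arm in window coords."""

    alignment: LocalAlignment
    start: int            # window coordinates, half-open
    end: int


@dataclass(frozen=True)
class DuplexEvaluation:
    """Verdicts of the three duplex acceptance criteria."""

    n_mismatches: int
    bulges: tuple[tuple[str, int], ...]   # (arm with extra bases, size)
    criterion_i: bool
    criterion_ii: bool
    criterion_iii: bool

    @property
    def accepted(self) -> bool:
        return self.criterion_i and self.criterion_ii and self.criterion_iii


@dataclass
class MatureRecord:
    """One sequenced arm (or end-variant) observed at a precursor."""

    sequence: str
    offset: int            # 0-based within the precursor
    arm: str               # '5p' or '3p'
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class PrecursorCandidate:
    """An accepted hairpin locus (1-based inclusive genome coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str
    precursor: str                     # uppercase RNA, 5'->3'
    matures: list[MatureRecord]
    star_offset: int
    star_arm: str
    fold: FoldStructure
    duplex: DuplexEvaluation
    context: str = "intergenic"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def mature(self) -> MatureRecord:
        """Highest-count sequenced arm."""
        return max(self.matures, key=lambda m: (sum(m.counts.values()), m.sequence))


def extract_flanks(
    hit: GenomeHit,
    index: GenomeIndex,
    flank_length: int = 200,
) -> FlankWindow:
    """Window of up to ``flank_length`` nt on each side of a hit."""
    chrom_len = len(index.chromosomes[hit.chrom])
    start = max(1, hit.start - flank_length)
    end = min(chrom_len, hit.end + flank_length)
    window_dna = index.slice(hit.chrom, start, end)
    if hit.strand == "+":
        seq = to_rna(window_dna)
        tag_offset = hit.start - start
    else:
        seq = revcomp_rna(to_rna(window_dna))
        tag_offset = end - hit.end
    trunc_up = (hit.start - flank_length) < 1
    trunc_down = (hit.end + flank_length) > chrom_len
    if hit.strand == "-":
        trunc_up, trunc_down = trunc_down, trunc_up
    return FlankWindow(
        sequence=seq,
        chrom=hit.chrom,
        strand=hit.strand,
        genome_start=start,
        genome_end=end,
        tag_offset=tag_offset,
        tag_length=hit.end - hit.start + 1,
        truncated_upstream=trunc_up,
        truncated_downstream=trunc_down,
    )


def locate_star(
    window: FlankWindow,
    tag_sequence: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> StarPlacement | None:
    """Best Smith-Waterman placement of the rc-tag outside the tag interval.

    Returns None when no alignment reaches the score floor
    (``star_min_score_frac`` of the perfect rc-tag score).
    """
    tag = to_rna(tag_sequence)
    t0 = window.tag_offset
    t1 = t0 + window.tag_length
    if window.sequence[t0:t1] != tag:
        raise RuntimeError("window does not contain the tag at its offset")
    rc_tag = revcomp_rna(tag)
    floor = config.star_min_score_frac * config.sw_match * len(tag)

    best: StarPlacement | None = None
    segments = [(0, window.sequence[:t0]), (t1, window.sequence[t1:])]
    for shift, segment in segments:
        if not segment:
            continue
        aln = smith_waterman(rc_tag, segment, config.sw_scoring)
        if aln.is_empty or aln.score < floor:
            continue
        placement = StarPlacement(
            alignment=aln,
            start=shift + aln.subject_start,
            end=shift + aln.subject_end,
        )
        if best is None or aln.score > best.alignment.score:
            best = placement
    return best


def _terminal_loop(
    fold: FoldStructure,
    mature: tuple[int, int],
    star: tuple[int, int],
) -> tuple[int, int] | None:
    """Unpaired region (half-open) of the hairpin loop between the arms."""
    loops = fold.hairpin_loops()
    if not loops:
        return None
    gap_lo = min(mature[1], star[1])
    gap_hi = max(mature[0], star[0])

    def overlap(pair: tuple[int, int]) -> int:
        i, j = pair
        return max(0, min(j - 1, gap_hi - 1) - max(i + 1, gap_lo) + 1)

    best = max(loops, key=lambda p: (overlap(p), -p[0]))
    if overlap(best) == 0:
        # fall back to the innermost loop of the longest stem
        best = max(loops, key=lambda p: p[0])
    i, j = best
    return (i + 1, j)


def evaluate_duplex(
    fold: FoldStructure,
    mature: tuple[int, int],
    star: tuple[int, int],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> DuplexEvaluation:
    """Apply the three acceptance criteria to a mature/star duplex.

    ``mature`` and ``star`` are half-open intervals on the folded
    sequence.  The evaluation is symmetric in its two interval
    arguments.
    """
    n = len(fold.sequence)
    for name, (a, b) in (("mature", mature), ("star", star)):
        if not (0 <= a < b <= n):
            raise ValueError(f"{name} interval {a, b} outside the precursor")

    loop = _terminal_loop(fold, mature, star)
    if loop is None:
        crit_i = False
        midpoint = n / 2
        loop_iv = (n, n)
    else:
        loop_iv = loop
        midpoint = (loop[0] + loop[1] - 1) / 2
        crit_i = True

    def side_ok(iv: tuple[int, int]) -> str | None:
        a, b = iv
        if b <= loop_iv[0] and (b - 1) < midpoint:
            return "5p"
        if a >= loop_iv[1] and a > midpoint:
            return "3p"
        return None

    if crit_i:
        side_m, side_s = side_ok(mature), side_ok(star)
        crit_i = side_m is not None and side_s is not None and side_m != side_s

    partner = fold.partner
    star_set = set(range(*star))
    mism = 0
    duplex_pairs = []
    for p in range(*mature):
        q = partner.get(p)
        if q is None or q not in star_set:
            mism += 1
        elif not config.gu_pairs_in_duplex and is_gu(fold.sequence[p], fold.sequence[q]):
            mism += 1
        else:
            duplex_pairs.append((p, q))
    crit_ii = mism <= config.max_duplex_mismatches

    duplex_pairs.sort()
    bulges: list[tuple[str, int]] = []
    for (p1, q1), (p2, q2) in zip(duplex_pairs, duplex_pairs[1:]):
        gap_m = p2 - p1 - 1
        gap_s = abs(q2 - q1) - 1
        if gap_m != gap_s:
            arm = "mature" if gap_m > gap_s else "star"
            bulges.append((arm, abs(gap_m - gap_s)))
    crit_iii = len(bulges) <= config.max_asym_bulges and all(
        size <= config.max_bulge_size for _arm, size in bulges
    )

    return DuplexEvaluation(
        n_mismatches=mism,
        bulges=tuple(bulges),
        criterion_i=bool(crit_i),
        criterion_ii=bool(crit_ii),
        criterion_iii=bool(crit_iii),
    )


def _candidate_from_hit(
    tag: Tag,
    hit: GenomeHit,
    index: GenomeIndex,
    config: PipelineConfig,
) -> PrecursorCandidate | None:
    window = extract_flanks(hit, index, config.flank_length)
    star = locate_star(window, tag.sequence, config)
    if star is None:
        return None
    t0 = window.tag_offset
    t1 = t0 + window.tag_length
    lo = min(t0, star.start)
    hi = max(t1, star.end)
    precursor = window.sequence[lo:hi]
    if len(precursor) < config.min_loop + 2:
        return None
    fold = fold_hairpin(precursor, min_loop=config.min_loop)
    mature_iv = (t0 - lo, t1 - lo)
    star_iv = (star.start - lo, star.end - lo)
    verdict = evaluate_duplex(fold, mature_iv, star_iv, config)
    if not verdict.accepted:
        return None
    loop = _terminal_loop(fold, mature_iv, star_iv)
    mature_arm = "5p" if loop is None or mature_iv[1] <= loop[0] else "3p"
    star_arm = "3p" if mature_arm == "5p" else "5p"
    g_start, g_end = window.to_genomic(lo, hi)
    return PrecursorCandidate(
        chrom=hit.chrom,
        start=g_start,
        end=g_end,
        strand=hit.strand,
        precursor=precursor,
        matures=[
            MatureRecord(tag.sequence, mature_iv[0], mature_arm, dict(tag.counts))
        ],
        star_offset=star_iv[0],
        star_arm=star_arm,
        fold=fold,
        duplex=verdict,
        context="intergenic",
    )


def _merge(cands: list[PrecursorCandidate]) -> list[PrecursorCandidate]:
    """Merge candidates at one locus (mature and star both sequenced,
    end-variants of the same arm) into a single record."""
    merged: list[PrecursorCandidate] = []
    for cand in sorted(cands, key=lambda c: (c.chrom, c.start, c.end, c.strand)):
        host = None
        for m in merged:
            if (
                m.chrom == cand.chrom
                and m.strand == cand.strand
                and min(m.end, cand.end) - max(m.start, cand.start) + 1
                >= 0.5 * min(m.length, cand.length)
            ):
                host = m
                break
        if host is None:
            merged.append(cand)
            continue
        # keep the widest precursor as the representative
        if cand.length > host.length:
            cand.matures = host.matures + cand.matures
            merged[merged.index(host)] = cand
            host = cand
        else:
            for rec in cand.matures:
                pos = host.precursor.find(rec.sequence)
                host.matures.append(
                    replace(rec, offset=pos if pos >= 0 else rec.offset)
                )
    for m in merged:
        m.matures.sort(key=lambda r: (r.offset, r.sequence))
    return merged


def discover(
    mapped: list[tuple[Tag, list[GenomeHit]]],
    index: GenomeIndex,
    annotation: list[Feature] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[PrecursorCandidate]:
    """Full per-hit chain extract -> locate star -> fold -> evaluate.

    Returns accepted candidates only, merged per locus and ordered by
    genomic coordinate.
    """
    cands: list[PrecursorCandidate] = []
    for tag, hits in mapped:
        for hit in hits:
            try:
                cand = _candidate_from_hit(tag, hit, index, config)
            except Exception:  # pragma: no cover - per-candidate robustness
                log.exception("candidate evaluation failed for %s @ %s:%d",
                              tag.sequence, hit.chrom, hit.start)
                continue
            if cand is not None:
                cands.append(cand)
    merged = _merge(cands)
    if annotation:
        for cand in merged:
            cand.context = label_context(annotation, cand.chrom, cand.start, cand.end)
    return merged
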