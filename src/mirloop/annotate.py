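"""Classification against known-miRNA catalogs, naming, isomiR grouping.

Accepted precursors are partitioned into novelty classes by comparing
their mature products with a same-species catalog and a catalog of other
plant species (miRBase-style FASTA, ids like ``gma-miR156d``).  Novel
families receive provisional SeqNN names with letter suffixes for
multiple loci and -5p/-3p arm suffixes when both arms of one precursor
were sequenced.  End-variants of one mature (isomiRs) are summarized
with the ``+n5/CORE/+n3`` pattern notation: the maximal common core and
the largest extra extension observed on each end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from ._seq import to_rna
from .discovery import PrecursorCandidate
from .io import read_fasta

log = logging.getLogger(__name__)


class NoveltyClass(Enum):
    NOVEL_FAMILY = "novel_family"
    CONSERVED_OTHER_SPECIES = "conserved_other_species"
    NEW_MEMBER_KNOWN_FAMILY = "new_member_known_family"
    ANTISENSE_ARM_OF_KNOWN = "antisense_arm_of_known"
    KNOWN = "known"
    ISOFORM = "isoform"


@dataclass
class MiRNARecord:
    """One mature product at one locus, with its classification."""

    mature: str                      # uppercase RNA
    arm: str                         # '5p' or '3p'
    chrom: str
    start: int
    end: int
    strand: str
    novelty_class: NoveltyClass
    candidate: PrecursorCandidate
    matched_id: str | None = None    # catalog id that triggered the class
    record_id: str | None = None     # assigned by assign_names
    family: str | None = None
    letter: str = ""
    arm_suffix: str = ""

    @property
    def first_nucleotide(self) -> str:
        return self.mature[0]


def load_catalog(path: str | Path) -> dict[str, str]:
    """miRBase-style FASTA -> {id: uppercase RNA sequence}."""
    return {name: to_rna(seq) for name, seq in read_fasta(path).items()}


def _species(catalog_id: str) -> str:
    return catalog_id.split("-", 1)[0].lower()


def _hamming(a: str, b: str) -> int | None:
    if len(a) != len(b):
        return None
    return sum(x != y for x, y in zip(a, b))


def _end_shifted(a: str, b: str, max_shift: int = 4) -> bool:
    """Whether two sequences are 5'/3' end-variants of one another
    (one is obtained from the other by trimming/extending the ends:
    they share a common core covering most of both)."""
    if a == b:
        return False
    shorter, longer = sorted((a, b), key=len)
    for off in range(len(longer) - len(shorter) + 1):
        if longer[off : off + len(shorter)] == shorter:
            return True
    # same length, shifted register: compare overlaps
    if len(a) == len(b):
        for s in range(1, max_shift + 1):
            if a[s:] == b[: len(b) - s] or b[s:] == a[: len(a) - s]:
                return True
    return False


def classify(
    candidates: list[PrecursorCandidate],
    soybean_mature: dict[str, str] | None = None,
    soybean_hairpin: dict[str, str] | None = None,
    other_species_mature: dict[str, str] | None = None,
    max_family_substitutions: int = 2,
) -> list[MiRNARecord]:
    """Partition the mature products of accepted precursors into classes.

    Priority: exact mature match at a catalog locus -> KNOWN; mature on
    the opposite arm of a known precursor -> ANTISENSE_ARM_OF_KNOWN;
    identical/near-identical mature at a new locus -> NEW_MEMBER;
    identical to a non-soybean plant entry -> CONSERVED_OTHER_SPECIES;
    an end-shifted variant of an already-assigned mature -> ISOFORM;
    everything else -> NOVEL_FAMILY.
    """
    gma_mature = {k: v for k, v in (soybean_mature or {}).items()}
    gma_hairpin = {k: v for k, v in (soybean_hairpin or {}).items()}
    other = {
        k: v for k, v in (other_species_mature or {}).items()
        if _species(k) != "gma"
    }

    records: list[MiRNARecord] = []
    for cand in candidates:
        by_arm: dict[str, list] = {}
        for m in cand.matures:
            by_arm.setdefault(m.arm, []).append(m)
        for arm, members in sorted(by_arm.items()):
            members.sort(key=lambda m: (-sum(m.counts.values()), m.sequence))
            representative, variants = members[0], members[1:]
            rec = _classify_one(
                representative.sequence, cand, arm,
                gma_mature, gma_hairpin, other,
                max_family_substitutions,
            )
            records.append(rec)
            # same-precursor end-shifts of the representative are isoforms
            for v in variants:
                records.append(
                    MiRNARecord(
                        mature=v.sequence, arm=arm, chrom=cand.chrom,
                        start=cand.start, end=cand.end, strand=cand.strand,
                        novelty_class=NoveltyClass.ISOFORM,
                        candidate=cand, matched_id=None,
                    )
                )
    return records


def _classify_one(
    seq, cand, arm, gma_mature, gma_hairpin, other, max_subs
) -> MiRNARecord:
    s = to_rna(seq)

    def make(cls, matched=None):
        return MiRNARecord(
            mature=s, arm=arm, chrom=cand.chrom, start=cand.start,
            end=cand.end, strand=cand.strand, novelty_class=cls,
            candidate=cand, matched_id=matched,
        )

    precursor = to_rna(cand.precursor)
    # KNOWN: catalog mature at a catalog locus (hairpin matches the precursor)
    for hid, hseq in gma_hairpin.items():
        if hseq in precursor or precursor in hseq:
            for mid, mseq in gma_mature.items():
                if mseq == s:
                    return make(NoveltyClass.KNOWN, mid)
            # opposite arm of a known precursor
            return make(NoveltyClass.ANTISENSE_ARM_OF_KNOWN, hid)
    # NEW_MEMBER: identical (or near-identical) mature at a new locus
    for mid, mseq in gma_mature.items():
        h = _hamming(s, mseq)
        if h is not None and h <= max_subs:
            return make(NoveltyClass.NEW_MEMBER_KNOWN_FAMILY, mid)
    for mid, mseq in other.items():
        if mseq == s:
            return make(NoveltyClass.CONSERVED_OTHER_SPECIES, mid)
    return make(NoveltyClass.NOVEL_FAMILY)


def assign_names(records: list[MiRNARecord], prefix: str = "gma-MIR-Seq") -> list[MiRNARecord]:
    """Name novel families SeqNN in coordinate order.

    Loci within one family are lettered a, b, ... by coordinate order;
    -5p/-3p is appended only when both arms of one precursor were
    observed.  Non-novel records keep their matched catalog id.
    """
    novel = [r for r in records if r.novelty_class is NoveltyClass.NOVEL_FAMILY]

    def locus_key(r: MiRNARecord):
        return (r.chrom, r.start, r.end)

    # One family = loci connected by a shared mature sequence; both arms of
    # one precursor always belong to the same family.
    parent: dict[tuple, tuple] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for r in novel:
        parent.setdefault(locus_key(r), locus_key(r))
    by_mature: dict[str, list[MiRNARecord]] = {}
    for r in novel:
        by_mature.setdefault(r.mature, []).append(r)
    for rs in by_mature.values():
        for a, b in zip(rs, rs[1:]):
            union(locus_key(a), locus_key(b))

    families: dict[tuple, list[MiRNARecord]] = {}
    for r in novel:
        families.setdefault(find(locus_key(r)), []).append(r)

    ordered = sorted(families.values(), key=lambda rs: min(locus_key(r) for r in rs))
    for number, members in enumerate(ordered, start=1):
        family = f"{prefix}{number:02d}"
        loci = sorted({locus_key(r) for r in members})
        letters = {locus: ("" if len(loci) == 1 else "abcdefghij"[i])
                   for i, locus in enumerate(loci)}
        by_locus: dict[tuple, list[MiRNARecord]] = {}
        for r in members:
            by_locus.setdefault(locus_key(r), []).append(r)
        for locus, recs in by_locus.items():
            arms = {r.arm for r in recs}
            for r in recs:
                r.family = family
                r.letter = letters[locus]
                r.arm_suffix = f"-{r.arm}" if len(arms) > 1 else ""
                r.record_id = f"{family}{r.letter}{r.arm_suffix}"
    for r in records:
        if r.novelty_class is not NoveltyClass.NOVEL_FAMILY and r.record_id is None:
            r.record_id = r.matched_id
    return records


@dataclass
class IsomirGroup:
    """All end-variants of one mature miRNA at one precursor."""

    precursor: str
    reference: str
    members: list[tuple[str, int]]       # (sequence, total count)
    core: str
    n5: int
    n3: int

    @property
    def n_isoforms(self) -> int:
        return len({seq for seq, _count in self.members})

    @property
    def pattern(self) -> str:
        out = self.core
        if self.n5:
            out = f"+{self.n5}/{out}"
        if self.n3:
            out = f"{out}/+{self.n3}"
        return out


def group_isomirs(
    members: list[tuple[str, int]],
    precursor: str,
    reference: str,
) -> IsomirGroup:
    """Summarize end-variants as the +n5/CORE/+n3 pattern.

    The core is the positional intersection of all members on the
    precursor; n5/n3 are the largest extensions observed beyond it.
    Members that are not substrings of the precursor are dropped with a
    warning.
    """
    placed = []
    for seq, count in members:
        pos = precursor.find(seq)
        if pos < 0:
            log.warning("isomiR member %s not a substring of the precursor", seq)
            continue
        placed.append((seq, count, pos, pos + len(seq)))
    if not placed:
        raise ValueError("no isomiR member is a substring of the precursor")
    core_start = max(p[2] for p in placed)
    core_end = min(p[3] for p in placed)
    if core_start >= core_end:
        raise ValueError("isomiR members share no common core on the precursor")
    n5 = max(core_start - p[2] for p in placed)
    n3 = max(p[3] - core_end for p in placed)
    return IsomirGroup(
        precursor=precursor,
        reference=reference,
        members=[(seq, count) for seq, count, _a, _b in placed],
        core=precursor[core_start:core_end],
        n5=n5,
        n3=n3,
    )
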