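"""Exact-match mapping of tags to both genome strands.

No mismatches are allowed; tags that map nowhere or to more than five
genomic loci are discarded.  The index is a simple seed hash of
fixed-length k-mers over the plus strand; minus-strand hits are found by
mapping the reverse complement and reported in plus-strand coordinates
with strand '-'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from ._seq import revcomp_dna, to_dna
from .config import DEFAULT_CONFIG, PipelineConfig
from .tags import Tag

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenomeHit:
    """One exact genomic match of a tag (1-based inclusive coordinates)."""

    tag_sequence: str    # uppercase RNA
    chrom: str
    start: int
    end: int
    strand: str          # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end - self.start + 1 != len(self.tag_sequence):
            raise ValueError("hit span does not match tag length")


class GenomeIndex:
    """Exact substring lookup over both strands of a small genome."""

    def __init__(self, chromosomes: dict[str, str], seed_length: int = 19):
        self.chromosomes = {name: to_dna(seq) for name, seq in chromosomes.items()}
        self.seed_length = seed_length
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for name in sorted(self.chromosomes):
            seq = self.chromosomes[name]
            for pos in range(len(seq) - seed_length + 1):
                self._seeds.setdefault(seq[pos : pos + seed_length], []).append(
                    (name, pos)
                )

    @classmethod
    def from_fasta(cls, path: str | Path, seed_length: int = 19) -> "GenomeIndex":
        chroms: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in chroms:
                raise ValueError(f"duplicate chromosome id {rec.id!r}")
            chroms[rec.id] = str(rec.seq)
        return cls(chroms, seed_length=seed_length)

    def _plus_strand_occurrences(self, query_dna: str) -> list[tuple[str, int]]:
        """All 0-based plus-strand start positions of an exact match."""
        k = self.seed_length
        out = []
        if len(query_dna) >= k:
            for chrom, pos in self._seeds.get(query_dna[:k], ()):
                if self.chromosomes[chrom][pos : pos + len(query_dna)] == query_dna:
                    out.append((chrom, pos))
        else:  # below seed length: naive scan
            for chrom in sorted(self.chromosomes):
                seq = self.chromosomes[chrom]
                start = seq.find(query_dna)
                while start != -1:
                    out.append((chrom, start))
                    start = seq.find(query_dna, start + 1)
        return out

    def lookup(self, tag_sequence: str) -> list[GenomeHit]:
        """Exact hits of an RNA/DNA query on both strands.

        Ordered by (chromosome, start, strand); overlapping self-matches
        each count as distinct loci.
        """
        q = to_dna(tag_sequence)
        rna = tag_sequence.upper().replace("T", "U")
        hits = [
            GenomeHit(rna, chrom, pos + 1, pos + len(q), "+")
            for chrom, pos in self._plus_strand_occurrences(q)
        ]
        for chrom, pos in self._plus_strand_occurrences(revcomp_dna(q)):
            hits.append(GenomeHit(rna, chrom, pos + 1, pos + len(q), "-"))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand genomic DNA slice, 1-based inclusive."""
        return self.chromosomes[chrom][start - 1 : end]


def build_index(genome_fasta: str | Path, seed_length: int = 19) -> GenomeIndex:
    """Build the exact-match index from a genome FASTA file."""
    return GenomeIndex.from_fasta(genome_fasta, seed_length=seed_length)


def map_and_filter(
    tags: Iterable[Tag],
    index: GenomeIndex,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[tuple[Tag, list[GenomeHit]]]:
    """Map tags and drop those with zero or too many genomic matches.

    Matches are counted over both strands combined against the
    ``max_genome_hits`` ceiling.
    """
    kept: list[tuple[Tag, list[GenomeHit]]] = []
    n_unmapped = n_repetitive = 0
    for tag in tags:
        hits = index.lookup(tag.sequence)
        if not hits:
            n_unmapped += 1
            log.debug("tag %s: no genomic match, dropped", tag.sequence)
            continue
        if len(hits) > config.max_genome_hits:
            n_repetitive += 1
            log.debug("tag %s: %d matches (> %d), dropped",
                      tag.sequence, len(hits), config.max_genome_hits)
            continue
        kept.append((tag, hits))
    if n_unmapped or n_repetitive:
        log.info("mapping dropped %d unmapped and %d repetitive tags",
                 n_unmapped, n_repetitive)
    return kept


def write_hits_bed(
    mapped: Iterable[tuple[Tag, list[GenomeHit]]],
    path: str | Path,
) -> None:
    """Write hits as BED (half-open on disk; name=tag, score=total count)."""
    with open(path, "w") as fh:
        for tag, hits in mapped:
            for h in hits:
                fh.write(
                    f"{h.chrom}\t{h.start - 1}\t{h.end}\t{tag.sequence}\t"
                    f"{tag.total_count}\t{h.strand}\n"
                )
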