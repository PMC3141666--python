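"""Read collapsing and tag filtering.

Adapter-trimmed small-RNA reads are collapsed into unique *tags* with
per-library read counts.  Tags with total count <= 2 and tags outside
the 19-24 nt window are discarded before mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from ._seq import RNA_ALPHABET, to_rna
from .config import DEFAULT_CONFIG, PipelineConfig

log = logging.getLogger(__name__)


@dataclass
class Tag:
    """A unique small-RNA sequence with per-library read counts."""

    sequence: str                      # uppercase RNA
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


def collapse_reads(reads: Iterable[tuple[str, str]]) -> list[Tag]:
    """Collapse ``(sequence, library_id)`` records into counted tags.

    Sequences are normalized to uppercase RNA (T -> U); records with
    characters outside ACGT/ACGU are skipped with a warning.  The
    result is ordered lexicographically by sequence.
    """
    table: dict[str, dict[str, int]] = {}
    skipped = 0
    for seq, lib in reads:
        rna = to_rna(seq)
        if not set(rna) <= RNA_ALPHABET:
            skipped += 1
            continue
        counts = table.setdefault(rna, {})
        counts[lib] = counts.get(lib, 0) + 1
    if skipped:
        log.warning("skipped %d reads with non-ACGU characters", skipped)
    return [Tag(seq, table[seq]) for seq in sorted(table)]


def filter_tags(
    tags: Iterable[Tag],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[Tag]:
    """Drop low-count tags and tags outside the length window.

    The count filter defaults to the pooled total across libraries;
    with ``config.per_library_counts`` a tag is kept if any single
    library reaches the threshold.
    """
    kept = []
    for tag in tags:
        if not (config.min_tag_length <= len(tag) <= config.max_tag_length):
            continue
        if config.per_library_counts:
            ok = any(c >= config.min_total_count for c in tag.counts.values())
        else:
            ok = tag.total_count >= config.min_total_count
        if ok:
            kept.append(tag)
    return kept


def read_reads_fasta(path: str | Path, library: str) -> Iterator[tuple[str, str]]:
    """Yield (sequence, library) from a FASTA file of trimmed reads."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield str(rec.seq), library


def read_reads_fastq(path: str | Path, library: str) -> Iterator[tuple[str, str]]:
    """Yield (sequence, library) from a FASTQ file; qualities are ignored."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq), library


def read_collapsed_tsv(path: str | Path) -> list[Tag]:
    """Load tags from a collapsed TSV (columns: sequence, library, count)."""
    table: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["sequence", "library", "count"]:
            raise ValueError(f"unexpected collapsed-TSV header: {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            seq, lib, count = fields
            counts = table.setdefault(to_rna(seq), {})
            counts[lib] = counts.get(lib, 0) + int(count)
    return [Tag(seq, table[seq]) for seq in sorted(table)]


def write_collapsed_tsv(tags: Iterable[Tag], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tlibrary\tcount\n")
        for tag in tags:
            for lib in sorted(tag.counts):
                fh.write(f"{tag.sequence}\t{lib}\t{tag.counts[lib]}\n")
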