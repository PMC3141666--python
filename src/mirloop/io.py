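"""On-disk formats: FASTA (60-column wrap), FASTQ, GFF3 and TSV reports.

GFF3 coordinates are 1-based inclusive; BED written elsewhere is
half-open, as documented in :mod:`mirloop.mapping`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Feature:
    """A minimal genomic annotation feature (1-based inclusive)."""

    chrom: str
    type: str           # gene, exon, CDS, five_prime_UTR, ...
    start: int
    end: int
    strand: str = "+"
    attributes: str = "."


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (read_id, sequence) pairs with dummy maximal qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_gff3(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            feats.append(Feature(chrom, ftype, int(start), int(end), strand, attrs))
    return feats


def write_gff3(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.chrom}\tmirloop\t{f.type}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{f.attributes}\n"
            )


def label_context(features: Iterable[Feature], chrom: str, start: int, end: int) -> str:
    """Genomic context of an interval: CDS, 5'UTR, intronic or intergenic.

    An interval overlapping a CDS/exon is labelled CDS; one inside a gene
    but outside its exons is intronic; 5' UTR overlap wins over intronic.
    """
    in_gene = in_exon = in_utr = False
    for f in features:
        if f.chrom != chrom or f.end < start or f.start > end:
            continue
        if f.type in ("CDS", "exon"):
            in_exon = True
        elif f.type == "five_prime_UTR":
            in_utr = True
        elif f.type in ("gene", "mRNA"):
            in_gene = True
    if in_exon:
        return "CDS"
    if in_utr:
        return "5'UTR"
    if in_gene:
        return "intronic"
    return "intergenic"
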