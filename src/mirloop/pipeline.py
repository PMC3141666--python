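"""End-to-end orchestration: collapse -> filter -> map -> discover -> annotate.

``run_pipeline`` wires the stages together, writes every stage's output
in a re-loadable text format and records a manifest with the full
configuration snapshot, input digests and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotate import MiRNARecord, assign_names, classify, load_catalog
from .config import PipelineConfig
from .discovery import PrecursorCandidate, discover
from .io import read_gff3
from .mapping import build_index, map_and_filter, write_hits_bed
from .qpcr import expression_report, read_ct_tsv, significance_labels
from .tags import (
    collapse_reads,
    filter_tags,
    read_collapsed_tsv,
    read_reads_fasta,
    read_reads_fastq,
    write_collapsed_tsv,
)
from .targets import scan_targets, write_targets_tsv

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]          # path -> sha256
    seed: int | None
    counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    failed_stage: str | None = None

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config_file(path: str | Path) -> PipelineConfig:
    """Read a YAML key-value file mirroring PipelineConfig field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def write_candidates_tsv(candidates: list[PrecursorCandidate], path: str | Path) -> None:
    """Candidate report: one row per sequenced arm, plus the structure."""
    cols = ["mature_sequence", "size", "chromosome", "start", "end", "length",
            "sense", "arm", "region", "precursor", "dot_bracket"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            for m in c.matures:
                fh.write("\t".join(map(str, [
                    m.sequence, len(m.sequence), c.chrom, c.start, c.end,
                    c.length, c.strand, m.arm, c.context, c.precursor,
                    c.fold.dot_bracket,
                ])) + "\n")


def write_records_tsv(records: list[MiRNARecord], path: str | Path) -> None:
    cols = ["record_id", "class", "mature_sequence", "size", "chromosome",
            "start", "end", "sense", "arm", "matched_id"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join(map(str, [
                r.record_id or "", r.novelty_class.value, r.mature,
                len(r.mature), r.chrom, r.start, r.end, r.strand, r.arm,
                r.matched_id or "",
            ])) + "\n")


def run_pipeline(
    output_dir: str | Path,
    genome_fasta: str | Path,
    read_files: list[tuple[str, str]] | None = None,     # (path, library)
    collapsed_tsv: str | Path | None = None,
    annotation_gff: str | Path | None = None,
    soybean_mature_fasta: str | Path | None = None,
    soybean_hairpin_fasta: str | Path | None = None,
    other_mature_fasta: str | Path | None = None,
    transcripts_fasta: str | Path | None = None,
    ct_tsv: str | Path | None = None,
    reference_genes: list[str] | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Execute the full discovery chain and write all reports.

    Returns the manifest; on a stage failure the partial outputs are
    retained and the manifest records the failed stage before the
    exception propagates.
    """
    config = config or PipelineConfig()
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = {}
    for p in [genome_fasta, collapsed_tsv, annotation_gff, soybean_mature_fasta,
              soybean_hairpin_fasta, other_mature_fasta, transcripts_fasta, ct_tsv]:
        if p is not None:
            inputs[str(p)] = _digest(p)
    for p, _lib in read_files or []:
        inputs[str(p)] = _digest(p)

    manifest = RunManifest(config=config.to_dict(), inputs=inputs, seed=seed)
    stage = "collapse"
    try:
        reads = []
        for path, lib in read_files or []:
            reader = read_reads_fastq if str(path).endswith(("fastq", "fq")) else read_reads_fasta
            reads.extend(reader(path, lib))
        tags = collapse_reads(reads)
        if collapsed_tsv is not None:
            tags = _merge_tags(tags, read_collapsed_tsv(collapsed_tsv))
        manifest.counts["tags_in"] = len(tags)

        stage = "filter"
        kept = filter_tags(tags, config)
        manifest.counts["tags_filtered"] = len(kept)
        write_collapsed_tsv(kept, outdir / "tags.tsv")

        stage = "map"
        index = build_index(genome_fasta)
        mapped = map_and_filter(kept, index, config)
        manifest.counts["tags_mapped"] = len(mapped)
        manifest.counts["hits"] = sum(len(h) for _t, h in mapped)
        write_hits_bed(mapped, outdir / "hits.bed")

        stage = "discover"
        annotation = read_gff3(annotation_gff) if annotation_gff else None
        candidates = discover(mapped, index, annotation, config)
        manifest.counts["accepted_precursors"] = len(candidates)
        write_candidates_tsv(candidates, outdir / "candidates.tsv")

        stage = "annotate"
        records = classify(
            candidates,
            load_catalog(soybean_mature_fasta) if soybean_mature_fasta else None,
            load_catalog(soybean_hairpin_fasta) if soybean_hairpin_fasta else None,
            load_catalog(other_mature_fasta) if other_mature_fasta else None,
        )
        assign_names(records)
        for r in records:
            key = f"class_{r.novelty_class.value}"
            manifest.counts[key] = manifest.counts.get(key, 0) + 1
        write_records_tsv(records, outdir / "records.tsv")

        if transcripts_fasta is not None:
            stage = "targets"
            from .io import read_fasta

            transcripts = read_fasta(transcripts_fasta)
            predictions = []
            for r in records:
                if r.record_id and r.novelty_class.value != "isoform":
                    predictions.extend(
                        scan_targets(r.mature, transcripts, config, r.record_id)
                    )
            manifest.counts["target_sites"] = len(predictions)
            write_targets_tsv(predictions, outdir / "targets.tsv")

        if ct_tsv is not None:
            stage = "qpcr"
            ct = read_ct_tsv(ct_tsv)
            genes = sorted(set(ct["gene"]))
            refs = reference_genes or [g for g in genes if g.lower().startswith("ref")]
            if not refs:
                raise ValueError("no reference genes given or recognisable")
            targets_q = [g for g in genes if g not in refs]
            report = expression_report(ct, targets_q, refs, config)
            report.to_csv(outdir / "qpcr.tsv", sep="\t", index=False)
            significance_labels(report).to_csv(
                outdir / "qpcr_labels.tsv", sep="\t", index=False
            )
            manifest.counts["qpcr_comparisons"] = len(report)
    except Exception:
        manifest.failed_stage = stage
        manifest.save(outdir / "manifest.json")
        raise
    manifest.save(outdir / "manifest.json")
    return manifest


def _merge_tags(a, b):
    by_seq = {t.sequence: t for t in a}
    for t in b:
        if t.sequence in by_seq:
            host = by_seq[t.sequence]
            for lib, c in t.counts.items():
                host.counts[lib] = host.counts.get(lib, 0) + c
        else:
            by_seq[t.sequence] = t
    return [by_seq[s] for s in sorted(by_seq)]
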