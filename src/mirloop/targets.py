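"""Complementarity-based miRNA target prediction.

An ungapped window of miRNA length slides along each transcript; the
miRNA is paired antiparallel to the window and each position classified
as Watson-Crick, G:U wobble or mismatch.  A site is reported when
mismatch_weight * mismatches + gu_weight * wobbles does not exceed the
cutoff (default 3.0 with weights 1 and 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._seq import to_rna
from .config import DEFAULT_CONFIG, PipelineConfig
from .pairing import render_pairing, score_pairing_string

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetPrediction:
    mirna_id: str
    transcript_id: str
    window_start: int       # 1-based position on the transcript
    pairing: str
    score: float
    reported: bool


def scan_targets(
    mirna: str,
    transcripts: dict[str, str],
    config: PipelineConfig = DEFAULT_CONFIG,
    mirna_id: str = "query",
) -> list[TargetPrediction]:
    """All passing target sites of one mature miRNA in a transcript set.

    Within each transcript the best-scoring window is reported first,
    then remaining passing windows by position; transcripts are visited
    in id order.  Transcripts shorter than the miRNA are skipped with a
    warning.
    """
    m = to_rna(mirna)
    if not (config.min_tag_length <= len(m) <= config.max_tag_length):
        raise ValueError(
            f"miRNA length {len(m)} outside {config.min_tag_length}-"
            f"{config.max_tag_length} nt"
        )
    out: list[TargetPrediction] = []
    for tid in sorted(transcripts):
        seq = to_rna(transcripts[tid])
        if len(seq) < len(m):
            log.warning("transcript %s shorter than the miRNA, skipped", tid)
            continue
        found = []
        for start in range(len(seq) - len(m) + 1):
            window = seq[start : start + len(m)]
            pairing = render_pairing(m, window[::-1])
            score = score_pairing_string(
                pairing, config.mismatch_weight, config.gu_weight
            )
            if _passes(score, config):
                found.append(
                    TargetPrediction(mirna_id, tid, start + 1, pairing, score, True)
                )
        found.sort(key=lambda p: (p.score, p.window_start))
        out.extend(found)
    return out


def _passes(score: float, config: PipelineConfig) -> bool:
    if config.cutoff_strict_less:
        return score < config.target_score_cutoff
    return score <= config.target_score_cutoff


def write_targets_tsv(predictions: list[TargetPrediction], path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttranscript_id\twindow_start\tpairing\tscore\n")
        for p in predictions:
            fh.write(
                f"{p.mirna_id}\t{p.transcript_id}\t{p.window_start}\t"
                f"{p.pairing}\t{p.score:g}\n"
            )
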