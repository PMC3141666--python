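"""Pipeline-wide thresholds and scoring parameters.

The defaults hold the constants of the discovery protocol: tags with total
read count <= 2 are discarded, the mature length window is 19-24 nt, 200 bp
of genomic flank is taken on each side of a mapped tag, tags with more than
five genomic matches are dropped, the mature/star duplex tolerates at most
four mismatches and one asymmetric bulge of at most two bases, and target
sites are reported when mismatch*1.0 + wobble*0.5 <= 3.0.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class PipelineConfig:
    # tag filtering
    min_total_count: int = 3            # keep tags with total count >= 3
    min_tag_length: int = 19
    max_tag_length: int = 24
    per_library_counts: bool = False    # apply the count filter per library

    # genome mapping
    max_genome_hits: int = 5

    # precursor discovery
    flank_length: int = 200
    max_duplex_mismatches: int = 4
    max_asym_bulges: int = 1            # strict reading of the criteria: 0
    max_bulge_size: int = 2
    gu_pairs_in_duplex: bool = True     # G:U counts as paired, not a mismatch
    star_min_score_frac: float = 0.6    # SW floor as fraction of perfect score
    min_loop: int = 3

    # Smith-Waterman scoring (local alignment of the rc-tag)
    sw_match: int = 1
    sw_mismatch: int = -1
    sw_gap: int = -2

    # target prediction
    target_score_cutoff: float = 3.0
    mismatch_weight: float = 1.0
    gu_weight: float = 0.5
    cutoff_strict_less: bool = False    # use score < cutoff instead of <=

    # expression analysis
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_total_count < 0 or self.max_genome_hits < 0:
            raise ValueError("thresholds must be non-negative")
        if self.mismatch_weight <= 0 or self.gu_weight <= 0:
            raise ValueError("scoring weights must be positive")
        if self.min_tag_length > self.max_tag_length:
            raise ValueError("invalid tag length window")

    @property
    def sw_scoring(self) -> tuple[int, int, int]:
        return (self.sw_match, self.sw_mismatch, self.sw_gap)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


DEFAULT_CONFIG = PipelineConfig()
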