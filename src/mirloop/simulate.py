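"""Synthetic genomes with planted miRNA hairpins and simulated libraries.

The generator emulates the data the discovery pipeline was designed for:
a multi-chromosome genome carrying pre-miRNA hairpins whose mature/star
duplex has canonical 2-nt 3' overhangs, eight small-RNA libraries (two
genotypes x two conditions for each of two stress types) with optional
isomiR end-variation and random background degradation tags, and
condition-dependent abundance fold-changes with known truth.

Every planted hairpin is checked at generation time against the
package's own folding and duplex criteria and resampled until it is
criteria-compliant, so recovery by the discovery chain is guaranteed by
construction.  All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import pairs, revcomp_dna, revcomp_rna, to_dna
from .alignment import smith_waterman
from .config import DEFAULT_CONFIG, PipelineConfig
from .discovery import evaluate_duplex
from .folding import fold_hairpin
from .io import Feature

log = logging.getLogger(__name__)

#: The eight library labels: Drought Sensitive/Tolerant Root Control/Treated,
#: Rust Susceptible/Resistant Leaf Control/Treated.
LIBRARY_LABELS = ("DSRC", "DSRT", "DTRC", "DTRT", "RSLC", "RSLT", "RRLC", "RRLT")

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SyntheticConfig:
    seed: int = 7
    n_chromosomes: int = 3
    chrom_length: int = 20_000
    n_hairpins: int = 20
    mature_length_range: tuple[int, int] = (19, 24)
    precursor_length_range: tuple[int, int] = (55, 240)
    duplex_mismatch_range: tuple[int, int] = (0, 2)   # admissible domain [0, 4]
    max_bulges: int = 0
    max_bulge_size: int = 2
    library_labels: tuple[str, ...] = LIBRARY_LABELS
    isomir_shift_prob: float = 0.0
    background_tag_count: int = 30
    fold_change_map: dict = field(default_factory=dict)
    # abundance model
    mature_base_count: int = 90
    star_base_count: int = 12
    isomir_base_count: int = 9
    sampling: str = "exact"           # or "multinomial"
    # genome layout
    minus_strand_prob: float = 0.4
    genic_fraction: float = 0.25
    five_prime_u_bias: float = 0.8

    def __post_init__(self) -> None:
        lo, hi = self.precursor_length_range
        min_needed = 2 * self.mature_length_range[1] + 8
        if hi < min_needed:
            raise ValueError(
                f"precursor_length_range {self.precursor_length_range} too small "
                f"to host mature + star + loop (needs at least {min_needed})"
            )
        if set(self.library_labels) != set(LIBRARY_LABELS):
            raise ValueError(f"library_labels must be {LIBRARY_LABELS}")
        if not (0 <= self.duplex_mismatch_range[0] <= self.duplex_mismatch_range[1] <= 4):
            raise ValueError("duplex_mismatch_range must lie within [0, 4]")


@dataclass
class HairpinTruth:
    """Ground truth for one planted hairpin (1-based inclusive coords)."""

    hairpin_id: str
    chrom: str
    start: int
    end: int
    strand: str
    precursor: str          # uppercase RNA, 5'->3' on the hairpin strand
    mature: str
    mature_arm: str
    star: str
    star_arm: str
    n_mismatches: int
    context: str
    expected_mature_counts: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _rand_rna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _make_duplex(
    rng: np.random.Generator, config: SyntheticConfig
) -> tuple[str, str, str, str, int]:
    """One hairpin cassette: (precursor, mature, star, mature_arm, n_mm).

    The mature/star duplex pairs position i of the mature with position
    Lm-3-i of the star, leaving the canonical 2-nt 3' overhang on both
    strands; planted mismatches are interior and chosen so the substituted
    star base cannot pair with the mature partner or its neighbours.
    """
    lm = int(rng.integers(config.mature_length_range[0],
                          config.mature_length_range[1] + 1))
    p_lo, p_hi = config.precursor_length_range
    loop_min = max(8, p_lo - 2 * lm)
    loop_max = p_hi - 2 * lm
    loop_len = int(rng.integers(loop_min, loop_max + 1))

    first = "U" if rng.random() < config.five_prime_u_bias else "ACG"[rng.integers(0, 3)]
    mature = first + _rand_rna(rng, lm - 1)

    star = [_COMP[mature[lm - 3 - j]] for j in range(lm - 2)]
    star += list(_rand_rna(rng, 2))                       # star 3' overhang

    n_mm = int(rng.integers(config.duplex_mismatch_range[0],
                            config.duplex_mismatch_range[1] + 1))
    interior = list(range(3, lm - 5))
    rng.shuffle(interior)
    planted = 0
    for i in interior:
        if planted == n_mm:
            break
        j = lm - 3 - i
        neighbours = [mature[i]]
        if i > 0:
            neighbours.append(mature[i - 1])
        if i < lm - 1:
            neighbours.append(mature[i + 1])
        options = [
            b for b in "ACGU"
            if not any(pairs(nb, b) or pairs(b, nb) for nb in neighbours)
        ]
        if not options:
            continue
        star[j] = options[int(rng.integers(0, len(options)))]
        planted += 1

    star_seq = "".join(star)
    loop = _rand_rna(rng, loop_len)
    # The loop base 5' of the star must not extend the duplex complement,
    # otherwise the full reverse complement of the mature reappears two
    # positions upstream of the star and the mature no longer maps uniquely.
    blocked = _COMP[mature[lm - 2]]
    choices = [b for b in "ACGU" if b != blocked]
    loop = loop[:-1] + choices[int(rng.integers(0, 3))]
    if rng.random() < 0.5:
        return mature + loop + star_seq, mature, star_seq, "5p", planted
    return star_seq + loop + mature, mature, star_seq, "3p", planted


def _cassette_is_valid(
    precursor: str, mature: str, star: str, mature_arm: str, pcfg: PipelineConfig
) -> bool:
    """Re-check a cassette with the discovery machinery itself."""
    if mature_arm == "5p":
        mature_iv = (0, len(mature))
        star_iv = (len(precursor) - len(star), len(precursor))
    else:
        star_iv = (0, len(star))
        mature_iv = (len(precursor) - len(mature), len(precursor))
    fold = fold_hairpin(precursor, min_loop=pcfg.min_loop)
    if not evaluate_duplex(fold, mature_iv, star_iv, pcfg).accepted:
        return False
    # the rc-tag must be locatable above the discovery score floor
    rc = revcomp_rna(mature)
    segment = precursor[: star_iv[1]] if mature_arm == "3p" else precursor[star_iv[0]:]
    aln = smith_waterman(rc, segment, pcfg.sw_scoring)
    return aln.score >= pcfg.star_min_score_frac * pcfg.sw_match * len(mature)


def generate_genome_and_truth(
    config: SyntheticConfig,
    pipeline_config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[dict[str, str], list[HairpinTruth], list[Feature]]:
    """Generate the genome (DNA), planted-hairpin truth and annotation.

    Deterministic for a fixed ``config.seed``; minus-strand hairpins are
    inserted as reverse complements.  Raises a RuntimeError if unique
    placement cannot be achieved (vanishingly unlikely at default sizes).
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"Chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    genome = {name: list(_rand_dna(rng, config.chrom_length)) for name in chrom_names}

    truths: list[HairpinTruth] = []
    features: list[Feature] = []
    margin = 300
    per_chrom = -(-config.n_hairpins // config.n_chromosomes) if config.n_hairpins else 0
    usable = config.chrom_length - 2 * margin
    if config.n_hairpins and usable < per_chrom * 600:
        raise ValueError("chromosomes too short for the requested hairpin count")

    for h in range(config.n_hairpins):
        chrom = chrom_names[h % config.n_chromosomes]
        slot = h // config.n_chromosomes
        slot_width = usable // per_chrom

        for _attempt in range(60):
            precursor, mature, star, mature_arm, n_mm = _make_duplex(rng, config)
            if not _cassette_is_valid(precursor, mature, star, mature_arm, pipeline_config):
                continue
            offset = margin + slot * slot_width + int(
                rng.integers(0, max(1, slot_width - len(precursor) - 100))
            )
            strand = "-" if rng.random() < config.minus_strand_prob else "+"
            insert = to_dna(precursor) if strand == "+" else revcomp_dna(to_dna(precursor))
            # the mature must map uniquely: once inside its own cassette and
            # nowhere else in the genome built so far
            dna_m, rc_m = to_dna(mature), revcomp_dna(to_dna(mature))
            if insert.count(dna_m) + insert.count(rc_m) != 1:
                continue
            current = {name: "".join(seq) for name, seq in genome.items()}
            if any(dna_m in s or rc_m in s for s in current.values()):
                continue
            genome[chrom][offset : offset + len(insert)] = list(insert)
            truths.append(
                HairpinTruth(
                    hairpin_id=f"hp{h + 1:02d}",
                    chrom=chrom,
                    start=offset + 1,
                    end=offset + len(precursor),
                    strand=strand,
                    precursor=precursor,
                    mature=mature,
                    mature_arm=mature_arm,
                    star=star,
                    star_arm="3p" if mature_arm == "5p" else "5p",
                    n_mismatches=n_mm,
                    context="intergenic",
                )
            )
            break
        else:  # pragma: no cover
            raise RuntimeError(f"could not generate a valid hairpin for slot {h}")

    genome_str = {name: "".join(seq) for name, seq in genome.items()}

    # uniqueness of every planted mature across both strands
    for t in truths:
        dna = to_dna(t.mature)
        occurrences = sum(
            seq.count(dna) + seq.count(revcomp_dna(dna)) for seq in genome_str.values()
        )
        if occurrences != 1:
            raise RuntimeError(
                f"planted mature for {t.hairpin_id} occurs {occurrences} times"
            )

    # annotate a fraction of hairpins as genic to exercise context labels
    for t in truths:
        if rng.random() >= config.genic_fraction:
            continue
        gene_start = max(1, t.start - 150)
        gene_end = min(config.chrom_length, t.end + 150)
        features.append(Feature(t.chrom, "gene", gene_start, gene_end, t.strand))
        if rng.random() < 0.5:
            features.append(Feature(t.chrom, "CDS", t.start, t.end, t.strand))
            t.context = "CDS"
        else:
            # exons flanking the hairpin: the hairpin itself is intronic
            features.append(Feature(t.chrom, "exon", gene_start, t.start - 10, t.strand))
            features.append(Feature(t.chrom, "exon", t.end + 10, gene_end, t.strand))
            t.context = "intronic"

    # per-library expected mature counts from the fold-change map
    for t in truths:
        fc = config.fold_change_map.get(t.hairpin_id, {})
        t.expected_mature_counts = {
            lib: config.mature_base_count * float(fc.get(lib, 1.0))
            for lib in config.library_labels
        }

    return genome_str, truths, features


def _isomir_variants(
    rng: np.random.Generator, t: HairpinTruth, config: SyntheticConfig
) -> list[str]:
    """End-shifted variants of the mature, kept inside the precursor."""
    variants: list[str] = []
    pos = t.precursor.find(t.mature)
    lo, hi = config.mature_length_range
    for d5, d3 in ((-1, 0), (0, 1), (1, -1), (-2, 0), (0, 2)):
        if rng.random() >= config.isomir_shift_prob:
            continue
        a, b = pos + d5, pos + len(t.mature) + d3
        if a < 0 or b > len(t.precursor) or not (lo <= b - a <= hi):
            continue
        var = t.precursor[a:b]
        if var != t.mature:
            variants.append(var)
    return variants


def simulate_libraries(
    truth: list[HairpinTruth],
    config: SyntheticConfig,
    genome: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Simulate collapsed tag counts for the eight libraries.

    Returns a DataFrame with columns (sequence, library, count, origin)
    where origin is ``hpNN:mature``, ``hpNN:star``, ``hpNN:isomir`` or
    ``background``.  With ``sampling="exact"`` counts equal rounded
    expectations; with ``"multinomial"`` each library's counts are one
    multinomial draw with the expectations as weights.  Background tags
    are rejected if they match the genome on either strand, so they are
    guaranteed true negatives for mapping.
    """
    if not truth and config.background_tag_count == 0:
        raise ValueError("nothing to simulate: empty truth and no background tags")
    rng = np.random.default_rng(config.seed + 1)
    rows: list[tuple[str, str, float, str]] = []

    for t in truth:
        fc = config.fold_change_map.get(t.hairpin_id, {})
        isomirs = _isomir_variants(rng, t, config) if config.isomir_shift_prob > 0 else []
        for lib in config.library_labels:
            mult = float(fc.get(lib, 1.0))
            rows.append((t.mature, lib, config.mature_base_count * mult,
                         f"{t.hairpin_id}:mature"))
            rows.append((t.star, lib, config.star_base_count * mult,
                         f"{t.hairpin_id}:star"))
            for v in isomirs:
                rows.append((v, lib, config.isomir_base_count * mult,
                             f"{t.hairpin_id}:isomir"))

    n_background = 0
    attempts = 0
    while n_background < config.background_tag_count and attempts < 50 * max(
        1, config.background_tag_count
    ):
        attempts += 1
        seq = _rand_rna(rng, int(rng.integers(19, 25)))
        if genome is not None:
            dna = to_dna(seq)
            rc = revcomp_dna(dna)
            if any(dna in chrom or rc in chrom for chrom in genome.values()):
                continue
        lib = config.library_labels[n_background % len(config.library_labels)]
        count = (n_background % 6) + 1       # some fall under the count filter
        rows.append((seq, lib, float(count), "background"))
        n_background += 1

    df = pd.DataFrame(rows, columns=["sequence", "library", "expected", "origin"])
    if config.sampling == "exact":
        df["count"] = df["expected"].round().astype(int)
    elif config.sampling == "multinomial":
        counts = np.zeros(len(df), dtype=int)
        for lib in config.library_labels:
            mask = (df["library"] == lib).to_numpy()
            w = df.loc[mask, "expected"].to_numpy()
            if w.sum() <= 0:
                continue
            total = int(round(w.sum()))
            counts[mask] = rng.multinomial(total, w / w.sum())
        df["count"] = counts
    else:
        raise ValueError(f"unknown sampling mode {config.sampling!r}")
    df = df[df["count"] > 0].reset_index(drop=True)
    return df[["sequence", "library", "count", "origin"]]


def libraries_to_reads(df: pd.DataFrame) -> list[tuple[str, str]]:
    """Expand a simulated count table into (sequence, library) read records."""
    reads = []
    for row in df.itertuples(index=False):
        reads.extend([(row.sequence, row.library)] * int(row.count))
    return reads


def simulate_ct_table(
    target_genes: list[str],
    reference_genes: list[str],
    log2_fold_changes: dict[str, dict[str, float]],
    conditions: tuple[str, ...] = LIBRARY_LABELS,
    n_replicates: int = 3,
    noise_sd: float = 0.15,
    base_ct: float = 25.0,
    reference_ct: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a Ct table consistent with chosen per-condition fold-changes.

    A gene up-regulated by ``x`` log2 units in a condition has its Ct
    lowered by ``x`` there (one PCR cycle per doubling).  Gaussian noise
    of ``noise_sd`` cycles is added to every replicate measurement.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in list(target_genes) + list(reference_genes):
        is_ref = gene in reference_genes
        for cond in conditions:
            l2fc = 0.0 if is_ref else log2_fold_changes.get(gene, {}).get(cond, 0.0)
            centre = (reference_ct if is_ref else base_ct) - l2fc
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (gene, cond, rep, centre + rng.normal(0.0, noise_sd))
                )
    return pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])


def write_truth_tsv(truth: list[HairpinTruth], path) -> None:
    cols = ["hairpin_id", "chrom", "start", "end", "strand", "precursor",
            "mature", "mature_arm", "star", "star_arm", "n_mismatches", "context"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truth:
            fh.write("\t".join(str(getattr(t, c)) for c in cols) + "\n")
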