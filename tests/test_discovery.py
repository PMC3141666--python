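"""Flank extraction, star location, duplex criteria and full discovery."""

import numpy as np
import pytest

from mirloop._seq import revcomp_rna, to_rna
from mirloop.config import PipelineConfig
from mirloop.discovery import (
    evaluate_duplex,
    extract_flanks,
    locate_star,
)
from mirloop.folding import FoldStructure, fold_hairpin
from mirloop.mapping import GenomeHit, GenomeIndex


def _rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


class TestExtractFlanks:
    def test_hit_at_chromosome_start_truncates_upstream(self):
        rng = np.random.default_rng(1)
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        index = GenomeIndex({"c1": chrom})
        hit = GenomeHit(to_rna(chrom[:21]), "c1", 1, 21, "+")
        w = extract_flanks(hit, index, flank_length=200)
        assert w.tag_offset == 0
        assert w.truncated_upstream
        assert not w.truncated_downstream

    def test_mid_chromosome_window_length(self):
        rng = np.random.default_rng(2)
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        index = GenomeIndex({"c1": chrom})
        hit = GenomeHit(to_rna(chrom[400:421]), "c1", 401, 421, "+")
        w = extract_flanks(hit, index, flank_length=200)
        assert len(w.sequence) == 421  # 200 + 21 + 200
        assert w.tag_offset == 200

    def test_minus_strand_window_is_reverse_complemented(self):
        rng = np.random.default_rng(3)
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        index = GenomeIndex({"c1": chrom})
        tag = revcomp_rna(to_rna(chrom[400:421]))
        hit = GenomeHit(tag, "c1", 401, 421, "-")
        w = extract_flanks(hit, index, flank_length=50)
        assert w.sequence[w.tag_offset : w.tag_offset + 21] == tag

    def test_coordinates_roundtrip_through_the_window_map(self):
        rng = np.random.default_rng(4)
        chrom = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        index = GenomeIndex({"c1": chrom})
        for strand in "+-":
            seq = to_rna(chrom[400:421])
            tag = seq if strand == "+" else revcomp_rna(seq)
            hit = GenomeHit(tag, "c1", 401, 421, strand)
            w = extract_flanks(hit, index, flank_length=100)
            t0 = w.tag_offset
            g_start, g_end = w.to_genomic(t0, t0 + 21)
            assert (g_start, g_end) == (401, 421)


class TestLocateStar:
    def _window(self, sequence, tag):
        index = GenomeIndex({"c1": sequence.replace("U", "T")})
        pos = sequence.find(tag)
        hit = GenomeHit(tag, "c1", pos + 1, pos + len(tag), "+")
        return extract_flanks(hit, index, flank_length=400)

    def test_planted_perfect_star_found_at_truth_coordinates(self):
        rng = np.random.default_rng(5)
        tag = _rna(rng, 21)
        star = revcomp_rna(tag)
        window = _rna(rng, 40) + tag + _rna(rng, 30) + star + _rna(rng, 40)
        w = self._window(window, tag)
        placement = locate_star(w, tag)
        assert placement is not None
        assert (placement.start, placement.end) == (91, 112)

    def test_random_window_without_complementarity_gives_none(self):
        rng = np.random.default_rng(6)
        tag = "A" * 21
        window = "C" * 80 + tag + "C" * 80
        w = self._window(window, tag)
        assert locate_star(w, tag) is None

    def test_star_overlapping_only_the_tag_interval_is_excluded(self):
        # the only complementary stretch is the tag interval itself
        rng = np.random.default_rng(7)
        tag = _rna(rng, 21)
        window = "C" * 60 + tag + "C" * 60
        w = self._window(window, tag)
        assert locate_star(w, tag) is None

    def test_consistency_error_when_tag_absent(self):
        rng = np.random.default_rng(8)
        tag = _rna(rng, 21)
        window = self._window("C" * 50 + tag + "C" * 50, tag)
        with pytest.raises(RuntimeError):
            locate_star(window, "G" * 21)


def _perfect_hairpin(rng, lm=21, loop=12):
    mature = _rna(rng, lm)
    star = revcomp_rna(mature)
    precursor = mature + _rna(rng, loop) + star
    return precursor, (0, lm), (lm + loop, lm + loop + lm)


class TestEvaluateDuplex:
    def test_perfect_stem_accepted(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            precursor, mature, star = _perfect_hairpin(rng)
            fold = fold_hairpin(precursor)
            verdict = evaluate_duplex(fold, mature, star)
            assert verdict.criterion_i and verdict.criterion_ii and verdict.criterion_iii
            assert verdict.accepted
            assert verdict.n_mismatches == 0
            assert verdict.bulges == ()

    def test_five_unpaired_mature_positions_reject_criterion_ii(self):
        # hand-built fold: drop five of the duplex pairs
        mature = "GGGGGGGGGGGGGGGGGGGGG"
        star = "CCCCCCCCCCCCCCCCCCCCC"
        precursor = mature + "AAAAAAAAAAAA" + star
        n = len(precursor)
        pairs = tuple(
            (i, n - 1 - i) for i in range(5, 21)   # 16 pairs, 5 mature bases free
        )
        fold = FoldStructure(precursor, pairs, sum(3 for _ in pairs))
        verdict = evaluate_duplex(fold, (0, 21), (33, 54))
        assert verdict.n_mismatches == 5
        assert not verdict.criterion_ii
        assert not verdict.accepted

    def test_three_base_asymmetric_bulge_rejects_criterion_iii(self):
        mature = "G" * 21
        star = "C" * 24
        precursor = mature + "A" * 12 + star
        n = len(precursor)
        # pairs jump 3 extra star bases in the middle of the duplex
        pairs = []
        for i in range(21):
            j = n - 1 - i if i < 10 else n - 4 - i
            pairs.append((i, j))
        fold = FoldStructure(precursor, tuple(sorted(pairs)), 63)
        verdict = evaluate_duplex(fold, (0, 21), (33, 57))
        assert verdict.bulges == (("star", 3),)
        assert not verdict.criterion_iii
        assert not verdict.accepted

    def test_single_small_bulge_accepted_by_default_but_not_strict(self):
        mature = "G" * 21
        star = "C" * 23
        precursor = mature + "A" * 12 + star
        n = len(precursor)
        pairs = []
        for i in range(21):
            j = n - 1 - i if i < 10 else n - 3 - i
            pairs.append((i, j))
        fold = FoldStructure(precursor, tuple(sorted(pairs)), 63)
        assert evaluate_duplex(fold, (0, 21), (33, 56)).accepted
        strict = PipelineConfig(max_asym_bulges=0)
        assert not evaluate_duplex(fold, (0, 21), (33, 56), strict).accepted

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            precursor, mature, star = _perfect_hairpin(rng, lm=20, loop=15)
            fold = fold_hairpin(precursor)
            a = evaluate_duplex(fold, mature, star)
            b = evaluate_duplex(fold, star, mature)
            assert a.accepted == b.accepted
            assert a.criterion_i == b.criterion_i

    def test_interval_outside_precursor_rejected(self):
        rng = np.random.default_rng(11)
        precursor, mature, star = _perfect_hairpin(rng)
        fold = fold_hairpin(precursor)
        with pytest.raises(ValueError):
            evaluate_duplex(fold, (0, len(precursor) + 5), star)


class TestDiscoverOnTruth:
    def test_all_planted_hairpins_recovered_with_correct_mature(self, discovery_run):
        truth = discovery_run["truth"]
        candidates = discovery_run["candidates"]
        for t in truth:
            matches = [
                c for c in candidates
                if c.chrom == t.chrom and c.strand == t.strand
                and min(c.end, t.end) - max(c.start, t.start) > 0
            ]
            assert matches, f"{t.hairpin_id} not recovered"
            assert any(
                any(m.sequence == t.mature for m in c.matures) for c in matches
            ), f"mature of {t.hairpin_id} missing"

    def test_no_candidate_at_a_background_locus(self, discovery_run):
        truth = discovery_run["truth"]
        for c in discovery_run["candidates"]:
            assert any(
                c.chrom == t.chrom and min(c.end, t.end) - max(c.start, t.start) > 0
                for t in truth
            ), f"candidate at unplanted locus {c.chrom}:{c.start}-{c.end}"

    def test_reported_length_equals_coordinate_span(self, discovery_run):
        for c in discovery_run["candidates"]:
            assert c.length == c.end - c.start + 1 == len(c.precursor)

    def test_context_labels_match_truth(self, discovery_run):
        truth = {(t.chrom, t.strand): t for t in discovery_run["truth"]}
        for c in discovery_run["candidates"]:
            t = truth.get((c.chrom, c.strand))
            if t and min(c.end, t.end) - max(c.start, t.start) > 0:
                assert c.context == t.context
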