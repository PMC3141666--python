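"""Novelty classification, family naming and isomiR grouping."""

import numpy as np
import pytest

from mirloop._seq import revcomp_rna
from mirloop.annotate import (
    NoveltyClass,
    assign_names,
    classify,
    group_isomirs,
)
from mirloop.discovery import MatureRecord, PrecursorCandidate
from mirloop.folding import fold_hairpin


def _candidate(mature, chrom="Gm01", start=1000, arm="5p", loop="AAACAAACAAAC",
               counts=None, extra_matures=()):
    star = revcomp_rna(mature)
    precursor = mature + loop + star if arm == "5p" else star + loop + mature
    offset = 0 if arm == "5p" else len(star) + len(loop)
    fold = fold_hairpin(precursor)
    matures = [MatureRecord(mature, offset, arm, counts or {"L1": 50})]
    for seq, m_arm, m_counts in extra_matures:
        matures.append(MatureRecord(seq, max(0, precursor.find(seq)), m_arm, m_counts))
    from mirloop.discovery import DuplexEvaluation

    return PrecursorCandidate(
        chrom=chrom, start=start, end=start + len(precursor) - 1, strand="+",
        precursor=precursor, matures=matures, star_offset=len(precursor) - len(star),
        star_arm="3p" if arm == "5p" else "5p", fold=fold,
        duplex=DuplexEvaluation(0, (), True, True, True),
    )


MATURE = "UGACAGAAGAGAGUGAGCACA"          # 21 nt
OTHER = "UCAUUGAGUGCAGCGUUGAUG"           # 21 nt


class TestClassify:
    def test_known_requires_catalog_mature_at_catalog_locus(self):
        cand = _candidate(MATURE)
        records = classify(
            [cand],
            soybean_mature={"gma-miR156d": MATURE},
            soybean_hairpin={"gma-MIR156d": cand.precursor},
        )
        assert records[0].novelty_class is NoveltyClass.KNOWN
        assert records[0].matched_id == "gma-miR156d"

    def test_opposite_arm_of_known_precursor_is_antisense_class(self):
        cand = _candidate(MATURE)
        star_seq = revcomp_rna(MATURE)
        star_cand = _candidate(star_seq)
        records = classify(
            [star_cand],
            soybean_mature={"gma-miR156d": MATURE},
            soybean_hairpin={"gma-MIR156d": star_cand.precursor},
        )
        assert records[0].novelty_class is NoveltyClass.ANTISENSE_ARM_OF_KNOWN

    def test_identical_mature_at_new_locus_is_new_member(self):
        cand = _candidate(MATURE, loop="AAACAAACAAACAAA")  # precursor != catalog hairpin
        records = classify(
            [cand],
            soybean_mature={"gma-miR156d": MATURE},
            soybean_hairpin={"gma-MIR156d": "ACGU" * 30},
        )
        assert records[0].novelty_class is NoveltyClass.NEW_MEMBER_KNOWN_FAMILY

    def test_two_substitution_variant_is_new_member(self):
        variant = "UGACAGAAGAGAGUGAGCAGG"  # 2 subs vs MATURE
        cand = _candidate(variant)
        records = classify([cand], soybean_mature={"gma-miR156d": MATURE})
        assert records[0].novelty_class is NoveltyClass.NEW_MEMBER_KNOWN_FAMILY

    def test_non_soybean_catalog_match_is_conserved_other_species(self):
        cand = _candidate(OTHER)
        records = classify(
            [cand],
            soybean_mature={"gma-miR156d": MATURE},
            other_species_mature={"ath-miR397": OTHER},
        )
        assert records[0].novelty_class is NoveltyClass.CONSERVED_OTHER_SPECIES

    def test_unmatched_candidate_falls_through_to_novel(self):
        novel = "UUAGGCAUCGAUCCGAUAGGU"
        cand = _candidate(novel)
        records = classify(
            [cand],
            soybean_mature={"gma-miR156d": MATURE},
            other_species_mature={"ath-miR397": OTHER},
        )
        assert records[0].novelty_class is NoveltyClass.NOVEL_FAMILY

    def test_end_variants_at_one_precursor_are_isoforms(self):
        novel = "UUAGGCAUCGAUCCGAUAGGU"
        cand = _candidate(
            novel,
            extra_matures=((novel[1:] + "A", "5p", {"L1": 3}),),
        )
        records = classify([cand])
        classes = sorted(r.novelty_class.value for r in records)
        assert classes == ["isoform", "novel_family"]
        # the representative is the higher-count member
        rep = next(r for r in records if r.novelty_class is NoveltyClass.NOVEL_FAMILY)
        assert rep.mature == novel

    def test_classification_is_a_partition(self):
        cands = [_candidate(MATURE), _candidate(OTHER, start=5000)]
        records = classify(
            cands,
            soybean_mature={"gma-miR156d": MATURE},
            other_species_mature={"ath-miR397": OTHER},
        )
        assert len(records) == 2
        assert all(isinstance(r.novelty_class, NoveltyClass) for r in records)
        again = classify(
            cands,
            soybean_mature={"gma-miR156d": MATURE},
            other_species_mature={"ath-miR397": OTHER},
        )
        assert [r.novelty_class for r in records] == [r.novelty_class for r in again]


class TestAssignNames:
    def _novel(self, mature, chrom, start):
        return classify([_candidate(mature, chrom=chrom, start=start)])[0]

    def test_two_locus_family_lettered_by_coordinate_order(self):
        m = "UUAGGCAUCGAUCCGAUAGGU"
        r1 = self._novel(m, "Gm18", 500)
        r2 = self._novel(m, "Gm08", 500)
        assign_names([r1, r2])
        assert r2.record_id == "gma-MIR-Seq01a"   # Gm08 before Gm18
        assert r1.record_id == "gma-MIR-Seq01b"

    def test_single_locus_family_gets_bare_id(self):
        r = self._novel("UUAGGCAUCGAUCCGAUAGGU", "Gm01", 100)
        assign_names([r])
        assert r.record_id == "gma-MIR-Seq01"

    def test_both_arms_at_one_locus_get_arm_suffixes(self):
        m = "UUAGGCAUCGAUCCGAUAGGU"
        cand = _candidate(m)
        star = revcomp_rna(m)
        cand.matures.append(MatureRecord(star, cand.star_offset, "3p", {"L1": 9}))
        records = classify([cand])
        assign_names(records)
        ids = sorted(r.record_id for r in records)
        # both arms observed: one family, -5p and -3p records share coordinates
        assert any(i.endswith("-5p") for i in ids)
        assert any(i.endswith("-3p") for i in ids)
        assert len({(r.start, r.end) for r in records}) == 1

    def test_naming_stable_when_a_later_family_is_added(self):
        m1 = "UUAGGCAUCGAUCCGAUAGGU"
        m2 = "UACCGAGGAAUCGAAUCGAAU"
        r1 = self._novel(m1, "Gm01", 100)
        assign_names([r1])
        first_id = r1.record_id
        r2 = self._novel(m2, "Gm09", 900)
        assign_names([r1, r2])
        assert r1.record_id == first_id
        assert r2.record_id == "gma-MIR-Seq02"


class TestGroupIsomirs:
    PRECURSOR = "UUAGGCAUCGAUCCGAUAGGUAAACAAAC" + revcomp_rna("UUAGGCAUCGAUCCGAUAGGU")

    def test_single_member_is_the_core(self):
        ref = "UUAGGCAUCGAUCCGAUAGGU"
        g = group_isomirs([(ref, 10)], self.PRECURSOR, ref)
        assert g.core == ref
        assert (g.n5, g.n3) == (0, 0)
        assert g.n_isoforms == 1
        assert g.pattern == ref

    def test_pattern_with_extensions_on_both_ends(self):
        ref = "UUAGGCAUCGAUCCGAUAGGU"
        members = [(ref, 10), (ref[3:], 4), (self.PRECURSOR[0:24], 2)]
        g = group_isomirs(members, self.PRECURSOR, ref)
        assert g.core == ref[3:21]
        assert g.n5 == 3
        assert g.n3 == 3
        assert g.pattern == f"+3/{ref[3:21]}/+3"
        assert g.n_isoforms == 3

    def test_member_not_in_precursor_dropped_with_warning(self):
        ref = "UUAGGCAUCGAUCCGAUAGGU"
        g = group_isomirs([(ref, 5), ("G" * 21, 1)], self.PRECURSOR, ref)
        assert g.n_isoforms == 1

    def test_disjoint_members_rejected(self):
        with pytest.raises(ValueError):
            group_isomirs(
                [(self.PRECURSOR[:19], 1), (self.PRECURSOR[-19:], 1)],
                self.PRECURSOR,
                self.PRECURSOR[:19],
            )

    def test_simulated_isomir_set_matches_truth_count(self):
        from mirloop.simulate import SyntheticConfig, generate_genome_and_truth
        from mirloop.simulate import simulate_libraries

        cfg = SyntheticConfig(seed=3, n_hairpins=6, isomir_shift_prob=1.0,
                              background_tag_count=0)
        genome, truth, _ = generate_genome_and_truth(cfg)
        libs = simulate_libraries(truth, cfg, genome)
        for t in truth:
            members = libs[
                libs["origin"].isin([f"{t.hairpin_id}:mature", f"{t.hairpin_id}:isomir"])
            ]
            unique = members.groupby("sequence")["count"].sum()
            g = group_isomirs(list(unique.items()), t.precursor, t.mature)
            assert g.n_isoforms == len(unique)
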