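"""Duplex geometry, sRNA clusters, re-annotation logic, motif matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degratrack import annotation_and_motif as am
from degratrack import signal_scan, synthetic_data
from degratrack.sequencing_io import MatureAnnotation, PrecursorRecord
from degratrack.signal_scan import TagAlignment


class TestPairMap:
    def test_simple_hairpin(self):
        pm = am.pair_map_from_dotbracket("((..))")
        assert pm.partner[1] == 6 and pm.partner[2] == 5
        assert pm.loop_midpoint == 3  # floor midpoint of run 3..4

    def test_unpaired_structure_has_no_loop(self):
        pm = am.pair_map_from_dotbracket("....")
        assert pm.partner == {} and pm.loop_midpoint is None

    def test_nested_pairs(self):
        pm = am.pair_map_from_dotbracket("(())")
        assert pm.partner[1] == 4 and pm.partner[2] == 3

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="unbalanced"):
            am.pair_map_from_dotbracket("((.)")

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_partner_is_involutive_on_random_hairpins(self, seed):
        rng = np.random.default_rng(seed)
        stem = int(rng.integers(1, 20))
        loop = int(rng.integers(3, 15))
        f5, f3 = int(rng.integers(0, 8)), int(rng.integers(0, 8))
        s = "." * f5 + "(" * stem + "." * loop + ")" * stem + "." * f3
        pm = am.pair_map_from_dotbracket(s)
        for i, j in pm.partner.items():
            assert pm.partner[j] == i and i != j
        # loop midpoint lies inside the loop run
        assert f5 + stem < pm.loop_midpoint <= f5 + stem + loop


def perfect_hairpin(stem=30, loop=12, f5=0, f3=0):
    structure = "." * f5 + "(" * stem + "." * loop + ")" * stem + "." * f3
    return am.pair_map_from_dotbracket(structure)


class TestDuplexOverhangs:
    def test_canonical_two_nt_overhangs_by_coordinate_oracle(self):
        # perfect stem: partner(i) = 2*stem + loop + 1 - i
        stem, loop, ml = 30, 12, 21
        pm = perfect_hairpin(stem, loop)
        for s5 in range(2, stem - ml):
            arm5 = (s5, s5 + ml - 1)
            arm3_end = (2 * stem + loop + 1 - s5) + 2
            arm3 = (arm3_end - ml + 1, arm3_end)
            check = am.duplex_overhangs(pm, arm5, arm3)
            assert (check.overhang_at_3p_end_of_3p, check.overhang_at_3p_end_of_5p) == (2, 2)
            assert check.canonical

    def test_shifted_arm_breaks_canonical_geometry(self):
        stem, loop, ml = 30, 12, 21
        pm = perfect_hairpin(stem, loop)
        s5 = 4
        arm5 = (s5, s5 + ml - 1)
        arm3_end = (2 * stem + loop + 1 - s5) + 2
        arm3 = (arm3_end - ml + 1 - 3, arm3_end - 3)  # shifted 3 nt toward 5'
        check = am.duplex_overhangs(pm, arm5, arm3)
        assert not check.canonical
        # hand-traced on the perfect pair map: both overhangs collapse to -1
        assert check.overhang_at_3p_end_of_3p == -1
        assert check.overhang_at_3p_end_of_5p == -1
        # a 5'-only lengthening (the annotated-vs-true mismatch pattern)
        # keeps the 3p-side overhang but breaks the 5p side
        longer = (arm3_end - ml + 1 - 3, arm3_end)
        check2 = am.duplex_overhangs(pm, arm5, longer)
        assert (check2.overhang_at_3p_end_of_3p, check2.overhang_at_3p_end_of_5p) == (2, -1)

    def test_blunt_placement_gives_zero_overhangs(self):
        stem, loop, ml = 30, 12, 21
        pm = perfect_hairpin(stem, loop)
        s5 = 4
        arm5 = (s5, s5 + ml - 1)
        arm3_end = 2 * stem + loop + 1 - s5  # exactly the partner: blunt
        arm3 = (arm3_end - ml + 1, arm3_end)
        check = am.duplex_overhangs(pm, arm5, arm3)
        assert (check.overhang_at_3p_end_of_3p, check.overhang_at_3p_end_of_5p) == (0, 0)
        assert not check.canonical

    def test_arm_without_paired_position_rejected(self):
        pm = am.pair_map_from_dotbracket("((((....))))....")
        with pytest.raises(ValueError, match="no paired position"):
            am.duplex_overhangs(pm, (1, 4), (13, 16))

    def test_arms_must_flank_the_loop(self):
        pm = perfect_hairpin(10, 4)
        with pytest.raises(ValueError, match="flank"):
            am.duplex_overhangs(pm, (1, 4), (5, 8))


class TestSrnaClusters:
    def align(self, seq, pos, rpm):
        return TagAlignment(tag_sequence=seq, precursor_id="p", five_prime_pos=pos, rpm=rpm)

    def test_five_prime_only_tags_leave_cluster3_empty(self):
        pm = perfect_hairpin(20, 10)
        c5, c3 = am.srna_clusters([self.align("A" * 10, 2, 5.0)], pm)
        assert len(c5.members) == 1 and c3.members == []

    def test_most_abundant_member_reported(self):
        pm = perfect_hairpin(20, 10)
        aligns = [self.align("A" * 10, 35, 100.0), self.align("C" * 10, 36, 40.0)]
        _, c3 = am.srna_clusters(aligns, pm)
        assert c3.top.tag_sequence == "A" * 10

    def test_midpoint_tie_goes_to_five_prime_arm(self):
        pm = perfect_hairpin(10, 5)  # loop 11..15, midpoint 13
        # tag of length 11 centred exactly on 13
        c5, c3 = am.srna_clusters([self.align("A" * 11, 8, 1.0)], pm)
        assert len(c5.members) == 1 and c3.members == []


class TestFivePrimeShift:
    def test_printed_mir168a_example(self):
        annotated = "GAUCCCGCCUUGCACCAAGUGAAU"
        candidate = "CCCGCCUUGCACCAAGUGAAU"
        assert am.five_prime_shift(annotated, candidate) == 3

    def test_extension_yields_negative_shift(self):
        assert am.five_prime_shift("CCGG", "AACCGG") == -2

    def test_unrelated_sequences_give_none(self):
        assert am.five_prime_shift("AAAA", "CCCC") is None


def _shift_cohort():
    cfg = synthetic_data.CohortConfig(
        n_precursors=6, seed=21, shift3p_prob=1.0, unannotated_arm_prob=0.0,
        planted_classes={1: 1.0, 3: 1.0, 4: 1.0}, tissues=("t",),
    )
    return synthetic_data.build_cohort(cfg)


def _scan_and_srna(cohort):
    lib = synthetic_data.simulate_degradome(cohort)
    ext = cohort.extended_precursors(50)
    scan = signal_scan.scan_library(lib, ext)
    srna = synthetic_data.simulate_srna(cohort, cohort.config.tissues[0])
    return scan.signals_by_precursor(), srna


class TestProposeReannotation:
    def test_shifted_3p_yields_shift_of_three(self):
        cohort = _shift_cohort()
        sig_by_pre, srna = _scan_and_srna(cohort)
        for pre in cohort.precursors:
            report = am.propose_reannotation(
                pre, cohort.annotations, sig_by_pre.get(pre.id, []), srna
            )
            assert report.recommendation == "SHIFT"
            assert report.shift_nt == 3
            assert report.evidence_degradome and report.evidence_abundance

    def test_unannotated_arm_yields_novel_arm(self):
        cfg = synthetic_data.CohortConfig(
            n_precursors=6, seed=22, shift3p_prob=0.0, unannotated_arm_prob=1.0,
            planted_classes={1: 1.0, 3: 1.0, 4: 1.0}, tissues=("t",),
        )
        cohort = synthetic_data.build_cohort(cfg)
        sig_by_pre, srna = _scan_and_srna(cohort)
        for pre in cohort.precursors:
            report = am.propose_reannotation(
                pre, cohort.annotations, sig_by_pre.get(pre.id, []), srna
            )
            assert report.recommendation == "NOVEL_ARM"
            assert report.arm == "3p"
            assert report.evidence_duplex

    def test_fully_supported_lc_pair_yields_promote(self):
        cfg = synthetic_data.CohortConfig(
            n_precursors=6, seed=23, shift3p_prob=0.0, unannotated_arm_prob=0.0,
            planted_classes={1: 1.0, 3: 1.0, 4: 1.0}, hc_prob=0.0, tissues=("t",),
        )
        cohort = synthetic_data.build_cohort(cfg)
        sig_by_pre, srna = _scan_and_srna(cohort)
        for pre in cohort.precursors:
            report = am.propose_reannotation(
                pre, cohort.annotations, sig_by_pre.get(pre.id, []), srna
            )
            assert report.recommendation == "PROMOTE"
            assert report.evidence_degradome and report.evidence_duplex and report.evidence_abundance

    def test_no_evidence_yields_none(self):
        cfg = synthetic_data.CohortConfig(
            n_precursors=3, seed=24, shift3p_prob=0.0, unannotated_arm_prob=0.0,
            planted_classes={}, tissues=("t",),
        )
        cohort = synthetic_data.build_cohort(cfg)
        srna = synthetic_data.simulate_srna(cohort, "t")
        for pre in cohort.precursors:
            report = am.propose_reannotation(pre, cohort.annotations, [], srna)
            assert report.recommendation == "NONE"

    def test_missing_structure_flags_partial(self):
        cohort = _shift_cohort()
        sig_by_pre, srna = _scan_and_srna(cohort)
        pre = cohort.precursors[0]
        bare = PrecursorRecord(id=pre.id, sequence=pre.sequence)
        report = am.propose_reannotation(
            bare, cohort.annotations, sig_by_pre.get(pre.id, []), srna
        )
        assert report.partial


class TestMotifWindows:
    def _pre(self, seq, pid="p"):
        return PrecursorRecord(id=pid, sequence=seq)

    def test_site_is_eleventh_nucleotide(self):
        seq = "ACGUACGUACGUACGUACGUACGUACGUAC"  # 30 nt
        (w,) = am.motif_windows([("p", 11)], [self._pre(seq)])
        assert w == seq[0:20]
        assert w[am.SITE_COLUMN - 1] == seq[10]

    def test_site_too_close_to_end_is_skipped(self):
        seq = "ACGUACGUACGUACGUACGUACGUACGUAC"
        assert am.motif_windows([("p", 5)], [self._pre(seq)]) == []
        assert am.motif_windows([("p", 25)], [self._pre(seq)]) == []

    def test_class_filter_selects_sites(self):
        anns = [
            MatureAnnotation("p", "m5", 12, 32, "5p"),
            MatureAnnotation("p", "m3", 40, 60, "3p"),
        ]
        sites = am.class_sites(anns, classes={1})
        assert sites == [("p", 12, 1)]
        sites34 = am.class_sites(anns, classes={3, 4})
        assert sites34 == [("p", 40, 3), ("p", 61, 4)]


class TestMotifMatrix:
    def test_pure_column_has_two_bits(self):
        windows = ["U" * 20] * 8
        m = am.motif_matrix(windows)
        assert m.information_content[am.SITE_COLUMN - 1] == pytest.approx(2.0)
        assert m.max_letter(am.SITE_COLUMN) == "U"

    def test_half_half_column_has_one_bit(self):
        windows = ["A" * 20, "C" * 20]
        m = am.motif_matrix(windows)
        assert m.information_content[0] == pytest.approx(1.0)

    def test_uniform_random_columns_have_near_zero_ic(self):
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list("ACGU"), 20)) for _ in range(1000)]
        m = am.motif_matrix(windows)
        assert np.all(m.information_content < 0.05)

    def test_ic_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(6)
        windows = ["".join(rng.choice(list("ACGU"), 20)) for _ in range(50)]
        m1 = am.motif_matrix(windows)
        assert np.all(m1.information_content >= 0.0)
        assert np.all(m1.information_content <= 2.0)
        m2 = am.motif_matrix(list(reversed(windows)))
        assert np.allclose(m1.information_content, m2.information_content)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed lengths"):
            am.motif_matrix(["AAAA", "AAA"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            am.motif_matrix([])
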