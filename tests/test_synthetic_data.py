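"""Generator: determinism, truth consistency, calibration, geometry."""

import filecmp

import pytest

from degratrack import annotation_and_motif as am
from degratrack import processing_support as ps
from degratrack import sequencing_io as sio
from degratrack import signal_scan, synthetic_data as sd


class TestConfig:
    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="stem_len"):
            sd.CohortConfig(stem_len=20, mature_len=21)

    def test_shallow_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            sd.CohortConfig(n_precursors=50, background_tags_per_precursor=25, depth=1000)


class TestMakeHairpin:
    def test_truth_arms_have_two_nt_overhangs(self, cohort):
        for pre in cohort.precursors:
            pm = am.pair_map_from_dotbracket(pre.structure)
            assert len(pm.partner) == 2 * cohort.config.stem_len
            mirnas = {m.arm: m for m in cohort.truth_mirnas if m.precursor_id == pre.id}
            check = am.duplex_overhangs(
                pm,
                (mirnas["5p"].true_start, mirnas["5p"].true_end),
                (mirnas["3p"].true_start, mirnas["3p"].true_end),
            )
            assert check.canonical

    def test_genomic_roundtrip_recovers_precursor(self, cohort):
        for pre in cohort.precursors:
            locus = pre.genomic_locus
            chrom = cohort.genome[locus.chrom]
            segment = chrom[locus.start - 1 : locus.end]
            if locus.strand == "+":
                assert sio.to_rna(segment) == pre.sequence
            else:
                assert sio.reverse_complement(sio.to_rna(segment)) == pre.sequence

    def test_structure_matches_sequence_pairing(self, cohort):
        # paired positions are exact reverse complements (perfect stems)
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
        pre = cohort.precursors[0]
        pm = am.pair_map_from_dotbracket(pre.structure)
        for i, j in pm.partner.items():
            assert pre.sequence[j - 1] == comp[pre.sequence[i - 1]]


class TestTruthConsistency:
    def test_planted_site_classes_recompute_from_annotations(self, cohort):
        """For unshifted annotated matures, classifying the truth position
        against the emitted annotation recovers the truth class label."""
        anns = {a.mature_id: a for a in cohort.annotations}
        shifted = {m.mature_id for m in cohort.truth_mirnas if m.shifted}
        checked = 0
        for site in cohort.truth_sites:
            ann = anns.get(site.mature_id)
            if ann is None or site.mature_id in shifted:
                continue
            res = ps.classify_offset(site.position, ann)
            assert res is not None
            end_kind, label = res
            assert label in {"5'", "3'"}
            assert ps.assign_position_class(ann.arm, end_kind) == site.position_class
            checked += 1
        assert checked > 100

    def test_shifted_truth_sites_appear_as_minus3_isomirs(self, cohort):
        anns = {a.mature_id: a for a in cohort.annotations}
        rows = [
            (s, anns[s.mature_id])
            for s in cohort.truth_sites
            for m in cohort.truth_mirnas
            if m.shifted and m.mature_id == s.mature_id and s.position_class == 3
            and s.mature_id in anns
        ]
        assert rows
        for site, ann in rows:
            assert ps.classify_offset(site.position, ann) == (ps.FIVE_PRIME, "5'_-3")


class TestSimulateDegradome:
    def test_realized_snr_within_factor_two_of_target(self, cohort, pooled_scan):
        planted = {
            (s.precursor_id, s.position) for s in cohort.truth_sites if s.planted
        }
        ratios = [
            s.ratio for s in pooled_scan.signals
            if (s.precursor_id, s.position) in planted
        ]
        assert len(ratios) >= 0.9 * len(planted)
        target = cohort.config.planted_snr
        in_band = [r for r in ratios if target / 2 <= r <= target * 2]
        assert len(in_band) >= 0.9 * len(ratios)

    def test_null_cohort_yields_no_prominent_signals(self):
        cfg = sd.CohortConfig(n_precursors=20, seed=31, planted_classes={},
                              shift3p_prob=0.0, unannotated_arm_prob=0.0)
        cohort = sd.build_cohort(cfg)
        lib = sd.simulate_degradome(cohort)
        scan = signal_scan.scan_library(lib, cohort.extended_precursors(50))
        assert scan.signals == []

    def test_tissue_library_plants_only_assigned_sites(self, cohort, tissue_scans):
        tissue = cohort.config.tissues[0]
        scan = tissue_scans[tissue]
        other_sites = {
            (s.precursor_id, s.position)
            for s in cohort.truth_sites
            if s.planted and s.tissue != tissue
        }
        hits = {(s.precursor_id, s.position) for s in scan.signals}
        assert not hits & other_sites


class TestSimulateSrna:
    def test_tissue_bias_drives_accumulation(self, cohort):
        from degratrack import comparative_analysis as ca

        lib_a = sd.simulate_srna(cohort, "tissueA")
        lib_b = sd.simulate_srna(cohort, "tissueB")
        matures = {
            m.mature_id: cohort.precursor(m.precursor_id).sequence[m.true_start - 1 : m.true_end]
            for m in cohort.truth_mirnas
        }
        calls = {c.mature_id: c.call for c in ca.accumulation_call(lib_a, lib_b, matures)}
        by_tissue = {m.mature_id: m.tissue for m in cohort.truth_mirnas}
        for mature_id, call in calls.items():
            expected = "high_in_A" if by_tissue[mature_id] == "tissueA" else "high_in_B"
            assert call == expected

    def test_shifted_variant_dominates_three_prime_cluster(self):
        cfg = sd.CohortConfig(n_precursors=4, seed=41, shift3p_prob=1.0,
                              unannotated_arm_prob=0.0, tissues=("t",))
        cohort = sd.build_cohort(cfg)
        srna = sd.simulate_srna(cohort, "t")
        for pre in cohort.precursors:
            pm = am.pair_map_from_dotbracket(pre.structure)
            aligns = signal_scan.map_tags(srna, pre)
            _, c3 = am.srna_clusters(aligns, pm)
            truth3 = next(
                m for m in cohort.truth_mirnas if m.precursor_id == pre.id and m.arm == "3p"
            )
            assert c3.top.five_prime_pos == truth3.true_start
            assert c3.top.five_prime_pos == truth3.annotated_start + 3


class TestFixtureDirectories:
    def test_identical_seed_gives_byte_identical_fixtures(self, tmp_path):
        cfg = sd.CohortConfig(n_precursors=5, seed=13)
        sd.generate_cohort(cfg, tmp_path / "a")
        sd.generate_cohort(cfg, tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b", names, shallow=False)
        assert mismatch == [] and errors == []

    def test_empty_cohort_writes_header_only_tables(self, tmp_path):
        cfg = sd.CohortConfig(n_precursors=0, seed=1)
        sd.generate_cohort(cfg, tmp_path)
        annotations = (tmp_path / "annotations.tsv").read_text().splitlines()
        assert annotations == ["precursor_id\tmature_id\tstart\tend\tarm\tconfidence"]
        assert (tmp_path / "degradome_pooled.tsv").read_text().splitlines() == [
            "sequence\traw_count"
        ]

    def test_fixture_loads_through_standard_io(self, tmp_path):
        cfg = sd.CohortConfig(n_precursors=5, seed=13)
        cohort = sd.generate_cohort(cfg, tmp_path)
        pres, anns = sio.read_precursors(tmp_path / "precursors.fa", tmp_path / "annotations.tsv")
        sio.read_structures(tmp_path / "structures.tsv", pres)
        assert [p.id for p in pres] == [p.id for p in cohort.precursors]
        assert [p.sequence for p in pres] == [p.sequence for p in cohort.precursors]
        assert len(anns) == len(cohort.annotations)
        lib = sio.load_tag_library(tmp_path / "degradome_pooled.tsv", "pooled")
        mem = sd.simulate_degradome(cohort)
        assert {s: t.raw_count for s, t in lib.tags.items()} == {
            s: t.raw_count for s, t in mem.tags.items()
        }
        ext_from_file = sio.extend_precursors(pres, tmp_path / "genome.fa", 50)
        ext_in_mem = cohort.extended_precursors(50)
        assert [p.sequence for p in ext_from_file] == [p.sequence for p in ext_in_mem]

    def test_full_pipeline_produces_all_output_schemas(self, tmp_path, cohort, pooled_scan):
        support = ps.call_support(
            {pooled_scan.sample_id: pooled_scan.signals}, cohort.annotations
        )
        summary = ps.summarize(cohort.precursors, cohort.annotations, support)
        sio.write_results_table(
            [
                {
                    "sample_id": pooled_scan.sample_id,
                    "precursor_id": s.precursor_id,
                    "position": s.position,
                    "signal": s.signal,
                    "noise": s.noise,
                    "ratio": s.ratio,
                    "top_rank": s.top_rank,
                }
                for s in pooled_scan.signals
            ],
            tmp_path / "signals.tsv",
            "prominent_signals",
        )
        sio.write_results_table(
            [
                {
                    "precursor_id": c.precursor_id,
                    "mature_id": c.mature_id,
                    "end_kind": c.end_kind,
                    "offset_label": c.offset_label,
                    "position_class": c.position_class,
                    "signal_position": c.signal_position,
                    "supporting_samples": ",".join(sorted(c.supporting_samples)),
                }
                for c in support.site_calls
            ],
            tmp_path / "calls.tsv",
            "support_calls",
        )
        sio.write_results_table(summary.as_rows(), tmp_path / "summary.tsv", "summary")
        planted1 = [
            (s.precursor_id, s.position)
            for s in cohort.truth_sites if s.position_class == 1 and s.planted
        ]
        matrix = am.motif_matrix(am.motif_windows(planted1, cohort.precursors))
        sio.write_results_table(matrix.as_rows(), tmp_path / "motif.tsv", "motif_matrix")
        srna = sd.simulate_srna(cohort, "tissueA")
        sig_by_pre = pooled_scan.signals_by_precursor()
        reports = [
            am.propose_reannotation(
                pre, cohort.annotations, sig_by_pre.get(pre.id, []), srna
            ).as_row()
            for pre in cohort.precursors
        ]
        sio.write_results_table(reports, tmp_path / "recs.tsv", "recommendations")
        for name in ("signals", "calls", "summary", "motif", "recs"):
            assert (tmp_path / f"{name}.tsv").stat().st_size > 0
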