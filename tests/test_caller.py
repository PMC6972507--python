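"""Clustering, consensus, reciprocal pairing, merging, annotation, sequence."""

import itertools

import numpy as np
import pytest

import nanobreak as nb
from nanobreak import simulate as sim
from nanobreak.caller import BreakendCall


def ev(pos1, pos2, chrom1="chrA", chrom2="chrB", ori="+-", read_id="r",
       svclass="translocation", gap=0):
    return nb.JunctionEvidence(read_id=read_id, bnd_1=nb.Locus(chrom1, pos1),
                               side_1="end" if ori[0] == "+" else "start",
                               bnd_2=nb.Locus(chrom2, pos2),
                               side_2="end" if ori[1] == "+" else "start",
                               orientation=ori, svclass=svclass, read_gap=gap,
                               min_mapq_of_pair=60, min_identity_of_pair=1.0)


class TestClustering:
    def test_nearby_evidence_forms_one_cluster(self, cfg):
        evs = [ev(50_000, 60_000, read_id="a"), ev(50_004, 60_002, read_id="b"),
               ev(49_998, 59_995, read_id="c")]
        clusters = nb.cluster_evidence(evs, cfg)
        assert len(clusters) == 1 and len(clusters[0]) == 3
        # oracle: brute-force all-pairs single linkage agrees
        linked = any(abs(a.bnd_1.pos - b.bnd_1.pos) > cfg.cluster_tol or
                     abs(a.bnd_2.pos - b.bnd_2.pos) > cfg.cluster_tol
                     for a, b in itertools.combinations(evs, 2))
        assert not linked

    def test_distant_evidence_stays_apart(self, cfg):
        clusters = nb.cluster_evidence([ev(50_000, 60_000), ev(55_000, 60_000)], cfg)
        assert len(clusters) == 2

    def test_opposite_orientations_never_merge(self, cfg):
        clusters = nb.cluster_evidence([ev(50_000, 60_000, ori="+-"),
                                        ev(50_000, 60_000, ori="-+")], cfg)
        assert len(clusters) == 2

    def test_transitive_single_linkage(self, cfg):
        """a-b and b-c within tolerance chains a-c into one cluster."""
        evs = [ev(50_000, 60_000, read_id="a"), ev(50_900, 60_000, read_id="b"),
               ev(51_700, 60_000, read_id="c")]
        assert len(nb.cluster_evidence(evs, cfg)) == 1


class TestConsensus:
    def test_median_and_ci_from_members(self, cfg):
        cluster = [ev(1000, 60_000, read_id="a"), ev(1004, 60_000, read_id="b"),
                   ev(998, 60_000, read_id="c")]
        a, b = nb.consensus_breakpoint(cluster, cfg)
        assert (a.locus.pos, a.locus.ci_lo, a.locus.ci_hi) == (1000, -2, 4)
        assert a.support == 3 and not a.imprecise
        assert b.locus.pos == 60_000 and b.mate.pos == 1000

    def test_even_count_takes_lower_middle(self, cfg):
        cluster = [ev(1000, 60_000, read_id="a"), ev(1002, 60_000, read_id="b")]
        a, _ = nb.consensus_breakpoint(cluster, cfg)
        assert a.locus.pos == 1000

    def test_single_member_low_support_flagged(self, cfg):
        a, _ = nb.consensus_breakpoint([ev(1000, 60_000)], cfg)
        assert a.support == 1 and a.imprecise

    def test_breakend_near_n_run_flagged_imprecise(self, cfg):
        ref = sim.make_reference({"chrA": 100_000, "chrB": 100_000}, seed=3,
                                 repeat_spec={"n_runs": [("chrA", 52_000, 500)]})
        members = [ev(50_000, 60_000, read_id=f"r{i}") for i in range(5)]
        a, _ = nb.consensus_breakpoint(members, cfg, reference=ref)
        assert a.imprecise  # within 5 kb of a 500-base N-run

    def test_noiseless_simulation_recovers_exact_positions(self, noiseless_sam, cfg):
        evs = [nb.junction_from_pair(sp)
               for ra in nb.read_alignments(noiseless_sam["sam"], cfg)
               for sp in nb.split_candidates(ra, cfg)]
        calls = nb.call_breakends(evs, cfg, reference=noiseless_sam["ref"])
        got = {frozenset([(c.locus.chrom, c.locus.pos), (c.mate.chrom, c.mate.pos)])
               for c in nb.iter_junctions(calls)}
        want = {frozenset([j.breakends()[0][:2], j.breakends()[1][:2]])
                for j in noiseless_sam["junctions"]}
        assert got == want


class TestReciprocalPairing:
    @staticmethod
    def _junction(cid, l1, o1, l2, o2, support=5):
        a = BreakendCall(f"{cid}_1", l1, l2, o1 + o2, "translocation", support,
                         (), 0, False, f"{cid}_2")
        b = BreakendCall(f"{cid}_2", l2, l1, o2 + o1, "translocation", support,
                         (), 0, False, f"{cid}_1")
        return [a, b]

    def test_microdeletion_interval_is_79_bases(self):
        """der1 retains chr22 through 20656021; der2 resumes at 20656101."""
        calls = (self._junction("J1", nb.Locus("8", 125_495_366), "+",
                                nb.Locus("22", 20_656_021), "+")
                 + self._junction("J2", nb.Locus("8", 125_495_367), "-",
                                  nb.Locus("22", 20_656_101), "-"))
        (event,) = nb.pair_reciprocal(calls)
        deleted = [event.deleted_interval(w) for w in ("a", "b")]
        assert ("22", 20_656_022, 20_656_100) in deleted
        assert sorted(g for g in (event.gap_a, event.gap_b)) == [0, 79]
        # inclusive length of the printed interval
        assert 20_656_100 - 20_656_022 + 1 == 79

    def test_balanced_event_has_zero_gaps(self, noiseless_sam, cfg):
        evs = [nb.junction_from_pair(sp)
               for ra in nb.read_alignments(noiseless_sam["sam"], cfg)
               for sp in nb.split_candidates(ra, cfg)]
        calls = nb.call_breakends(evs, cfg)
        (event,) = nb.pair_reciprocal(calls)
        assert event.der2 is not None
        assert (event.gap_a, event.gap_b) == (0, 0)

    def test_planted_duplication_reported_as_negative_gap(self, small_ref, cfg, tmp_path):
        # a 150-base duplication: derB resumes chrA 150 bases BEFORE the stop
        haps = sim.diploid_from_reference(small_ref)
        der = sim.Haplotype(index=2, contigs=[
            sim.HapContig("der_chrA", [sim.Block("chrA", 0, 50_000),
                                       sim.Block("chrB", 60_000, 100_000)]),
            sim.HapContig("der_chrB", [sim.Block("chrB", 0, 60_000),
                                       sim.Block("chrA", 50_000 - 150, 100_000)]),
        ])
        reads = sim.simulate_reads([der], small_ref, depth=10, seed=41,
                                   error_model=sim.ErrorModel(0, 0, 0))
        sam = str(tmp_path / "dup.sam")
        sim.simulate_alignments(reads, [der], small_ref, sam)
        evs = [nb.junction_from_pair(sp) for ra in nb.read_alignments(sam, cfg)
               for sp in nb.split_candidates(ra, cfg)]
        (event,) = nb.pair_reciprocal(nb.call_breakends(evs, cfg))
        assert event.gap_a == -150
        assert event.gap_b == 0

    def test_unpaired_junction_returned_as_singleton(self):
        calls = self._junction("J1", nb.Locus("chrA", 1000), "+",
                               nb.Locus("chrB", 2000), "-")
        (event,) = nb.pair_reciprocal(calls)
        assert event.der2 is None and event.gap_a is None


class TestMerging:
    @staticmethod
    def _calls(pos1, pos2, cid="X0", reads=("r1", "r2", "r3")):
        l1, l2 = nb.Locus("chrA", pos1), nb.Locus("chrB", pos2)
        a = BreakendCall(f"{cid}_1", l1, l2, "+-", "translocation", len(reads),
                         tuple(reads), 0, False, f"{cid}_2")
        b = BreakendCall(f"{cid}_2", l2, l1, "-+", "translocation", len(reads),
                         tuple(reads), 0, False, f"{cid}_1")
        return [a, b]

    def test_nearby_calls_merge_with_read_union(self, cfg):
        merged = nb.merge_callsets(self._calls(50_000, 60_001, reads=("a", "b")),
                                   self._calls(50_020, 60_010, reads=("b", "c")),
                                   merge_tol=cfg.merge_tol)
        junctions = nb.iter_junctions(merged)
        assert len(junctions) == 1
        assert junctions[0].read_ids == ("a", "b", "c")
        assert junctions[0].support == 3

    def test_disjoint_calls_kept_with_source_tags(self, cfg):
        merged = nb.merge_callsets(self._calls(50_000, 60_001),
                                   self._calls(90_000, 10_000, cid="Y0"),
                                   merge_tol=cfg.merge_tol, names=("s1", "s2"))
        sources = sorted(c.source for c in nb.iter_junctions(merged))
        assert sources == ["s1", "s2"]

    def test_merge_is_idempotent_and_commutative(self, cfg):
        s1 = self._calls(50_000, 60_001, reads=("a", "b"))
        s2 = self._calls(50_020, 60_010, cid="Y0", reads=("b", "c"))

        def signature(calls):
            return sorted(((c.locus.chrom, c.locus.pos), (c.mate.chrom, c.mate.pos),
                           c.orientation, c.read_ids) for c in nb.iter_junctions(calls))

        self_merge = nb.merge_callsets(s1, s1, merge_tol=cfg.merge_tol)
        assert signature(self_merge) == signature(s1)
        ab = nb.merge_callsets(s1, s2, merge_tol=cfg.merge_tol)
        ba = nb.merge_callsets(s2, s1, merge_tol=cfg.merge_tol)
        assert signature(ab) == signature(ba)


class TestAnnotation:
    @staticmethod
    def _bed(tmp_path, lines):
        p = tmp_path / "rep.bed"
        p.write_text("".join(lines))
        return str(p)

    @staticmethod
    def _call(chrom, pos):
        return BreakendCall("c_1", nb.Locus(chrom, pos), nb.Locus("chrB", 1),
                            "+-", "translocation", 5, (), 0, False, "c_2")

    def test_containment_labels_breakend(self, tmp_path):
        bed = self._bed(tmp_path, ["chr18\t28685000\t28686000\tAluY\n"])
        (c,) = nb.annotate_calls([self._call("chr18", 28_685_658)], bed)
        assert c.labels == ("AluY",)

    def test_breakend_at_interval_end_not_contained(self, tmp_path):
        bed = self._bed(tmp_path, ["chr18\t28685000\t28686000\tAluY\n"])
        # 0-based breakend coordinate == exclusive end -> outside
        (c,) = nb.annotate_calls([self._call("chr18", 28_686_001)], bed)
        assert c.labels == ()
        # ... but the last covered base is inside
        (c,) = nb.annotate_calls([self._call("chr18", 28_686_000)], bed)
        assert c.labels == ("AluY",)

    def test_overlapping_features_reported_in_file_order(self, tmp_path):
        bed = self._bed(tmp_path, ["chr9\t44216000\t44217000\tAluSx3\n",
                                   "chr9\t44210000\t44220000\tL1PA4\n"])
        (c,) = nb.annotate_calls([self._call("chr9", 44_216_447)], bed)
        assert c.labels == ("AluSx3", "L1PA4")

    def test_malformed_bed_line_reports_line_number(self, tmp_path):
        bed = self._bed(tmp_path, ["chr1\t100\t200\tok\n", "chr1\tnope\t300\tbad\n"])
        with pytest.raises(ValueError, match=":2:"):
            nb.annotate_calls([self._call("chr1", 150)], bed)


class TestJunctionSequence:
    def test_length_is_twice_flank(self, small_ref):
        call = BreakendCall("c_1", nb.Locus("chrA", 50_000), nb.Locus("chrB", 60_001),
                            "+-", "translocation", 5, (), 0, False, "c_2")
        _, seq = nb.junction_sequence(small_ref, call, flank=500)
        assert len(seq) == 1000

    def test_sequence_is_substring_of_derivative(self, noiseless_sam, cfg):
        evs = [nb.junction_from_pair(sp)
               for ra in nb.read_alignments(noiseless_sam["sam"], cfg)
               for sp in nb.split_candidates(ra, cfg)]
        calls = nb.call_breakends(evs, cfg)
        mats = noiseless_sam["haplotype"].materialize(noiseless_sam["ref"])
        derivatives = [m.tobytes().decode() for m in mats.values()]
        for c in nb.iter_junctions(calls):
            _, seq = nb.junction_sequence(noiseless_sam["ref"], c, flank=400)
            assert any(seq in d or nb.revcomp(seq) in d for d in derivatives)

    def test_inversion_flank_is_reverse_complemented(self, small_ref, cfg, tmp_path):
        haps = sim.diploid_from_reference(small_ref)
        spec = sim.EventSpec(kind="inversion", chrom_a="chrA", pos_a=30_000,
                             pos_b=70_000)
        der, junctions, _ = sim.apply_rearrangement(small_ref, haps[1], spec)
        reads = sim.simulate_reads([der], small_ref, depth=10, seed=51,
                                   error_model=sim.ErrorModel(0, 0, 0))
        sam = str(tmp_path / "inv.sam")
        sim.simulate_alignments(reads, [der], small_ref, sam)
        evs = [nb.junction_from_pair(sp) for ra in nb.read_alignments(sam, cfg)
               for sp in nb.split_candidates(ra, cfg)]
        calls = nb.call_breakends(evs, cfg)
        derivative = der.materialize(small_ref)["der_chrA"].tobytes().decode()
        assert all(c.svclass == "inversion" for c in calls)
        got = {frozenset([(c.locus.chrom, c.locus.pos), (c.mate.chrom, c.mate.pos)])
               for c in nb.iter_junctions(calls)}
        want = {frozenset([j.breakends()[0][:2], j.breakends()[1][:2]])
                for j in junctions}
        assert got == want
        for c in nb.iter_junctions(calls):
            _, seq = nb.junction_sequence(small_ref, c, flank=300)
            assert seq in derivative or nb.revcomp(seq) in derivative
            # the distal side must come from the reverse strand of the reference
            ref_a = small_ref.sequences["chrA"]
            assert seq not in ref_a and nb.revcomp(seq) not in ref_a

    def test_imprecise_call_refused(self, small_ref):
        call = BreakendCall("c_1", nb.Locus("chrA", 50_000, -10, 10),
                            nb.Locus("chrB", 60_001), "+-", "translocation",
                            5, (), 0, True, "c_2")
        with pytest.raises(ValueError, match="imprecise"):
            nb.junction_sequence(small_ref, call, flank=100)

    def test_flank_truncated_at_contig_edge_with_warning(self, small_ref):
        call = BreakendCall("c_1", nb.Locus("chrA", 100), nb.Locus("chrB", 60_001),
                            "+-", "translocation", 5, (), 0, False, "c_2")
        with pytest.warns(UserWarning, match="truncated"):
            _, seq = nb.junction_sequence(small_ref, call, flank=500)
        assert len(seq) == 600
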