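"""Het-site detection, allele matrices and MEC haplotype partitioning."""

import itertools

import numpy as np
import pytest

import nanobreak as nb
from nanobreak import simulate as sim
from nanobreak.phasing import AlleleMatrix
from tests.conftest import make_translocation


def _matrix(rows, ids=None):
    arr = np.array(rows, dtype=np.int8)
    ids = ids or [f"r{i}" for i in range(arr.shape[0])]
    return AlleleMatrix(matrix=arr, read_ids=ids, sites=[None] * arr.shape[1])


def _mec_bruteforce(mat):
    """Exhaustive minimum over all bipartitions (independent oracle)."""
    n = mat.shape[0]
    best = None
    for labels in itertools.product((1, 2), repeat=n):
        score = nb.mec_score(mat, list(labels))
        best = score if best is None else min(best, score)
    return best


# ---------------------------------------------------------------------------
# Pileup het sites
# ---------------------------------------------------------------------------

_HEADER = "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:1000\n"


def _pileup_sam(tmp_path, bases_at_11, depth_each=1):
    """Reads of 21 bases starting at pos 1; base at reference position 11 varies."""
    lines = []
    i = 0
    for base in bases_at_11:
        seq = "A" * 10 + base + "A" * 10
        lines.append(f"p{i}\t0\tc1\t1\t60\t21M\t*\t0\t0\t{seq}\t*\n")
        i += 1
    p = tmp_path / "pile.sam"
    p.write_text(_HEADER + "".join(lines))
    return str(p)


@pytest.fixture
def pileup_ref():
    return nb.Reference({"c1": "A" * 1000})


class TestPileup:
    def test_balanced_site_detected(self, tmp_path, cfg, pileup_ref):
        sam = _pileup_sam(tmp_path, "AAAAA" + "GGGGG")
        sites = nb.pileup_het_sites(sam, ("c1", 1, 100), cfg, pileup_ref)
        assert len(sites) == 1
        s = sites[0]
        assert (s.locus.pos, s.ref_allele, s.alt_allele) == (11, "A", "G")
        assert s.alt_fraction == pytest.approx(0.5) and s.depth == 10

    def test_low_depth_rejected(self, tmp_path, cfg, pileup_ref):
        sam = _pileup_sam(tmp_path, "AG" + "G")  # depth 3 < het_min_depth
        sites = nb.pileup_het_sites(sam, ("c1", 5, 100), cfg, pileup_ref)
        assert sites == []

    def test_rare_alt_rejected_as_homozygous_ref(self, tmp_path, cfg, pileup_ref):
        sam = _pileup_sam(tmp_path, "A" * 19 + "G")  # af 0.05 < het_af_lo
        sites = nb.pileup_het_sites(sam, ("c1", 1, 100), cfg, pileup_ref)
        assert sites == []

    def test_region_outside_contig_is_error(self, tmp_path, cfg, pileup_ref):
        sam = _pileup_sam(tmp_path, "AG")
        with pytest.raises(ValueError):
            nb.pileup_het_sites(sam, ("c1", 1, 5000), cfg, pileup_ref)


class TestAlleleMatrix:
    def test_rows_encode_ref_alt_and_missing(self, tmp_path, cfg, pileup_ref):
        # two het sites (positions 11 and 16); p10 carries a sequencing error
        # (third base, T) at site 16 but a clean ref allele at site 11
        lines = []
        for i in range(11):
            b11 = "A" if i < 5 or i == 10 else "G"
            b16 = ("A" if i < 5 else "G") if i < 10 else "T"
            seq = "A" * 10 + b11 + "A" * 4 + b16 + "A" * 5
            lines.append(f"p{i}\t0\tc1\t1\t60\t21M\t*\t0\t0\t{seq}\t*\n")
        sam = tmp_path / "mat.sam"
        sam.write_text(_HEADER + "".join(lines))
        sites = nb.pileup_het_sites(str(sam), ("c1", 1, 100), cfg, pileup_ref)
        assert [s.locus.pos for s in sites] == [11, 16]
        m = nb.allele_matrix(str(sam), sites, cfg)
        rows = {rid: list(m.matrix[i]) for i, rid in enumerate(m.read_ids)}
        assert rows["p0"] == [0, 0] and rows["p5"] == [1, 1]
        assert rows["p10"] == [0, -1]  # third base -> missing at that site


# ---------------------------------------------------------------------------
# MEC partitioning
# ---------------------------------------------------------------------------


class TestMec:
    def test_separable_matrix_partitions_with_zero_mec(self):
        m = _matrix([[0, 0], [0, 0], [1, 1], [1, 1]])
        part = nb.phase_reads(m)
        assert part.mec == 0
        groups = {part.assignment[r] for r in ("r0", "r1")}
        assert len(groups) == 1
        assert part.assignment["r2"] == part.assignment["r3"] != groups.pop()

    def test_single_conflicting_entry_costs_one(self):
        m = _matrix([[0, 0], [0, 1], [1, 1], [1, 1]])
        part = nb.phase_reads(m)
        assert part.mec == 1 == _mec_bruteforce(m.matrix)

    def test_mec_score_examples(self):
        m = _matrix([[0, 0], [0, 0], [1, 1], [1, 1]])
        assert nb.mec_score(m, [1, 1, 2, 2]) == 0
        assert nb.mec_score(m, [1, 2, 1, 2]) == 4

    def test_mec_invariant_under_label_swap(self):
        rng = np.random.default_rng(71)
        for _ in range(25):
            mat = rng.integers(-1, 2, size=(8, 6)).astype(np.int8)
            labels = rng.integers(1, 3, size=8)
            swapped = np.where(labels == 1, 2, 1)
            assert nb.mec_score(_matrix(mat), labels) == \
                nb.mec_score(_matrix(mat), swapped)

    @staticmethod
    def random_diploid_matrix(rng, n_reads, n_sites, error=0.05, missing=0.2):
        """Haplotype-structured matrix with random flips and dropout."""
        h1 = rng.integers(0, 2, size=n_sites)
        labels = rng.integers(0, 2, size=n_reads)
        mat = np.where(labels[:, None] == 0, h1[None, :], 1 - h1[None, :])
        flip = rng.random(mat.shape) < error
        mat = np.where(flip, 1 - mat, mat).astype(np.int8)
        mat[rng.random(mat.shape) < missing] = -1
        # guarantee every read keeps one observed entry
        for i in range(n_reads):
            if (mat[i] < 0).all():
                mat[i, rng.integers(n_sites)] = 0
        return mat

    def test_heuristic_matches_exhaustive_on_small_matrices(self):
        rng = np.random.default_rng(72)
        for _ in range(40):
            n = int(rng.integers(4, 11))
            s = int(rng.integers(3, 8))
            mat = self.random_diploid_matrix(rng, n, s)
            m = _matrix(mat)
            heur = nb.phase_reads(m, method="heuristic", rng_seed=0)
            exact = nb.phase_reads(m, method="exact")
            assert heur.mec == exact.mec == _mec_bruteforce(mat)

    def test_phasing_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(73)
        mat = self.random_diploid_matrix(rng, 20, 10)
        m = _matrix(mat)
        a = nb.phase_reads(m, method="heuristic", rng_seed=5)
        b = nb.phase_reads(m, method="heuristic", rng_seed=5)
        assert a.assignment == b.assignment and a.mec == b.mec

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            nb.phase_reads(_matrix([[-1, -1], [-1, -1]]))


class TestSvHaplotypeAssignment:
    @staticmethod
    def _partition(groups):
        return nb.HaplotypePartition(
            assignment={f"r{i}": g for i, g in enumerate(groups)},
            hap1_alleles=np.zeros(1, np.int8), hap2_alleles=np.ones(1, np.int8),
            mec=0)

    def test_unanimous_reads_assign(self):
        part = self._partition([1, 1, 1, 1, 1])
        assert nb.assign_sv_haplotype(part, [f"r{i}" for i in range(5)]) == "H1"

    def test_three_two_split_unassigned(self):
        part = self._partition([1, 1, 1, 2, 2])
        assert nb.assign_sv_haplotype(part, [f"r{i}" for i in range(5)]) == "unassigned"

    def test_too_few_overlapping_reads_unassigned(self):
        part = self._partition([1, 1, 1])
        assert nb.assign_sv_haplotype(part, ["r0", "zz"]) == "unassigned"


# ---------------------------------------------------------------------------
# Simulated diploid
# ---------------------------------------------------------------------------


def _switch_errors(phased, truth):
    """Count adjacent flips of the phased-vs-truth agreement pattern."""
    agree = [int(p == t) for p, t in zip(phased, truth) if p >= 0]
    return sum(1 for a, b in zip(agree, agree[1:]) if a != b)


def test_noiseless_diploid_phases_without_switch_errors(small_ref, cfg, tmp_path):
    haps, snp_table = sim.plant_het_variants(small_ref, 0.001, seed=81)
    der, _, _ = make_translocation(small_ref)
    der.snp_pos, der.snp_alt = haps[1].snp_pos, haps[1].snp_alt
    use = [haps[0], der]
    reads = sim.simulate_reads(use, small_ref, depth=12, seed=82,
                               error_model=sim.ErrorModel(0, 0, 0))
    sam = str(tmp_path / "dip.sam")
    sim.simulate_alignments(reads, use, small_ref, sam)

    sites = nb.pileup_het_sites(sam, ("chrA", 20_000, 50_000), cfg, small_ref)
    planted = {p for c, p, _, _ in snp_table if c == "chrA" and 20_000 <= p <= 50_000}
    assert {s.locus.pos for s in sites} <= planted
    assert len(sites) >= 20

    m = nb.allele_matrix(sam, sites, cfg)
    part = nb.phase_reads(m, rng_seed=cfg.rng_seed)
    assert part.mec == 0
    # alt alleles live on haplotype 2 by construction
    truth_alt = [1] * len(sites)
    assert min(_switch_errors(part.hap1_alleles, truth_alt),
               _switch_errors(part.hap2_alleles, truth_alt)) == 0

    # matrix rows match the source haplotype at >= 90% of observed entries
    truth_hap = {r.read_id: r.hap_index for r in reads.reads}
    for i, rid in enumerate(m.read_ids):
        row = m.matrix[i]
        obs = row[row >= 0]
        if len(obs) == 0:
            continue
        expect = 1 if truth_hap[rid] == 2 else 0
        assert (obs == expect).mean() >= 0.9

    # the rearrangement was planted on haplotype 2
    evs = [nb.junction_from_pair(sp) for ra in nb.read_alignments(sam, cfg)
           for sp in nb.split_candidates(ra, cfg)]
    calls = nb.call_breakends(evs, cfg)
    junction_reads = sorted({r for c in calls for r in c.read_ids})
    sv_hap = nb.assign_sv_haplotype(part, junction_reads)
    carrier_group = {part.assignment[r] for r in junction_reads
                     if r in part.assignment}
    if sv_hap != "unassigned":
        assert all(truth_hap[r] == 2 for r in junction_reads)
        assert carrier_group == {1 if sv_hap == "H1" else 2}
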