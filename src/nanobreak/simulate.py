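"""Synthetic data generation with full truth tracking.

Every pipeline stage is testable offline: this module builds random
references (optionally stamped with repeat units and N-runs), applies
reciprocal translocations and inversions with junction micro-indels to a
diploid genome, plants heterozygous SNVs, draws nanopore-like reads
(lognormal lengths, configurable mismatch/insertion/deletion rates with
default identity near 0.85), and emits the alignments a long-read aligner
would produce — primary plus SA-linked supplementary records with
junction-side soft clips — so tests need no external aligner.

Derivative genomes are represented as block lists over the reference
(interval, strand, or literal inserted sequence), which makes the
read-to-reference mapping, the junction truth table and the per-read
provenance exact by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .formats import AlignedSegment, Locus, ReadAlignment, Reference

__all__ = ["ErrorModel", "EventSpec", "Block", "HapContig", "Haplotype",
           "JunctionTruth", "TruthSet", "ReadTruth", "ReadSet",
           "make_reference", "diploid_from_reference", "apply_rearrangement",
           "apply_deletion", "plant_het_variants", "simulate_reads",
           "simulate_alignments"]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgtNn", b"TGCAtgcaNn"):
    _COMP[_a] = _b


def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _ACGT[rng.integers(0, 4, size=n)]


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ErrorModel:
    """Per-base error probabilities; defaults give read identity near 0.85."""

    mismatch_rate: float = 0.06
    ins_rate: float = 0.04
    del_rate: float = 0.05

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.ins_rate, self.del_rate):
            if not (0 <= r < 1):
                raise ValueError("error rates must lie in [0, 1)")
        if self.mismatch_rate + self.del_rate >= 1:
            raise ValueError("mismatch_rate + del_rate must be < 1")

    @property
    def noiseless(self) -> bool:
        return self.mismatch_rate == self.ins_rate == self.del_rate == 0


@dataclass
class EventSpec:
    """One planted rearrangement.

    For a reciprocal translocation, ``pos_a``/``pos_b`` are the 1-based last
    retained bases of each chromosome's own derivative; junction deletions
    remove bases immediately distal to the breakpoint on the resuming
    fragment and insertions add random sequence at the junction.  For an
    inversion, ``chrom_b`` is ``None`` and ``pos_b`` is the distal
    breakpoint on ``chrom_a``; the segment ``(pos_a, pos_b]`` is
    reverse-complemented in place.
    """

    kind: str  # reciprocal_translocation | inversion
    chrom_a: str
    pos_a: int
    pos_b: int
    chrom_b: str | None = None
    junction_del_a: int = 0
    junction_del_b: int = 0
    junction_ins_a: int = 0
    junction_ins_b: int = 0
    carrier_haplotype: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("reciprocal_translocation", "inversion"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if min(self.junction_del_a, self.junction_del_b,
               self.junction_ins_a, self.junction_ins_b) < 0:
            raise ValueError("junction indel sizes must be >= 0")
        if self.carrier_haplotype not in (1, 2):
            raise ValueError("carrier_haplotype must be 1 or 2")
        if self.kind == "inversion":
            if self.chrom_b is not None and self.chrom_b != self.chrom_a:
                raise ValueError("inversion must stay on one chromosome")
            if not self.pos_a < self.pos_b:
                raise ValueError("inversion requires pos_a < pos_b")


@dataclass
class Block:
    """One piece of a derivative contig: a reference slice or an insertion."""

    chrom: str | None  # None for inserted sequence
    start: int  # 0-based half-open on the reference
    end: int
    strand: str = "+"
    seq: str | None = None

    @property
    def length(self) -> int:
        return len(self.seq) if self.chrom is None else self.end - self.start


@dataclass
class HapContig:
    name: str
    blocks: list[Block]

    @property
    def length(self) -> int:
        return sum(b.length for b in self.blocks)

    def offsets(self) -> list[int]:
        """Cumulative start offset of each block (plus the total)."""
        out, acc = [0], 0
        for b in self.blocks:
            acc += b.length
            out.append(acc)
        return out


@dataclass
class Haplotype:
    index: int  # 1 | 2
    contigs: list[HapContig]
    snp_pos: dict[str, np.ndarray] = field(default_factory=dict)  # 0-based ref positions
    snp_alt: dict[str, np.ndarray] = field(default_factory=dict)  # uint8 bases

    @property
    def length(self) -> int:
        return sum(c.length for c in self.contigs)

    def materialize(self, reference: Reference) -> dict[str, np.ndarray]:
        """Contig sequences (uint8) with the SNP overlay applied."""
        base: dict[str, np.ndarray] = {}
        for chrom, seq in reference.sequences.items():
            arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
            if chrom in self.snp_pos and len(self.snp_pos[chrom]):
                arr[self.snp_pos[chrom]] = self.snp_alt[chrom]
            base[chrom] = arr
        out: dict[str, np.ndarray] = {}
        for contig in self.contigs:
            parts = []
            for b in contig.blocks:
                if b.chrom is None:
                    parts.append(np.frombuffer(b.seq.encode(), dtype=np.uint8))
                else:
                    piece = base[b.chrom][b.start:b.end]
                    parts.append(_revcomp_arr(piece) if b.strand == "-" else piece)
            out[contig.name] = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        return out


@dataclass
class JunctionTruth:
    """A planted novel adjacency inside one derivative contig."""

    contig: str
    offset: int  # 0-based derivative position where the right side begins
    locus_l: Locus
    ori_l: str
    locus_r: Locus
    ori_r: str
    ins_len: int
    svclass: str

    def breakends(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return ((self.locus_l.chrom, self.locus_l.pos, self.ori_l),
                (self.locus_r.chrom, self.locus_r.pos, self.ori_r))


@dataclass
class TruthSet:
    reference: Reference
    haplotypes: list[Haplotype]
    junctions: list[JunctionTruth] = field(default_factory=list)
    snp_table: list[tuple[str, int, str, str]] = field(default_factory=list)
    deleted_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def write_truth(self, prefix: str) -> None:
        with open(prefix + ".junctions.bedpe", "w") as fh:
            for i, j in enumerate(self.junctions):
                (c1, p1, o1), (c2, p2, o2) = j.breakends()
                fh.write(f"{c1}\t{p1 - 1}\t{p1}\t{c2}\t{p2 - 1}\t{p2}\t"
                         f"truth{i}\t0\t{o1}\t{o2}\t{j.svclass}\t{j.ins_len}\n")
        with open(prefix + ".snps.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\n")
            for chrom, pos, ref, alt in self.snp_table:
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
        with open(prefix + ".manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------


def make_reference(contig_lengths: dict[str, int], seed: int,
                   repeat_spec: dict | None = None) -> Reference:
    """Uniform-random reference, optionally stamped with repeats and N-runs.

    ``repeat_spec`` keys: ``unit_length`` (default 300, an Alu-scale unit),
    ``placements`` — list of (chrom, 0-based pos) where exact copies of the
    unit are stamped, and ``n_runs`` — list of (chrom, 0-based start,
    length) to stamp N-runs (centromere/assembly-gap stand-ins).
    Overlapping stamped features are an error.  Deterministic per seed.
    """
    for name, length in contig_lengths.items():
        if length < 10_000:
            raise ValueError(f"contig {name!r} shorter than 10 kb")
    rng = np.random.default_rng(seed)
    seqs = {name: _rand_seq(rng, length) for name, length in contig_lengths.items()}

    if repeat_spec:
        unit_len = int(repeat_spec.get("unit_length", 300))
        unit = _rand_seq(rng, unit_len)
        stamped: dict[str, list[tuple[int, int]]] = {}

        def stamp(chrom: str, start: int, payload: np.ndarray) -> None:
            end = start + len(payload)
            if chrom not in seqs:
                raise ValueError(f"repeat_spec references unknown contig {chrom!r}")
            if not (0 <= start and end <= len(seqs[chrom])):
                raise ValueError(f"stamped feature {chrom}:{start}-{end} outside contig")
            for s, e in stamped.get(chrom, []):
                if start < e and s < end:
                    raise ValueError(f"overlapping stamped features on {chrom} at {start}")
            stamped.setdefault(chrom, []).append((start, end))
            seqs[chrom][start:end] = payload

        for chrom, pos in repeat_spec.get("placements", []):
            stamp(chrom, int(pos), unit)
        for chrom, start, length in repeat_spec.get("n_runs", []):
            stamp(chrom, int(start), np.full(int(length), ord("N"), dtype=np.uint8))

    return Reference({name: arr.tobytes().decode() for name, arr in seqs.items()})


def diploid_from_reference(reference: Reference) -> list[Haplotype]:
    """Two identical haplotypes, each one identity block per contig."""
    haps = []
    for idx in (1, 2):
        contigs = [HapContig(name=c, blocks=[Block(c, 0, reference.lengths[c])])
                   for c in reference.sequences]
        haps.append(Haplotype(index=idx, contigs=contigs))
    return haps


# ---------------------------------------------------------------------------
# Rearrangement and variant planting
# ---------------------------------------------------------------------------


def _check_pos(reference: Reference, chrom: str, pos: int) -> None:
    if chrom not in reference.lengths:
        raise ValueError(f"unknown contig {chrom!r}")
    if not (1 <= pos <= reference.lengths[chrom]):
        raise ValueError(f"position {chrom}:{pos} outside contig")
    p0 = pos - 1
    for s, e in reference.n_runs(chrom):
        if s <= p0 < e:
            raise ValueError(f"breakpoint {chrom}:{pos} lies in an N-run; junction undefined")


def apply_rearrangement(reference: Reference, hap: Haplotype, spec: EventSpec,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[Haplotype, list[JunctionTruth], list[tuple[str, int, int]]]:
    """Rearrange a haplotype per ``spec``; returns the derivative haplotype,
    the junction truth table, and micro-deleted reference intervals
    (1-based inclusive)."""
    rng = rng or np.random.default_rng(0)
    _check_pos(reference, spec.chrom_a, spec.pos_a)
    _check_pos(reference, spec.chrom_b or spec.chrom_a, spec.pos_b)
    by_name = {c.name: c for c in hap.contigs}

    def intact(chrom: str) -> None:
        c = by_name.get(chrom)
        if c is None or len(c.blocks) != 1 or c.blocks[0].chrom != chrom:
            raise ValueError(f"contig {chrom!r} already rearranged or missing")

    junctions: list[JunctionTruth] = []
    deleted: list[tuple[str, int, int]] = []

    if spec.kind == "reciprocal_translocation":
        if spec.chrom_b is None or spec.chrom_b == spec.chrom_a:
            raise ValueError("reciprocal translocation needs two distinct chromosomes")
        intact(spec.chrom_a)
        intact(spec.chrom_b)
        A, B = spec.chrom_a, spec.chrom_b
        len_a, len_b = reference.lengths[A], reference.lengths[B]
        if spec.pos_a + spec.junction_del_a > len_a or spec.pos_b + spec.junction_del_b > len_b:
            raise ValueError("junction deletion extends past the contig end")
        ins_a = _rand_seq(rng, spec.junction_ins_a).tobytes().decode()
        ins_b = _rand_seq(rng, spec.junction_ins_b).tobytes().decode()

        der_a = [Block(A, 0, spec.pos_a)]
        if ins_a:
            der_a.append(Block(None, 0, 0, seq=ins_a))
        der_a.append(Block(B, spec.pos_b + spec.junction_del_b, len_b))
        der_b = [Block(B, 0, spec.pos_b)]
        if ins_b:
            der_b.append(Block(None, 0, 0, seq=ins_b))
        der_b.append(Block(A, spec.pos_a + spec.junction_del_a, len_a))

        new_contigs = []
        for c in hap.contigs:
            if c.name == A:
                new_contigs.append(HapContig(name=f"der_{A}", blocks=der_a))
            elif c.name == B:
                new_contigs.append(HapContig(name=f"der_{B}", blocks=der_b))
            else:
                new_contigs.append(c)
        junctions.append(JunctionTruth(
            contig=f"der_{A}", offset=spec.pos_a,
            locus_l=Locus(A, spec.pos_a), ori_l="+",
            locus_r=Locus(B, spec.pos_b + spec.junction_del_b + 1), ori_r="-",
            ins_len=spec.junction_ins_a, svclass="translocation"))
        junctions.append(JunctionTruth(
            contig=f"der_{B}", offset=spec.pos_b,
            locus_l=Locus(B, spec.pos_b), ori_l="+",
            locus_r=Locus(A, spec.pos_a + spec.junction_del_a + 1), ori_r="-",
            ins_len=spec.junction_ins_b, svclass="translocation"))
        if spec.junction_del_a:
            deleted.append((A, spec.pos_a + 1, spec.pos_a + spec.junction_del_a))
        if spec.junction_del_b:
            deleted.append((B, spec.pos_b + 1, spec.pos_b + spec.junction_del_b))
    else:  # inversion
        if max(spec.junction_del_a, spec.junction_del_b,
               spec.junction_ins_a, spec.junction_ins_b) > 0:
            raise ValueError("junction indels are not supported for inversions")
        intact(spec.chrom_a)
        A = spec.chrom_a
        len_a = reference.lengths[A]
        blocks = [Block(A, 0, spec.pos_a),
                  Block(A, spec.pos_a, spec.pos_b, strand="-"),
                  Block(A, spec.pos_b, len_a)]
        blocks = [b for b in blocks if b.length > 0]
        new_contigs = [HapContig(name=f"der_{A}", blocks=blocks) if c.name == A else c
                       for c in hap.contigs]
        junctions.append(JunctionTruth(
            contig=f"der_{A}", offset=spec.pos_a,
            locus_l=Locus(A, spec.pos_a), ori_l="+",
            locus_r=Locus(A, spec.pos_b), ori_r="+",
            ins_len=0, svclass="inversion"))
        junctions.append(JunctionTruth(
            contig=f"der_{A}", offset=spec.pos_b,
            locus_l=Locus(A, spec.pos_a + 1), ori_l="-",
            locus_r=Locus(A, spec.pos_b + 1), ori_r="-",
            ins_len=0, svclass="inversion"))

    derived = Haplotype(index=hap.index, contigs=new_contigs,
                        snp_pos=hap.snp_pos, snp_alt=hap.snp_alt)
    return derived, junctions, deleted


def apply_deletion(reference: Reference, hap: Haplotype, chrom: str,
                   start: int, end: int) -> Haplotype:
    """Delete the 1-based inclusive interval [start, end] from one haplotype
    (copy-number test helper; not a junction-truth event)."""
    if not (1 <= start <= end <= reference.lengths[chrom]):
        raise ValueError("deletion interval outside contig")
    new_contigs = []
    for c in hap.contigs:
        if c.name == chrom and len(c.blocks) == 1 and c.blocks[0].chrom == chrom:
            blocks = [Block(chrom, 0, start - 1), Block(chrom, end, reference.lengths[chrom])]
            new_contigs.append(HapContig(name=f"del_{chrom}",
                                         blocks=[b for b in blocks if b.length > 0]))
        else:
            new_contigs.append(c)
    return Haplotype(index=hap.index, contigs=new_contigs,
                     snp_pos=hap.snp_pos, snp_alt=hap.snp_alt)


def plant_het_variants(reference: Reference, rate: float, seed: int,
                       haplotypes: list[Haplotype] | None = None,
                       ) -> tuple[list[Haplotype], list[tuple[str, int, str, str]]]:
    """Substitute bases on haplotype 2 at Bernoulli(rate) positions.

    N-run positions are never mutated.  Returns the (possibly newly built)
    diploid pair and the variant truth table (chrom, 1-based pos, ref, alt).
    """
    if not (0 <= rate < 0.01):
        raise ValueError("het rate must lie in [0, 0.01)")
    rng = np.random.default_rng(seed)
    haps = haplotypes if haplotypes is not None else diploid_from_reference(reference)
    table: list[tuple[str, int, str, str]] = []
    hap2 = next(h for h in haps if h.index == 2)
    for chrom, seq in reference.sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        pos = np.flatnonzero(rng.random(len(arr)) < rate) if rate > 0 else np.empty(0, np.int64)
        ok = arr[pos] != ord("N")
        pos = pos[ok]
        ref_bases = arr[pos]
        # shift each base by 1-3 within ACGT so alt always differs from ref
        ref_idx = np.searchsorted(_ACGT, ref_bases)
        alt = _ACGT[(ref_idx + rng.integers(1, 4, size=len(pos))) % 4]
        hap2.snp_pos[chrom] = pos
        hap2.snp_alt[chrom] = alt
        table.extend((chrom, int(p) + 1, chr(r), chr(a))
                     for p, r, a in zip(pos, ref_bases, alt))
    return haps, table


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadTruth:
    read_id: str
    hap_index: int
    contig: str
    start: int  # 0-based half-open template interval on the derivative contig
    end: int
    strand: str  # sequencer orientation relative to the contig
    seq: str | None = None  # as sequenced (reverse-complemented when strand is -)
    keep: np.ndarray | None = None  # template positions surviving deletion errors
    ins: np.ndarray | None = None  # insertion-after flags per template position
    mis: np.ndarray | None = None  # mismatch flags per template position

    @property
    def length(self) -> int:
        if self.seq is not None:
            return len(self.seq)
        if self.keep is not None:
            return int(self.keep.sum() + self.ins.sum())
        return self.end - self.start


@dataclass
class ReadSet:
    reads: list[ReadTruth]
    error_model: ErrorModel
    seed: int

    def write_fastq(self, path: str) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                if r.seq is None:
                    raise ValueError("read set was simulated without sequences")
                fh.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def _lognormal_lengths(rng: np.random.Generator, n: int, mean_len: float,
                       sigma: float = 0.6, lo: int = 1_000, hi: int = 100_000,
                       ) -> np.ndarray:
    mu = np.log(mean_len) - sigma ** 2 / 2
    return np.clip(rng.lognormal(mu, sigma, size=n).astype(np.int64), lo, hi)


def _apply_errors(template: np.ndarray, rng: np.random.Generator, em: ErrorModel,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Returns (read array in template orientation, keep, ins, mis masks)."""
    L = len(template)
    r = rng.random(L)
    keep = r >= em.del_rate
    mis = keep & (r < em.del_rate + em.mismatch_rate)
    ins = rng.random(L) < em.ins_rate

    bases = template.copy()
    mi = np.flatnonzero(mis)
    if len(mi):
        idx = np.searchsorted(_ACGT, bases[mi])
        bases[mi] = _ACGT[(idx + rng.integers(1, 4, size=len(mi))) % 4]

    contrib = keep.astype(np.int64) + ins.astype(np.int64)
    ends = np.cumsum(contrib)
    starts = ends - contrib
    out = np.empty(int(ends[-1]) if L else 0, dtype=np.uint8)
    out[starts[keep]] = bases[keep]
    ins_slots = (starts + keep.astype(np.int64))[ins]
    if len(ins_slots):
        out[ins_slots] = _rand_seq(rng, len(ins_slots))
    return out, keep, ins, mis


def simulate_reads(haplotypes: Sequence[Haplotype], reference: Reference,
                   depth: float, seed: int, mean_length: float = 13_000,
                   sigma: float = 0.6, error_model: ErrorModel | None = None,
                   with_sequences: bool = True) -> ReadSet:
    """Draw reads alternating over the given haplotypes to the target total depth.

    Starts are uniform per contig (contigs weighted by length); lengths are
    lognormal with the given mean, truncated to [1 kb, 100 kb] and to the
    contig end.  With ``with_sequences=False`` only the layout (per-read
    provenance) is generated — enough for read-count analyses.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    em = error_model if error_model is not None else ErrorModel()
    rng = np.random.default_rng(seed)
    mean_hap_len = float(np.mean([h.length for h in haplotypes]))
    n_reads = max(int(round(depth * mean_hap_len / mean_length)), 1)
    lengths = _lognormal_lengths(rng, n_reads, mean_length, sigma)

    mats = {id(h): h.materialize(reference) for h in haplotypes} if with_sequences else {}
    contig_choices = []
    for h in haplotypes:
        names = [c.name for c in h.contigs]
        lens = np.array([c.length for c in h.contigs], dtype=float)
        contig_choices.append((names, lens / lens.sum(),
                               {c.name: c.length for c in h.contigs}))

    reads: list[ReadTruth] = []
    for i in range(n_reads):
        hap = haplotypes[i % len(haplotypes)]
        names, probs, lens = contig_choices[i % len(haplotypes)]
        contig = names[int(rng.choice(len(names), p=probs))]
        clen = lens[contig]
        start = int(rng.integers(0, clen))
        end = min(start + int(lengths[i]), clen)
        strand = "+" if rng.random() < 0.5 else "-"
        rt = ReadTruth(read_id=f"r{i:06d}", hap_index=hap.index, contig=contig,
                       start=start, end=end, strand=strand)
        if with_sequences:
            template = mats[id(hap)][contig][start:end]
            if em.noiseless:
                arr = template.copy()
                rt.keep = np.ones(len(template), dtype=bool)
                rt.ins = np.zeros(len(template), dtype=bool)
                rt.mis = np.zeros(len(template), dtype=bool)
            else:
                arr, rt.keep, rt.ins, rt.mis = _apply_errors(template, rng, em)
            if strand == "-":
                arr = _revcomp_arr(arr)
            rt.seq = arr.tobytes().decode()
        reads.append(rt)
    return ReadSet(reads=reads, error_model=em, seed=seed)


# ---------------------------------------------------------------------------
# Aligner emulation
# ---------------------------------------------------------------------------

_M, _I, _D = 0, 1, 2


def _cigar_runs(keep: np.ndarray, ins: np.ndarray) -> list[list[int]]:
    """Per-template-position op stream (M/D then optional I), run-length encoded."""
    n = len(keep)
    tokens = np.empty(2 * n, dtype=np.int8)
    tokens[0::2] = np.where(keep, _M, _D)
    tokens[1::2] = np.where(ins, _I, 3)
    tokens = tokens[tokens != 3]
    if len(tokens) == 0:
        return []
    change = np.flatnonzero(np.diff(tokens)) + 1
    bounds = np.concatenate(([0], change, [len(tokens)]))
    return [[int(tokens[b]), int(e - b)] for b, e in zip(bounds[:-1], bounds[1:])]


def _trim_runs(runs: list[list[int]]) -> tuple[list[list[int]], int, int, int, int]:
    """Strip leading/trailing D (unaligned template) and I (clip-absorbed query)."""
    lead_del = lead_ins = trail_del = trail_ins = 0
    while runs and runs[0][0] in (_D, _I):
        op, ln = runs.pop(0)
        if op == _D:
            lead_del += ln
        else:
            lead_ins += ln
    while runs and runs[-1][0] in (_D, _I):
        op, ln = runs.pop()
        if op == _D:
            trail_del += ln
        else:
            trail_ins += ln
    return runs, lead_del, lead_ins, trail_del, trail_ins


def _count_snps(hap: Haplotype, chrom: str, ref_start0: int, ref_end0: int) -> int:
    pos = hap.snp_pos.get(chrom)
    if pos is None or not len(pos):
        return 0
    return int(np.searchsorted(pos, ref_end0) - np.searchsorted(pos, ref_start0))


def simulate_alignments(readset: ReadSet, haplotypes: Sequence[Haplotype],
                        reference: Reference, path: str) -> None:
    """Emit the SAM a long-read aligner would produce for the simulated reads.

    Each read yields one record per reference segment it traverses (block
    structure of its source contig), with the longest-aligned record primary
    and the rest supplementary, SA-linked; junction-side bases are soft
    clips and CIGARs reflect the planted errors.  Records are
    coordinate-sorted.  Reads spanning more than three junctions are not
    supported.
    """
    by_index = {h.index: h for h in haplotypes}
    contig_maps: dict[tuple[int, str], HapContig] = {}
    for h in haplotypes:
        for c in h.contigs:
            contig_maps[(h.index, c.name)] = c

    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": name, "LN": reference.lengths[name]}
                for name in reference.sequences]})
    ref_ids = {name: i for i, name in enumerate(reference.sequences)}
    records = []

    for rt in readset.reads:
        if rt.seq is None:
            raise ValueError("alignments need simulated sequences")
        hap = by_index[rt.hap_index]
        contig = contig_maps[(rt.hap_index, rt.contig)]
        offsets = contig.offsets()
        spanned = sum(1 for o in offsets[1:-1] if rt.start < o < rt.end)
        if spanned > 3:
            raise ValueError(f"read {rt.read_id} spans {spanned} junctions (> 3 unsupported)")

        keep, ins = rt.keep, rt.ins
        qcum = np.concatenate(([0], np.cumsum(keep.astype(np.int64) + ins.astype(np.int64))))
        lq = int(qcum[-1])
        stored_cache: dict[bool, str] = {}
        templ_read = rt.seq if rt.strand == "+" else _revcomp_arr(
            np.frombuffer(rt.seq.encode(), dtype=np.uint8)).tobytes().decode()

        segs = []
        for bi, block in enumerate(contig.blocks):
            b_lo, b_hi = offsets[bi], offsets[bi + 1]
            t0, t1 = max(rt.start, b_lo), min(rt.end, b_hi)
            if t1 <= t0 or block.chrom is None:
                continue
            a, b = t0 - rt.start, t1 - rt.start
            runs, lead_del, lead_ins, trail_del, trail_ins = _trim_runs(
                _cigar_runs(keep[a:b], ins[a:b]))
            if not runs:
                continue
            q_lo = int(qcum[a]) + lead_ins
            q_hi = int(qcum[b]) - trail_ins
            if q_hi <= q_lo:
                continue
            # template (contig-forward) positions actually aligned
            t0p, t1p = t0 + lead_del, t1 - trail_del
            off_in_block_lo, off_in_block_hi = t0p - b_lo, t1p - b_lo
            if block.strand == "+":
                ref_s0 = block.start + off_in_block_lo
                ref_e0 = block.start + off_in_block_hi
                cig_runs = runs
                left_clip, right_clip = q_lo, lq - q_hi
            else:
                ref_s0 = block.end - off_in_block_hi
                ref_e0 = block.end - off_in_block_lo
                cig_runs = runs[::-1]
                left_clip, right_clip = lq - q_hi, q_lo
            rec_strand = (block.strand if rt.strand == "+"
                          else ("-" if block.strand == "+" else "+"))
            n_ins = sum(ln for op, ln in runs if op == _I)
            n_del = sum(ln for op, ln in runs if op == _D)
            n_mis = int(rt.mis[a:b].sum())  # trimmed edges hold no mismatches
            nm = n_ins + n_del + n_mis + _count_snps(hap, block.chrom, ref_s0, ref_e0)
            cigar = []  # _M/_I/_D match the SAM numeric op codes
            if left_clip:
                cigar.append((4, left_clip))
            cigar.extend((op, ln) for op, ln in cig_runs)
            if right_clip:
                cigar.append((4, right_clip))
            stored_fwd = block.strand == "+"
            if stored_fwd not in stored_cache:
                stored_cache[stored_fwd] = templ_read if stored_fwd else _revcomp_arr(
                    np.frombuffer(templ_read.encode(), dtype=np.uint8)).tobytes().decode()
            segs.append({"chrom": block.chrom, "pos0": ref_s0, "strand": rec_strand,
                         "cigar": cigar, "nm": nm, "seq": stored_cache[stored_fwd],
                         "qspan": q_hi - q_lo})
        if not segs:
            continue
        primary = max(range(len(segs)), key=lambda k: segs[k]["qspan"])
        for k, sd in enumerate(segs):
            rec = pysam.AlignedSegment(header=header)
            rec.query_name = rt.read_id
            rec.reference_id = ref_ids[sd["chrom"]]
            rec.reference_start = sd["pos0"]
            rec.mapping_quality = 60
            rec.cigartuples = sd["cigar"]
            rec.query_sequence = sd["seq"]
            rec.flag = (16 if sd["strand"] == "-" else 0) | (0 if k == primary else 2048)
            sa = "".join(
                f"{o['chrom']},{o['pos0'] + 1},{o['strand']},"
                f"{_cigar_str(o['cigar'])},60,{o['nm']};"
                for j, o in enumerate(segs) if j != k)
            tags = [("NM", sd["nm"])]
            if sa:
                tags.append(("SA", sa))
            rec.set_tags(tags)
            records.append(rec)

    records.sort(key=lambda r: (r.reference_id, r.reference_start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def _cigar_str(cigar: list[tuple[int, int]]) -> str:
    ops = "MIDNSHP=X"
    return "".join(f"{ln}{ops[op]}" for op, ln in cigar)


def layout_to_alignments(readset: ReadSet, haplotypes: Sequence[Haplotype],
                         ) -> list[ReadAlignment]:
    """Error-free in-memory alignments straight from the read layout.

    Bypasses SAM for analyses that only need coordinates (window read
    counts): each read maps through its contig's block structure to exact
    reference segments with all-match tallies.
    """
    contig_maps = {(h.index, c.name): c for h in haplotypes for c in h.contigs}
    out = []
    for rt in readset.reads:
        contig = contig_maps[(rt.hap_index, rt.contig)]
        offsets = contig.offsets()
        segs = []
        read_off = 0
        for bi, block in enumerate(contig.blocks):
            t0, t1 = max(rt.start, offsets[bi]), min(rt.end, offsets[bi + 1])
            if t1 <= t0:
                continue
            span = t1 - t0
            if block.chrom is not None:
                off_lo, off_hi = t0 - offsets[bi], t1 - offsets[bi]
                if block.strand == "+":
                    rs, re = block.start + off_lo, block.start + off_hi
                else:
                    rs, re = block.end - off_hi, block.end - off_lo
                segs.append(AlignedSegment(
                    read_id=rt.read_id, chrom=block.chrom,
                    ref_start=rs + 1, ref_end=re,
                    read_start=read_off + 1, read_end=read_off + span,
                    strand=block.strand, mapq=60, n_match=span,
                    is_primary=False))
            read_off += span
        if not segs:
            continue
        longest = max(segs, key=lambda s: s.read_span)
        longest.is_primary = True
        total = rt.end - rt.start
        if rt.strand == "-":
            for s in segs:
                s.read_start, s.read_end = total - s.read_end + 1, total - s.read_start + 1
                s.strand = "+" if s.strand == "-" else "-"
            segs.sort(key=lambda s: s.read_start)
        out.append(ReadAlignment(read_id=rt.read_id, read_length=total, segments=segs))
    return out
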