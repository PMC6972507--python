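"""Split-read evidence extraction: per-read junction calls from chimeric alignments.

A chimeric (split) read aligns in two or more segments; the boundary between
segments adjacent on the read marks a candidate breakpoint junction.  Each
surviving adjacent pair yields one :class:`JunctionEvidence` carrying the two
breakend loci, their orientation, the unaligned read bases at the junction
(inserted sequence), and the pair's quality attributes.

Orientation convention: each breakend carries ``+`` when the aligned segment
lies on the reference to the *left* of (and including) the breakend position
(junction at the segment's end), and ``-`` when it lies to the right
(junction at the segment's start).  This matches the VCF 4.2 bracket table:
a ``+-`` junction at A:p1 / B:p2 is written ``N[B:p2[``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats import AlignedSegment, Config, Locus, ReadAlignment, segment_identity

__all__ = ["SplitPair", "JunctionEvidence", "split_candidates",
           "junction_from_pair", "classify_evidence", "evidence_to_tsv"]


@dataclass
class SplitPair:
    """Two alignment segments of one read, adjacent in read order."""

    read_id: str
    seg_a: AlignedSegment
    seg_b: AlignedSegment


@dataclass
class JunctionEvidence:
    """One split read's inferred pair of breakends."""

    read_id: str
    bnd_1: Locus
    side_1: str  # "end" (+) | "start" (-)
    bnd_2: Locus
    side_2: str
    orientation: str  # two chars from {+,-}: bnd_1 then bnd_2
    svclass: str  # translocation | inversion | intra_other
    read_gap: int  # unaligned read bases at the junction (inserted sequence)
    min_mapq_of_pair: int
    min_identity_of_pair: float

    def canonical(self) -> "JunctionEvidence":
        """Order breakends by (chrom, pos) so equivalent evidence compares equal."""
        if (self.bnd_1.chrom, self.bnd_1.pos) <= (self.bnd_2.chrom, self.bnd_2.pos):
            return self
        return JunctionEvidence(
            read_id=self.read_id,
            bnd_1=self.bnd_2, side_1=self.side_2,
            bnd_2=self.bnd_1, side_2=self.side_1,
            orientation=self.orientation[1] + self.orientation[0],
            svclass=self.svclass, read_gap=self.read_gap,
            min_mapq_of_pair=self.min_mapq_of_pair,
            min_identity_of_pair=self.min_identity_of_pair)


def split_candidates(ra: ReadAlignment, cfg: Config) -> list[SplitPair]:
    """Adjacent segment pairs of a read after quality filtering.

    Segments failing ``min_mapq`` or ``min_segment_len`` are dropped first;
    every adjacency among the survivors (in read order) yields one pair, so a
    read with k kept segments yields k-1 pairs.  Pairs whose read spans
    overlap by more than half of the shorter segment are rejected as
    alignment artifacts.
    """
    kept = [s for s in ra.segments
            if s.mapq >= cfg.min_mapq and s.read_span >= cfg.min_segment_len]
    kept.sort(key=lambda s: (s.read_start, s.read_end))
    pairs = []
    for a, b in zip(kept, kept[1:]):
        overlap = a.read_end - b.read_start + 1
        if overlap > 0.5 * min(a.read_span, b.read_span):
            continue
        pairs.append(SplitPair(read_id=ra.read_id, seg_a=a, seg_b=b))
    return pairs


def junction_from_pair(sp: SplitPair) -> JunctionEvidence:
    """Derive the breakend pair implied by one split pair.

    The first segment's breakend sits at its read-distal reference end
    (``ref_end`` on ``+``, ``ref_start`` on ``-``); the second segment's at
    its read-proximal end.  The breakpoint is assigned to the last aligned
    base of each segment; unaligned read bases between the segments are
    reported as ``read_gap`` (junction insertion length).
    """
    a, b = sp.seg_a, sp.seg_b
    if a.strand == "+":
        pos1, ori1 = a.ref_end, "+"
    else:
        pos1, ori1 = a.ref_start, "-"
    if b.strand == "+":
        pos2, ori2 = b.ref_start, "-"
    else:
        pos2, ori2 = b.ref_end, "+"

    if a.chrom != b.chrom:
        svclass = "translocation"
    elif a.strand != b.strand:
        svclass = "inversion"
    else:
        svclass = "intra_other"

    return JunctionEvidence(
        read_id=sp.read_id,
        bnd_1=Locus(a.chrom, pos1), side_1="end" if ori1 == "+" else "start",
        bnd_2=Locus(b.chrom, pos2), side_2="end" if ori2 == "+" else "start",
        orientation=ori1 + ori2,
        svclass=svclass,
        read_gap=max(b.read_start - a.read_end - 1, 0),
        min_mapq_of_pair=min(a.mapq, b.mapq),
        min_identity_of_pair=min(segment_identity(a), segment_identity(b)),
    )


def classify_evidence(ev: JunctionEvidence, cfg: Config) -> tuple[str, bool]:
    """Return (svclass, keep?).

    Interchromosomal evidence is always retained for clustering.  Within a
    chromosome, junctions spanning less than ``min_sv_len`` are rejected as
    alignment artifacts (same-strand) or below the caller's minimum SV size
    (inversions).
    """
    if ev.svclass == "translocation":
        return ev.svclass, True
    span = abs(ev.bnd_1.pos - ev.bnd_2.pos)
    return ev.svclass, span >= cfg.min_sv_len


def evidence_to_tsv(evidences, path_or_handle) -> None:
    """Debugging dump of raw per-read evidence."""
    import csv

    close = False
    fh = path_or_handle
    if isinstance(path_or_handle, str):
        fh, close = open(path_or_handle, "w"), True
    try:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["read_id", "chromA", "posA", "sideA", "chromB", "posB", "sideB",
                    "orientation", "svclass", "read_gap", "min_mapq", "min_identity"])
        for ev in evidences:
            w.writerow([ev.read_id, ev.bnd_1.chrom, ev.bnd_1.pos, ev.side_1,
                        ev.bnd_2.chrom, ev.bnd_2.pos, ev.side_2, ev.orientation,
                        ev.svclass, ev.read_gap, ev.min_mapq_of_pair,
                        f"{ev.min_identity_of_pair:.4f}"])
    finally:
        if close:
            fh.close()
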