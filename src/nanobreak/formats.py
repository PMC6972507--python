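"""Standard-format I/O, shared domain types, and per-sample QC summaries.

Coordinate conventions
----------------------
All user-facing coordinates (``Locus.pos``, VCF, the call TSV) are 1-based
inclusive.  Internal interval arithmetic (reference N-run scans, BED/BEDPE,
window bookkeeping) is 0-based half-open; conversion happens only at the
I/O boundary.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

__all__ = [
    "Locus",
    "AlignedSegment",
    "ReadAlignment",
    "QCReport",
    "Config",
    "Reference",
    "parse_locus",
    "parse_region",
    "read_alignments",
    "segment_identity",
    "read_length_n50",
    "qc_summary",
    "write_breakend_vcf",
    "read_breakend_vcf",
    "write_bedpe",
    "read_bedpe",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Locus:
    """A 1-based reference position with a signed uncertainty interval.

    ``ci_lo``/``ci_hi`` are offsets around ``pos`` (both 0 for a precise
    breakend); a ranged entry like ``22:20326956~20327048`` is stored as the
    lower bound with ``ci_hi`` equal to the span.
    """

    chrom: str
    pos: int
    ci_lo: int = 0
    ci_hi: int = 0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not (self.ci_lo <= 0 <= self.ci_hi):
            raise ValueError(f"confidence interval must bracket 0: ({self.ci_lo},{self.ci_hi})")

    @property
    def precise(self) -> bool:
        return self.ci_lo == 0 and self.ci_hi == 0

    def __str__(self) -> str:
        if self.precise:
            return f"{self.chrom}:{self.pos}"
        return f"{self.chrom}:{self.pos + self.ci_lo}~{self.pos + self.ci_hi}"


@dataclass
class AlignedSegment:
    """One mapped block of a read.

    Reference span is 1-based inclusive.  ``read_start``/``read_end`` are
    1-based inclusive positions on the read in its original (sequencer)
    orientation, clips included.  Tallies satisfy
    ``n_match + n_mismatch + n_del == ref_end - ref_start + 1``.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    mapq: int
    n_match: int = 0
    n_mismatch: int = 0
    n_ins: int = 0
    n_del: int = 0
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end:
            raise ValueError("ref_start must be <= ref_end")
        if self.read_start > self.read_end:
            raise ValueError("read_start must be <= read_end")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start + 1


@dataclass
class ReadAlignment:
    """All mapped blocks of one read, ordered along the read."""

    read_id: str
    read_length: int
    segments: list[AlignedSegment] = field(default_factory=list)

    def primary(self) -> AlignedSegment | None:
        for seg in self.segments:
            if seg.is_primary:
                return seg
        return None


@dataclass
class QCReport:
    n_reads: int
    n_mapped_bases: int
    mean_len: float
    median_len: float
    n50: int
    mean_identity: float
    median_identity: float
    depth: float
    coverage_rate: float
    warning: str = ""

    def to_row(self) -> dict:
        d = dataclasses.asdict(self)
        d["coverage_rate_pct"] = 100.0 * self.coverage_rate
        return d


@dataclass
class Config:
    """Pipeline thresholds.  Sizes are in bases; fractions in [0, 1]."""

    min_mapq: int = 20
    min_segment_len: int = 200
    cluster_tol: int = 1000
    min_support: int = 3
    min_sv_len: int = 50
    merge_tol: int = 200
    cnv_window: int = 10_000
    cnv_log2_thresh: float = 0.4
    cnv_min_windows: int = 3
    phase_flank: int = 2_000_000
    het_min_depth: int = 5
    het_af_lo: float = 0.2
    het_af_hi: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_segment_len", "cluster_tol", "min_support", "min_sv_len",
                     "merge_tol", "cnv_window", "cnv_min_windows", "phase_flank",
                     "het_min_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.het_af_lo < self.het_af_hi <= 1):
            raise ValueError("require 0 <= het_af_lo < het_af_hi <= 1")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------


class Reference:
    """In-memory reference with contig lengths, N-run index and FASTA I/O."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = dict(sequences)
        self.lengths = {name: len(s) for name, s in self.sequences.items()}
        self._n_runs: dict[str, list[tuple[int, int]]] = {}
        for name, seq in self.sequences.items():
            arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            mask = arr == ord("N")
            edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.uint8), [0]))))
            self._n_runs[name] = list(zip(edges[0::2].tolist(), edges[1::2].tolist()))

    @classmethod
    def from_fasta(cls, path: str) -> "Reference":
        seqs: dict[str, str] = {}
        with pysam.FastxFile(str(path)) as fh:
            for rec in fh:
                seqs[rec.name] = rec.sequence
        return cls(seqs)

    def n_runs(self, chrom: str) -> list[tuple[int, int]]:
        """0-based half-open intervals of N bases on ``chrom``."""
        return self._n_runs[chrom]

    def non_n_length(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return self.lengths[chrom] - sum(e - s for s, e in self._n_runs[chrom])
        return sum(self.non_n_length(c) for c in self.sequences)

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """0-based half-open slice, clamped to the contig."""
        return self.sequences[chrom][max(0, start0):min(self.lengths[chrom], end0)]

    def write(self, path: str, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
        pysam.faidx(str(path))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_LOCUS_RE = re.compile(r"^([^:\s~]+):(\d+)(?:~(\d+))?$")


def parse_locus(text: str) -> Locus:
    """Parse ``CHROM:POS`` or ranged ``CHROM:POS~POS`` breakpoint notation.

    The ranged form returns the lower bound with ``ci_hi`` set to the span.
    """
    m = _LOCUS_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed breakpoint locus {text!r}: expected CHROM:POS or CHROM:POS~POS")
    chrom, lo = m.group(1), int(m.group(2))
    if m.group(3) is None:
        return Locus(chrom, lo)
    hi = int(m.group(3))
    if hi < lo:
        raise ValueError(f"malformed breakpoint locus {text!r}: range upper bound {hi} < lower bound {lo}")
    return Locus(chrom, lo, 0, hi - lo)


_REGION_RE = re.compile(r"^([^:\s]+):([\d,]+)-([\d,]+)$")


def parse_region(text: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive; commas allowed)."""
    m = _REGION_RE.match(text.strip())
    if not m:
        raise ValueError(f"malformed region {text!r}: expected chrom:start-end")
    start, end = int(m.group(2).replace(",", "")), int(m.group(3).replace(",", ""))
    if not (1 <= start <= end):
        raise ValueError(f"malformed region {text!r}: need 1 <= start <= end")
    return m.group(1), start, end


# ---------------------------------------------------------------------------
# SAM/BAM reading
# ---------------------------------------------------------------------------

_QUERY_OPS = {0, 1, 4, 7, 8}  # consume query (soft clips included)
_CLIP_OPS = {4, 5}


def _segment_from_record(rec: "pysam.AlignedSegment") -> AlignedSegment:
    cig = rec.cigartuples
    if not cig:
        raise ValueError(f"record {rec.query_name} has no CIGAR")
    lead = 0
    for op, ln in cig:
        if op in _CLIP_OPS:
            lead += ln
        else:
            break
    trail = 0
    for op, ln in reversed(cig):
        if op in _CLIP_OPS:
            trail += ln
        else:
            break
    aligned_q = sum(ln for op, ln in cig if op in (0, 1, 7, 8))
    read_len = lead + aligned_q + trail
    if rec.is_reverse:
        read_start = read_len - (lead + aligned_q) + 1
        read_end = read_len - lead
    else:
        read_start = lead + 1
        read_end = lead + aligned_q

    m_ops = sum(ln for op, ln in cig if op in (0, 7, 8))
    n_ins = sum(ln for op, ln in cig if op == 1)
    n_del = sum(ln for op, ln in cig if op == 2)
    n_eq = sum(ln for op, ln in cig if op == 7)
    n_x = sum(ln for op, ln in cig if op == 8)
    if n_eq or n_x:
        n_mismatch = n_x
    elif rec.has_tag("NM"):
        n_mismatch = max(int(rec.get_tag("NM")) - n_ins - n_del, 0)
    else:
        n_mismatch = 0
    n_mismatch = min(n_mismatch, m_ops)

    return AlignedSegment(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        ref_start=rec.reference_start + 1,
        ref_end=rec.reference_end,  # pysam end is 0-based exclusive == 1-based inclusive
        read_start=read_start,
        read_end=read_end,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
        n_match=m_ops - n_mismatch,
        n_mismatch=n_mismatch,
        n_ins=n_ins,
        n_del=n_del,
        is_primary=not rec.is_supplementary,
    )


def read_alignments(path: str, cfg: Config | None = None) -> Iterator[ReadAlignment]:
    """Group primary + SA-linked supplementary records by read name.

    Unmapped and secondary records are excluded; segments are ordered by
    their position on the read in sequencer orientation.  ``cfg`` is accepted
    for interface symmetry; filtering happens downstream so that QC sees all
    mapped reads.
    """
    groups: dict[str, list[AlignedSegment]] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), check_sq=True) as fh:
        if not fh.lengths:
            raise ValueError(f"{path}: header has no reference lengths")
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.reference_name is None:
                raise ValueError(f"record {rec.query_name} references a contig absent from the header")
            seg = _segment_from_record(rec)
            groups.setdefault(rec.query_name, []).append(seg)
            lengths[rec.query_name] = max(lengths.get(rec.query_name, 0), seg.read_end,
                                          rec.infer_read_length() or 0)
    for read_id, segs in groups.items():
        segs.sort(key=lambda s: (s.read_start, s.read_end))
        if not any(s.is_primary for s in segs):
            # orphan supplementary group (primary filtered upstream): promote longest
            max(segs, key=lambda s: s.read_span).is_primary = True
        yield ReadAlignment(read_id=read_id, read_length=lengths[read_id], segments=segs)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def segment_identity(seg: AlignedSegment) -> float:
    """BLAST-style identity: matches over all alignment columns (gaps counted)."""
    denom = seg.n_match + seg.n_mismatch + seg.n_ins + seg.n_del
    if denom == 0:
        raise ValueError(f"segment {seg.read_id} has all-zero tallies; identity undefined")
    return seg.n_match / denom


def read_length_n50(lengths: Sequence[int]) -> int:
    """Smallest L such that reads of length >= L hold at least half the bases."""
    if not lengths:
        raise ValueError("N50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("read lengths must be positive")
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if 2 * acc >= total:
            return l
    return min(lengths)  # unreachable


def qc_summary(alignments: Iterable[ReadAlignment], reference: Reference) -> QCReport:
    """Depth, coverage and identity summary over mapped reads.

    Depth divides total aligned reference bases by the non-N reference
    length; coverage rate is the fraction of non-N bases covered at least
    once (per-base accumulation over all mapped segments).
    """
    cov = {c: np.zeros(reference.lengths[c] + 1, dtype=np.int32) for c in reference.sequences}
    lengths: list[int] = []
    idents: list[float] = []
    n_mapped_bases = 0
    n_reads = 0
    for ra in alignments:
        if not ra.segments:
            continue
        n_reads += 1
        lengths.append(ra.read_length)
        for seg in ra.segments:
            n_mapped_bases += seg.ref_span
            cov[seg.chrom][seg.ref_start - 1] += 1
            cov[seg.chrom][seg.ref_end] -= 1
            if seg.is_primary:
                idents.append(segment_identity(seg))

    non_n = reference.non_n_length()
    if non_n <= 0:
        raise ValueError("reference has no non-N bases")
    if n_reads == 0:
        return QCReport(0, 0, 0.0, 0.0, 0, 0.0, 0.0, 0.0, 0.0, warning="no mapped reads")

    covered_non_n = 0
    for chrom, diffs in cov.items():
        mask = np.cumsum(diffs[:-1]) > 0
        for s, e in reference.n_runs(chrom):
            mask[s:e] = False
        covered_non_n += int(mask.sum())

    return QCReport(
        n_reads=n_reads,
        n_mapped_bases=n_mapped_bases,
        mean_len=float(np.mean(lengths)),
        median_len=float(np.median(lengths)),
        n50=read_length_n50(lengths),
        mean_identity=float(np.mean(idents)) if idents else 0.0,
        median_identity=float(np.median(idents)) if idents else 0.0,
        depth=n_mapped_bases / non_n,
        coverage_rate=covered_non_n / non_n,
    )


def write_qc_tsv(report: QCReport, path_or_handle, sample: str = "sample") -> None:
    """One-line TSV mirroring the per-sample summary table columns."""
    cols = ["sample", "n_reads", "n_mapped_bases", "depth", "coverage_rate_pct",
            "mean_len", "median_len", "n50", "mean_identity", "median_identity", "warning"]
    row = report.to_row()
    row["sample"] = sample
    close = False
    fh = path_or_handle
    if isinstance(path_or_handle, str):
        fh, close = open(path_or_handle, "w"), True
    try:
        w = csv.DictWriter(fh, fieldnames=cols, delimiter="\t", extrasaction="ignore")
        w.writeheader()
        w.writerow({k: (f"{v:.4f}" if isinstance(v, float) else v) for k, v in row.items()})
        fh.write("# coverage_rate denominator: non-N reference length\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# VCF 4.2 breakend output / input
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVCLASS,Number=1,Type=String,Description="translocation|inversion|intra_other">',
    '##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">',
    '##INFO=<ID=SR,Number=1,Type=Integer,Description="Number of distinct supporting split reads">',
    '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise structural variation">',
    '##INFO=<ID=INSLEN,Number=1,Type=Integer,Description="Median inserted bases at the junction">',
    '##INFO=<ID=SOURCE,Number=1,Type=String,Description="Call-set of origin after merging">',
    '##INFO=<ID=RNAMES,Number=.,Type=String,Description="Supporting read names">',
    '##INFO=<ID=REPEAT,Number=.,Type=String,Description="Repeat annotation labels at the breakend">',
]


def _bnd_alt(ref_base: str, own_ori: str, mate: Locus, mate_ori: str) -> str:
    m = f"{mate.chrom}:{mate.pos}"
    if own_ori == "+":
        return f"{ref_base}[{m}[" if mate_ori == "-" else f"{ref_base}]{m}]"
    return f"[{m}[{ref_base}" if mate_ori == "-" else f"]{m}]{ref_base}"


_ALT_RE = re.compile(r"^(?:([ACGTN]+)(\[|\])([^\[\]:]+):(\d+)(\[|\])|(\[|\])([^\[\]:]+):(\d+)(\[|\])([ACGTN]+))$")


def _parse_bnd_alt(alt: str) -> tuple[str, str, int, str]:
    """Return (own_ori, mate_chrom, mate_pos, mate_ori)."""
    m = _ALT_RE.match(alt)
    if not m:
        raise ValueError(f"unparseable breakend ALT {alt!r}")
    if m.group(1) is not None:
        own_ori = "+"
        chrom, pos, bracket = m.group(3), int(m.group(4)), m.group(2)
    else:
        own_ori = "-"
        chrom, pos, bracket = m.group(7), int(m.group(8)), m.group(6)
    mate_ori = "-" if bracket == "[" else "+"
    return own_ori, chrom, pos, mate_ori


def write_breakend_vcf(calls: Sequence, contigs: dict[str, int], path: str,
                       sample: str = "sample") -> None:
    """Write mated BND records (VCF 4.2) for a flat list of breakend calls.

    ``calls`` holds both ends of each junction, cross-linked by ``mate_id``;
    an end whose mate is absent raises.
    """
    by_id = {c.call_id: c for c in calls}
    orphans = [c.call_id for c in calls if c.mate_id not in by_id]
    if orphans:
        raise ValueError(f"orphan breakend(s) without a mate record: {orphans}")
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.locus.chrom, c.locus.pos, c.call_id)):
            rec = out.new_record()
            rec.contig = c.locus.chrom
            rec.start = c.locus.pos - 1
            rec.id = c.call_id
            rec.ref = "N"
            rec.alts = (_bnd_alt("N", c.orientation[0], c.mate, c.orientation[1]),)
            rec.info["SVTYPE"] = "BND"
            rec.info["SVCLASS"] = c.svclass
            rec.info["MATEID"] = (c.mate_id,)
            rec.info["SR"] = c.support
            rec.info["CIPOS"] = (c.locus.ci_lo, c.locus.ci_hi)
            rec.info["INSLEN"] = c.median_insertion
            if c.imprecise:
                rec.info["IMPRECISE"] = True
            if c.source:
                rec.info["SOURCE"] = c.source
            if c.read_ids:
                rec.info["RNAMES"] = tuple(c.read_ids)
            if c.labels:
                rec.info["REPEAT"] = tuple(c.labels)
            out.write(rec)


def read_breakend_vcf(path: str) -> list:
    """Read BND records written by :func:`write_breakend_vcf` back into calls."""
    from .caller import BreakendCall  # deferred: caller imports formats

    calls = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            own_ori, mchrom, mpos, mate_ori = _parse_bnd_alt(rec.alts[0])
            ci = tuple(rec.info.get("CIPOS", (0, 0)))
            calls.append(BreakendCall(
                call_id=rec.id,
                locus=Locus(rec.contig, rec.pos, int(ci[0]), int(ci[1])),
                mate=Locus(mchrom, mpos),
                orientation=own_ori + mate_ori,
                svclass=rec.info.get("SVCLASS", "translocation"),
                support=int(rec.info.get("SR", 1)),
                read_ids=tuple(rec.info.get("RNAMES", ())),
                median_insertion=int(rec.info.get("INSLEN", 0)),
                imprecise=bool(rec.info.get("IMPRECISE", False)),
                mate_id=rec.info["MATEID"][0],
                source=rec.info.get("SOURCE", "") or "",
                labels=tuple(rec.info.get("REPEAT", ())),
            ))
    # restore mate CI from the mate record
    by_id = {c.call_id: c for c in calls}
    for c in calls:
        mate = by_id.get(c.mate_id)
        if mate is not None:
            c.mate = mate.locus
    return calls


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------


def _locus_to_bed_interval(locus: Locus) -> tuple[int, int]:
    """1-based locus with CI -> 0-based half-open interval."""
    return locus.pos - 1 + locus.ci_lo, locus.pos + locus.ci_hi


def write_bedpe(calls: Sequence, path: str) -> None:
    """One BEDPE line per junction (each mated pair written once)."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for c in calls:
            if c.call_id in seen or c.mate_id in seen:
                continue
            seen.add(c.call_id)
            s1, e1 = _locus_to_bed_interval(c.locus)
            s2, e2 = _locus_to_bed_interval(c.mate)
            w.writerow([c.locus.chrom, s1, e1, c.mate.chrom, s2, e2,
                        c.call_id, c.support, c.orientation[0], c.orientation[1],
                        c.svclass, c.median_insertion])


def read_bedpe(path: str) -> list:
    from .caller import BreakendCall

    calls = []
    with open(path) as fh:
        for i, line in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not line or line[0].startswith("#"):
                continue
            if len(line) < 10:
                raise ValueError(f"{path}:{i}: expected >= 10 BEDPE columns")
            c1, s1, e1, c2, s2, e2, name, score, o1, o2 = line[:10]
            svclass = line[10] if len(line) > 10 else "translocation"
            inslen = int(line[11]) if len(line) > 11 else 0
            l1 = Locus(c1, int(s1) + 1, 0, int(e1) - int(s1) - 1)
            l2 = Locus(c2, int(s2) + 1, 0, int(e2) - int(s2) - 1)
            calls.append(BreakendCall(
                call_id=name, locus=l1, mate=l2, orientation=o1 + o2,
                svclass=svclass, support=int(score), read_ids=(),
                median_insertion=inslen,
                imprecise=not (l1.precise and l2.precise), mate_id=name + "_m"))
    return calls
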