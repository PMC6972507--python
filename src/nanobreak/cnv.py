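"""Window read-count copy-number estimation in no-control mode.

Reads are counted once each, in the consecutive non-overlapping window
containing the primary alignment's start position, so window counts
partition the counted reads exactly.  With no matched control, the
per-window ratio is taken against the sample's own median window count
(a 0.5 pseudo-count keeps sparse windows finite):

    log2((count + 0.5) / (median + 0.5))

Windows that are mostly reference N (non-N fraction < 0.5) are masked and
carry no ratio; they are transparent to segmentation, which merges
consecutive same-state runs and folds runs shorter than ``cnv_min_windows``
into the neutral background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats import Config, ReadAlignment, Reference

__all__ = ["WindowCount", "CnvSegment", "CnvCall", "window_counts",
           "normalize_log2", "segment_ratios", "call_cnvs", "write_windows_tsv",
           "write_calls_bed"]


@dataclass
class WindowCount:
    chrom: str
    window_index: int
    start: int  # 1-based inclusive
    end: int
    n_reads: int
    n_frac: float  # fraction of the window that is non-N

    @property
    def masked(self) -> bool:
        return self.n_frac < 0.5


@dataclass
class CnvSegment:
    chrom: str
    first_window: int
    last_window: int
    start: int
    end: int
    mean_log2: float
    n_windows: int
    state: str  # gain | loss | neutral


@dataclass
class CnvCall:
    chrom: str
    start: int
    end: int
    direction: str  # gain | loss
    mean_log2: float
    size: int


def window_counts(alignments: Iterable[ReadAlignment], reference: Reference,
                  cfg: Config) -> list[WindowCount]:
    """Per-window read-start counts over consecutive non-overlapping windows."""
    w = cfg.cnv_window
    counts = {c: np.zeros(-(-length // w), dtype=np.int64)
              for c, length in reference.lengths.items()}
    for ra in alignments:
        seg = ra.primary()
        if seg is None or seg.chrom not in counts:
            continue
        counts[seg.chrom][(seg.ref_start - 1) // w] += 1

    out: list[WindowCount] = []
    for chrom, arr in counts.items():
        length = reference.lengths[chrom]
        n_bases = np.zeros(len(arr), dtype=np.int64)
        for s, e in reference.n_runs(chrom):
            first, last = s // w, (e - 1) // w
            for wi in range(first, last + 1):
                lo, hi = max(s, wi * w), min(e, (wi + 1) * w)
                n_bases[wi] += hi - lo
        for wi in range(len(arr)):
            start0, end0 = wi * w, min((wi + 1) * w, length)
            span = end0 - start0
            out.append(WindowCount(chrom=chrom, window_index=wi,
                                   start=start0 + 1, end=end0,
                                   n_reads=int(arr[wi]),
                                   n_frac=(span - int(n_bases[wi])) / span))
    return out


def normalize_log2(windows: Sequence[WindowCount]) -> np.ndarray:
    """Per-window log2 ratio against the sample median; NaN for masked windows."""
    counts = np.array([w.n_reads for w in windows], dtype=float)
    mask = np.array([w.masked for w in windows])
    if mask.all() or len(windows) == 0:
        raise ValueError("all windows are masked; cannot normalize")
    median = float(np.median(counts[~mask]))
    ratios = np.log2((counts + 0.5) / (median + 0.5))
    ratios[mask] = np.nan
    return ratios


def segment_ratios(windows: Sequence[WindowCount], ratios: np.ndarray,
                   cfg: Config) -> list[CnvSegment]:
    """Greedy run-merging of same-state windows.

    State per unmasked window is gain (ratio > +threshold), loss
    (< -threshold) or neutral; consecutive same-state windows on a
    chromosome merge (masked windows are transparent).  Neutral gaps
    shorter than ``cnv_min_windows`` flanked by the same non-neutral state
    are absorbed into it (Poisson count noise inside a real event would
    otherwise fragment it), then non-neutral runs shorter than
    ``cnv_min_windows`` fold into the neutral background.
    """
    thresh = cfg.cnv_log2_thresh
    by_chrom: dict[str, list[tuple[WindowCount, float]]] = {}
    for w_, r in zip(windows, ratios):
        if not w_.masked and not math.isnan(r):
            by_chrom.setdefault(w_.chrom, []).append((w_, float(r)))

    segments: list[CnvSegment] = []
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: t[0].window_index)
        states = ["gain" if r > thresh else "loss" if r < -thresh else "neutral"
                  for _, r in items]
        # bridge sub-minimum neutral gaps flanked by the same non-neutral state,
        # so count noise inside a genuine event does not fragment it
        i = 0
        while i < len(states):
            j = i
            while j < len(states) and states[j] == states[i]:
                j += 1
            if (states[i] == "neutral" and j - i < cfg.cnv_min_windows
                    and 0 < i and j < len(states) and states[i - 1] == states[j]
                    and states[j] != "neutral"):
                for k in range(i, j):
                    states[k] = states[j]
            i = j
        # fold short non-neutral runs into neutral
        i = 0
        while i < len(states):
            j = i
            while j < len(states) and states[j] == states[i]:
                j += 1
            if states[i] != "neutral" and j - i < cfg.cnv_min_windows:
                for k in range(i, j):
                    states[k] = "neutral"
            i = j
        # emit merged runs
        i = 0
        while i < len(states):
            j = i
            while j < len(states) and states[j] == states[i]:
                j += 1
            ws = [w_ for w_, _ in items[i:j]]
            rs = [r for _, r in items[i:j]]
            segments.append(CnvSegment(
                chrom=chrom, first_window=ws[0].window_index,
                last_window=ws[-1].window_index, start=ws[0].start, end=ws[-1].end,
                mean_log2=float(np.mean(rs)), n_windows=len(ws), state=states[i]))
            i = j
    return segments


def call_cnvs(segments: Sequence[CnvSegment], cfg: Config) -> list[CnvCall]:
    """Non-neutral segments meeting the minimum size become CNV calls."""
    min_size = cfg.cnv_min_windows * cfg.cnv_window
    calls = []
    for seg in segments:
        size = seg.end - seg.start + 1
        if seg.state != "neutral" and size >= min_size:
            calls.append(CnvCall(chrom=seg.chrom, start=seg.start, end=seg.end,
                                 direction=seg.state, mean_log2=seg.mean_log2,
                                 size=size))
    return calls


def write_windows_tsv(windows: Sequence[WindowCount], ratios: np.ndarray,
                      path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcount\tlog2\tmasked\n")
        for w_, r in zip(windows, ratios):
            log2 = "NA" if math.isnan(r) else f"{r:.4f}"
            fh.write(f"{w_.chrom}\t{w_.start}\t{w_.end}\t{w_.n_reads}\t{log2}\t"
                     f"{int(w_.masked)}\n")


def write_calls_bed(calls: Sequence[CnvCall], path: str) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.direction}\t"
                     f"{c.mean_log2:.4f}\n")
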