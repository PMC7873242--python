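"""CLIP/MeRIP read-coverage computations on the L1 consensus.

Three defined operations: a per-base coverage track optionally normalized
to the total mapped read count; regional mean coverage by the
begin-and-end-within rule (a read counts for a region only when it lies
entirely inside it, so boundary-straddling reads count for no region); and
DRACH-containment filtering of peak intervals, the sequence-level stand-in
for model-based m6A-site prediction when narrowing peaks to motif-bearing
candidates.

Reads are strandless fragments already mapped to the consensus; no mapping,
trimming or peak calling happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif import scan_drach


@dataclass
class ReadAln:
    """One read aligned to the consensus, 0-based half-open."""

    read_id: str
    start: int
    end: int
    replicate: str = "rep1"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid read interval [{self.start}, {self.end})")


@dataclass
class RegionTable:
    """Ordered, non-overlapping named regions (5'UTR, ORF1, ORF2, 3'UTR)."""

    regions: list[tuple[str, int, int]]   # (name, start, end) half-open

    def __post_init__(self):
        prev_end = 0
        for name, s, e in self.regions:
            if s < prev_end or s >= e:
                raise ValueError("regions must be ordered and non-overlapping")
            prev_end = e

    def __iter__(self):
        return iter(self.regions)


@dataclass
class Peak:
    start: int
    end: int
    replicate_support: int = 1
    has_motif: bool = False


def coverage_track(reads: list[ReadAln], consensus_len: int,
                   normalize: bool = False) -> np.ndarray:
    """Per-base read depth; if ``normalize``, divided by the total number
    of mapped reads (the track then sums to mean read length)."""
    depth = np.zeros(consensus_len + 1)
    for r in reads:
        if r.end > consensus_len:
            raise ValueError(f"read {r.read_id} extends past the consensus")
        depth[r.start] += 1
        depth[r.end] -= 1
    depth = np.cumsum(depth[:-1])
    if normalize and reads:
        depth /= len(reads)
    return depth


def regional_mean_coverage(reads: list[ReadAln], regions: RegionTable) -> dict[str, float]:
    """reads fully inside each region / region length (reads per bp)."""
    out: dict[str, float] = {}
    for name, s, e in regions:
        n = sum(1 for r in reads if r.start >= s and r.end <= e)
        out[name] = n / (e - s)
    return out


def peak_motif_filter(peaks: list[Peak], consensus_seq: str,
                      margin: int = 0) -> list[Peak]:
    """Annotate ``has_motif``: at least one DRACH hit within the peak span
    widened by ``margin`` bp on both sides (motif window fully inside)."""
    for p in peaks:
        lo = max(0, p.start - margin)
        hi = min(len(consensus_seq), p.end + margin)
        p.has_motif = bool(scan_drach(consensus_seq[lo:hi]))
    return peaks


def intersect_replicate_peaks(a: list[Peak], b: list[Peak],
                              min_overlap: int = 1) -> list[Peak]:
    """Peaks from replicate a that overlap some replicate-b peak by at
    least ``min_overlap`` bp, with replicate_support=2."""
    out = []
    for p in a:
        if any(min(p.end, q.end) - max(p.start, q.start) >= min_overlap for q in b):
            out.append(Peak(p.start, p.end, replicate_support=2))
    return out


def reads_from_sam(path, reference: str | None = None) -> list[ReadAln]:
    """Read a plain-text SAM subset into consensus-mapped fragments."""
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            if reference is not None and aln.reference_name != reference:
                continue
            reads.append(ReadAln(aln.query_name, aln.reference_start,
                                 aln.reference_end))
    return reads


def reads_from_bed(intervals) -> list[ReadAln]:
    return [ReadAln(iv.name, iv.start, iv.end) for iv in intervals]
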