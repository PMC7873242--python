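"""Seed-and-extend local search of a query against a genome.

Stands in for a BLAT-style search: exact k-mer seeds from a sorted-array
index, chained by diagonal and proximity, then verified/refined with a
banded edit-distance alignment (edlib).  Good for the regimes this package
works in — planted or orthologous sequences within ~25% divergence — not a
general-purpose aligner.

Identity of a hit is approximated as ``1 - editDistance / max(query_len,
span_len)``; exact column-wise identity for near-identical hits, slightly
conservative when indels are present.  N never seeds and never matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np

from .seq import encode, revcomp

logger = logging.getLogger(__name__)


@dataclass
class SearchHit:
    """One local hit of a query on a target contig (0-based half-open)."""

    target_contig: str
    start: int
    end: int
    strand: str
    identity: float
    query_start: int
    query_end: int

    @property
    def span(self) -> int:
        return self.end - self.start


class KmerIndex:
    """Sorted-array index of all N-free k-mers of one contig."""

    def __init__(self, seq: str, k: int = 16, contig: str = "contig"):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.seq = seq
        self.k = k
        self.contig = contig
        codes, valid = _kmer_codes(seq, k)
        pos = np.nonzero(valid)[0]
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order].astype(np.int64)

    def lookup(self, qcodes: np.ndarray, qvalid: np.ndarray):
        """Return (tpos, qpos) arrays of all exact seed matches."""
        qpos_all = np.nonzero(qvalid)[0]
        qc = qcodes[qpos_all]
        lo = np.searchsorted(self._codes, qc, side="left")
        hi = np.searchsorted(self._codes, qc, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        qpos = np.repeat(qpos_all, counts)
        # concatenated ranges lo[i]..hi[i] without a python loop
        starts = np.repeat(lo, counts)
        cum = np.concatenate(([0], np.cumsum(counts)))[:-1]
        offs = np.arange(total) - np.repeat(cum, counts)
        tpos = self._pos[starts + offs]
        return tpos, qpos


def _kmer_codes(seq: str, k: int):
    """uint64 codes of all k-mers plus a validity mask (no N in window)."""
    b = encode(seq)
    n = b.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | b[j:j + n].astype(np.uint64)
    is_n = (b == 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(is_n)))
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def _mask_n(s: str, lower: bool) -> str:
    # edlib treats equal characters as matches; force N to mismatch
    # everything (including N) by casing the two sides differently.
    return s.replace("N", "n") if lower else s


def seed_extend_search(query: str, target, k: int = 16,
                       min_identity: float = 0.8, min_span: int = 100,
                       band_frac: float = 0.15, chain_gap: int = 500,
                       pad: int = 50, max_edit_frac: float = 0.35) -> list[SearchHit]:
    """Find local hits of ``query`` on ``target`` on both strands.

    ``target`` is a sequence string or a prebuilt :class:`KmerIndex`
    (prebuild it when searching many queries against one genome).  Hits
    below ``min_identity`` or shorter than ``min_span`` are discarded;
    the result is sorted by descending identity × span.
    """
    index = target if isinstance(target, KmerIndex) else KmerIndex(target, k=k)
    k = index.k
    if len(query) < k:
        logger.warning("query shorter than seed length %d; no search performed", k)
        return []

    hits: list[SearchHit] = []
    tlen = len(index.seq)
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        qcodes, qvalid = _kmer_codes(q, k)
        tpos, qpos = index.lookup(qcodes, qvalid)
        if tpos.size == 0:
            continue
        band = max(k, int(band_frac * len(q)))
        for ct, cq in _chain(tpos, qpos, band, chain_gap + k):
            q0 = max(0, int(cq.min()) - pad)
            q1 = min(len(q), int(cq.max()) + k + pad)
            t0 = max(0, int(ct.min()) - pad)
            t1 = min(tlen, int(ct.max()) + k + pad)
            if q1 - q0 < k or t1 - t0 < k:
                continue
            sub = q[q0:q1]
            res = edlib.align(_mask_n(sub, False), _mask_n(index.seq[t0:t1], True),
                              mode="HW", task="locations",
                              k=max(1, int(max_edit_frac * len(sub))))
            if res["editDistance"] < 0 or not res["locations"]:
                continue
            loc0, loc1 = res["locations"][0]
            start, end = t0 + loc0, t0 + loc1 + 1
            ident = 1.0 - res["editDistance"] / max(len(sub), end - start)
            if ident < min_identity or end - start < min_span:
                continue
            if strand == "+":
                qs, qe = q0, q1
            else:
                qs, qe = len(q) - q1, len(q) - q0
            hits.append(SearchHit(index.contig, start, end, strand, ident, qs, qe))

    hits = _dedupe(hits)
    hits.sort(key=lambda h: (-h.identity * h.span, h.start, h.strand))
    return hits


def _chain(tpos: np.ndarray, qpos: np.ndarray, band: int, max_gap: int):
    """Group seed matches into clusters by diagonal band, then target gap."""
    diag = tpos - qpos
    order = np.argsort(diag, kind="stable")
    diag_s, t_s, q_s = diag[order], tpos[order], qpos[order]
    breaks = np.nonzero(np.diff(diag_s) > band)[0] + 1
    for dgrp in np.split(np.arange(diag_s.size), breaks):
        t_g, q_g = t_s[dgrp], q_s[dgrp]
        o2 = np.argsort(t_g, kind="stable")
        t_g, q_g = t_g[o2], q_g[o2]
        b2 = np.nonzero(np.diff(t_g) > max_gap)[0] + 1
        for grp in np.split(np.arange(t_g.size), b2):
            if grp.size:
                yield t_g[grp], q_g[grp]


def _dedupe(hits: list[SearchHit]) -> list[SearchHit]:
    """Drop hits mostly contained in a better hit on the same strand."""
    kept: list[SearchHit] = []
    for h in sorted(hits, key=lambda h: (-h.identity * h.span, h.start)):
        redundant = False
        for g in kept:
            if g.strand != h.strand:
                continue
            ov = min(g.end, h.end) - max(g.start, h.start)
            if ov > 0.5 * h.span:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept
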