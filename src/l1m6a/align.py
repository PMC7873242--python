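"""Affine-gap global alignment and consensus-coordinate projection.

These primitives replace the external aligners a genome-scale study would
use (MUSCLE-style pairwise alignment, liftOver-style coordinate transfer)
with small, fully specified in-package equivalents:

* :func:`global_align` — Needleman–Wunsch/Gotoh alignment with affine gaps.
  Convention: a gap run of length L costs ``gap_open + L * gap_extend``
  (the first gap base pays open + extend).  Conventions differ between
  tools, so this is stated here once and used everywhere, including the
  brute-force oracle in the test suite.
* :func:`map_consensus_coords` — projects a pairwise alignment whose target
  is a subfamily consensus into a 1-based consensus-position → query-position
  map, the shared coordinate frame in which sites such as A332 are quoted.

Tie-breaking in the traceback prefers diagonal over vertical (target-
consuming) over horizontal moves, making alignments deterministic.
Complexity is O(n·m) time and memory; intended for sequences up to a few kb
(consensus 5' UTRs, flanks), not whole genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a consensus position absent from the query (deletion).
DELETED = -1

NEG = -np.inf
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters. N never matches anything (scores as mismatch)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0


@dataclass
class Alignment:
    """A pairwise global alignment.

    ``aligned_pairs`` is an ordered list of ``(target_pos, query_pos)``
    tuples, 0-based, with ``None`` on the gapped side of a column.
    ``identity`` counts matches over all aligned columns including gap
    columns (the conservative definition; see :func:`alignment_identity`).
    """

    target_id: str
    query_id: str
    score: float
    aligned_pairs: list[tuple[int | None, int | None]]
    identity: float
    n_matches: int = 0
    n_mismatches: int = 0
    n_gap_columns: int = 0


def alignment_identity(n_matches: int, n_mismatches: int, n_gap_columns: int,
                       include_gaps: bool = True) -> float:
    """matches / aligned columns; optionally excluding gap columns."""
    denom = n_matches + n_mismatches + (n_gap_columns if include_gaps else 0)
    return n_matches / denom if denom else 0.0


def global_align(a: str, b: str, params: AlignParams = AlignParams(),
                 target_id: str = "target", query_id: str = "query",
                 include_gaps_in_identity: bool = True) -> Alignment:
    """Optimal global alignment of target ``a`` vs query ``b`` (Gotoh).

    Returns the optimal-score alignment under the affine convention of this
    module (gap run of length L costs ``open + L*extend``).  Empty vs empty
    aligns to an empty alignment with score 0.
    """
    from .seq import encode

    n, m = len(a), len(b)
    if (n + 1) * (m + 1) > 40_000_000:
        raise ValueError("global_align is O(n*m) in memory; inputs too large")
    o, e = params.gap_open, params.gap_extend

    if n == 0 and m == 0:
        return Alignment(target_id, query_id, 0.0, [], 0.0)

    ea = encode(a).astype(np.int16)
    eb = encode(b).astype(np.int16)

    # state matrices: M diag, F vertical (target consumed), E horizontal
    M = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    j_arange = np.arange(1, m + 1)
    if m:
        E[0, 1:] = o + e * j_arange
    if n:
        F[1:, 0] = o + e * np.arange(1, n + 1)

    for i in range(1, n + 1):
        # substitution scores of target base i-1 vs all query bases
        sub = np.where((eb == ea[i - 1]) & (eb < 4), params.match, params.mismatch)
        prev_best = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
        M[i, 1:] = sub + prev_best[:-1]
        F[i, 1:] = np.maximum(F[i - 1, 1:] + e,
                              np.maximum(M[i - 1, 1:], E[i - 1, 1:]) + o + e)
        # E via running max over G[k] - e*k, G = max(M, F) in this row
        G = np.maximum(M[i], F[i])
        x = G - e * np.arange(m + 1)
        run = np.maximum.accumulate(x)
        E[i, 1:] = o + e * j_arange + run[:-1]

    # traceback; states 0=M, 1=F, 2=E; ties prefer M > F > E
    def _pick(vm: float, vf: float, ve: float) -> int:
        best = max(vm, vf, ve)
        if vm >= best - _TIE_EPS:
            return 0
        if vf >= best - _TIE_EPS:
            return 1
        return 2

    score = max(M[n, m], F[n, m], E[n, m])
    state = _pick(M[n, m], F[n, m], E[n, m])
    i, j = n, m
    pairs: list[tuple[int | None, int | None]] = []
    nmatch = nmis = ngap = 0
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            if ea[i - 1] == eb[j - 1] and ea[i - 1] < 4:
                nmatch += 1
            else:
                nmis += 1
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = _pick(M[i, j], F[i, j], E[i, j])
        elif state == 1:
            pairs.append((i - 1, None))
            ngap += 1
            cur = F[i, j]
            i -= 1
            if abs(M[i, j] + o + e - cur) <= _TIE_EPS:
                state = 0
            elif abs(F[i, j] + e - cur) <= _TIE_EPS:
                state = 1
            else:
                state = 2
        else:
            pairs.append((None, j - 1))
            ngap += 1
            cur = E[i, j]
            j -= 1
            if abs(M[i, j] + o + e - cur) <= _TIE_EPS:
                state = 0
            elif abs(F[i, j] + o + e - cur) <= _TIE_EPS:
                state = 1
            else:
                state = 2
    pairs.reverse()
    ident = alignment_identity(nmatch, nmis, ngap, include_gaps_in_identity)
    return Alignment(target_id, query_id, float(score), pairs, ident,
                     nmatch, nmis, ngap)


@dataclass
class CoordinateMap:
    """1-based consensus position → 1-based query position (or DELETED).

    Built from one pairwise alignment whose *target* is the consensus.
    Query insertions never create consensus positions; monotone over
    positions that map to bases.
    """

    consensus_id: str
    query_id: str
    mapping: dict[int, int] = field(default_factory=dict)

    def __getitem__(self, consensus_pos: int) -> int:
        return self.mapping[consensus_pos]

    def __contains__(self, consensus_pos: int) -> bool:
        return consensus_pos in self.mapping

    def covers(self, positions) -> bool:
        return all(p in self.mapping for p in positions)


def map_consensus_coords(aln: Alignment) -> CoordinateMap:
    """Project an alignment (target = consensus) into a CoordinateMap.

    Every consensus position covered by the alignment appears exactly once,
    mapped to a 1-based query position or to :data:`DELETED`.
    """
    mapping: dict[int, int] = {}
    for tpos, qpos in aln.aligned_pairs:
        if tpos is None:
            continue
        mapping[tpos + 1] = DELETED if qpos is None else qpos + 1
    return CoordinateMap(aln.target_id, aln.query_id, mapping)
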