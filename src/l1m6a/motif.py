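"""Subfamily classification, consensus-coordinate m6A-site calling, and
prevalence/logo aggregation.

The m6A writer complex methylates adenosines in the DRACH context
(D = G/A/U, R = G/A, H = U/C/A; U maps to T on DNA).  Site status at a
consensus position (A332, A495, A600 by default, in the coordinate-reference
consensus numbering) is called from the query bases mapped to positions
site-2..site+2:

* ``full_drach`` — the mapped 5-mer must satisfy D-R-A-C-H;
* ``followed_by_C`` — A at the site and C at site+1 (the operational
  definition used for lineage prevalence counts: a T→C substitution at
  site+1, e.g. T333C, is exactly the motif-gain event).

Elements whose site maps to a deletion are ``deleted``; windows containing
N are ``ambiguous``.  Both count in prevalence denominators by default
(conservative), switchable to callable-only denominators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .align import DELETED, AlignParams, CoordinateMap, global_align
from .io_formats import ConsensusLibrary

D_BASES = "GAT"
R_BASES = "GA"
H_BASES = "TCA"

#: All 5-mers accepted by the DRACH rule (3 x 2 x 1 x 1 x 3 = 18).
DRACH_KMERS = frozenset(
    d + r + "AC" + h
    for d, r, h in itertools.product(D_BASES, R_BASES, H_BASES)
)


@dataclass
class SiteMotifCall:
    locus_id: str
    site: int                 # 1-based consensus position of the adenosine
    status: str               # positive | negative | deleted | ambiguous
    window: str               # query bases at site-2..site+2, '-' for deletions


def scan_drach(seq: str) -> list[int]:
    """1-based positions of every A whose 5-mer context (A centered, i.e.
    window [pos-2, pos+2]) matches D-R-A-C-H.  Windows truncated by the
    sequence ends are not callable and are skipped."""
    seq = seq.upper()
    return [i + 3 for i in range(len(seq) - 4) if seq[i:i + 5] in DRACH_KMERS]


def call_site_motif(query_utr: str, cmap: CoordinateMap, site: int,
                    mode: str = "followed_by_C",
                    locus_id: str = "") -> SiteMotifCall:
    """Call one consensus site in one element from its coordinate map."""
    window_pos = range(site - 2, site + 3)
    if not cmap.covers(window_pos):
        raise ValueError(f"coordinate map does not cover site {site} +/- 2")
    chars = []
    for p in window_pos:
        q = cmap[p]
        chars.append("-" if q == DELETED else query_utr[q - 1])
    window = "".join(chars)

    if window[2] == "-":
        status = "deleted"
    elif "N" in window:
        status = "ambiguous"
    elif mode == "followed_by_C":
        status = "positive" if window[2] == "A" and window[3] == "C" else "negative"
    elif mode == "full_drach":
        status = "positive" if ("-" not in window and window in DRACH_KMERS) else "negative"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SiteMotifCall(locus_id, site, status, window)


def classify_subfamily(locus_seq: str, library: ConsensusLibrary,
                       region: str = "utr",
                       params: AlignParams = AlignParams()):
    """Nearest-consensus subfamily assignment.

    Aligns the locus against every library consensus (5' UTR region by
    default — the lineage-diagnostic sequence turnover of L1 lives there —
    or the full consensus with ``region="full"``) and assigns the argmax
    identity.  Exact ties return ``None`` (ambiguous, excluded downstream).
    Returns ``(name_or_None, {subfamily: identity})``.
    """
    if len(library) < 2:
        raise ValueError("need at least 2 consensuses to classify")
    idents: dict[str, float] = {}
    for cons in library:
        ref = cons.utr if region == "utr" else cons.sequence
        query = locus_seq[:len(ref)] if region == "utr" else locus_seq
        aln = global_align(ref, query, params=params)
        idents[cons.name] = aln.identity
    best = max(idents.values())
    winners = [n for n, v in idents.items() if v == best]
    return (winners[0] if len(winners) == 1 else None), idents


def map_onto_reference(locus_seq: str, library: ConsensusLibrary,
                       params: AlignParams = AlignParams()) -> tuple[str, CoordinateMap]:
    """Align the element's 5' UTR onto the coordinate-reference consensus
    UTR and return ``(query_utr_slice, CoordinateMap)``.

    Pairwise star mapping onto the reference replaces a multiple alignment:
    every element is projected into the same consensus numbering, which is
    all the site caller needs.
    """
    ref = library.reference
    lo, hi = ref.utr_span
    query_utr = locus_seq[:(hi - lo + 1) + 120]   # slack for small indels
    aln = global_align(ref.utr, query_utr, params=params,
                       target_id=ref.name, query_id="query_utr")
    from .align import map_consensus_coords
    return query_utr, map_consensus_coords(aln)


def round_pct(x: float) -> float:
    """Percentage display: one decimal, round-half-up."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def prevalence_table(calls: list[SiteMotifCall],
                     loci_meta: dict[str, tuple[str, str]],
                     denominator: str = "all",
                     groups: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-(species, subfamily) motif prevalence.

    ``loci_meta`` maps locus_id -> (species, subfamily).  ``denominator``
    is ``all`` (deleted/ambiguous count in n_total but never in n_positive)
    or ``callable`` (positive+negative only).  ``groups`` adds pooled rows
    over named subfamily groups (e.g. {"L1PA2_and_younger": [...]}), keyed
    species x group.  Percentages are also returned as raw ratios; cells
    with n_total == 0 are NA, never 0%.
    """
    rows: dict[tuple[str, str], dict] = {}
    sites = sorted({c.site for c in calls})

    def _bucket(key):
        if key not in rows:
            rows[key] = {"species": key[0], "subfamily": key[1],
                         **{f"n_total_{s}": 0 for s in sites},
                         **{f"n_positive_{s}": 0 for s in sites}}
        return rows[key]

    for c in calls:
        sp, fam = loci_meta[c.locus_id]
        keys = [(sp, fam)]
        for gname, members in (groups or {}).items():
            if fam in members:
                keys.append((sp, gname))
        for key in keys:
            b = _bucket(key)
            countable = (c.status in ("positive", "negative")
                         if denominator == "callable" else True)
            if countable:
                b[f"n_total_{c.site}"] += 1
            if c.status == "positive":
                b[f"n_positive_{c.site}"] += 1

    out = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["species"], r["subfamily"])))
    for s in sites:
        ratio = out[f"n_positive_{s}"] / out[f"n_total_{s}"].replace(0, np.nan)
        out[f"ratio_{s}"] = ratio
        out[f"pct_{s}"] = ratio.map(lambda v: np.nan if pd.isna(v) else round_pct(100 * v))
    return out


def position_frequency_matrix(windows: list[str], window_span: tuple[int, int]) -> pd.DataFrame:
    """Per-column base counts/frequencies over aligned windows (logo input).

    ``windows`` are equal-length strings drawn from the same consensus span
    (1-based inclusive); gap characters '-' are tallied as their own symbol.
    Returns a tidy frame: one row per consensus position, count and
    frequency columns per symbol; frequencies sum to 1 per row.
    """
    lo, hi = window_span
    width = hi - lo + 1
    if any(len(w) != width for w in windows):
        raise ValueError("all windows must match the span width")
    symbols = "ACGT-"
    counts = np.zeros((width, len(symbols)), dtype=int)
    lut = {ch: i for i, ch in enumerate(symbols)}
    for w in windows:
        for j, ch in enumerate(w.upper()):
            counts[j, lut.get(ch, lut["-"])] += 1
    df = pd.DataFrame({"consensus_pos": np.arange(lo, hi + 1)})
    total = counts.sum(axis=1)
    for i, ch in enumerate(symbols):
        label = "gap" if ch == "-" else ch
        df[f"count_{label}"] = counts[:, i]
        with np.errstate(invalid="ignore"):
            df[f"freq_{label}"] = np.where(total > 0, counts[:, i] / np.maximum(total, 1), np.nan)
    return df


def extract_window(query_utr: str, cmap: CoordinateMap,
                   window_span: tuple[int, int]) -> str | None:
    """Query bases over a consensus span via the coordinate map, '-' for
    deletions; None when the map does not cover the span."""
    lo, hi = window_span
    if not cmap.covers(range(lo, hi + 1)):
        return None
    out = []
    for p in range(lo, hi + 1):
        q = cmap[p]
        out.append("-" if q == DELETED else query_utr[q - 1])
    return "".join(out)
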