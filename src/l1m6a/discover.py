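"""Find candidate L1 loci, apply full-length/gap filters, and call
species-specificity by flank orthology.

The specificity caller operationalizes the empty-site/filled-site test used
for presence-absence dating of retrotransposon insertions: the 2 kb flanks
of a candidate locus are located in each other genome; if the flank hits
are adjacent (up to TSD-sized jitter) the orthologous site is *empty* and
the insertion postdates the species split; if they are separated by roughly
the locus length and the intervening sequence looks like an L1, the site is
*filled* (shared insertion).  Anything else — multiple flank hits, missing
flank hits, inverted or incoherent geometry — is ambiguous and the locus is
excluded rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .io_formats import ConsensusLibrary
from .search import KmerIndex, SearchHit, seed_extend_search, _mask_n
from .seq import revcomp


@dataclass
class DiscoveryParams:
    """Tunable knobs of locus discovery and specificity calling."""

    k: int = 16
    min_identity: float = 0.7        # locus discovery hits
    min_span: int = 300
    merge_gap: int = 200
    min_full_len: int = 5500         # "less than 5.5 kb" removed, inclusive keep
    flank_len: int = 2000
    ortho_min_identity: float = 0.9  # flank hits in other genomes
    ortho_min_span_frac: float = 0.9
    empty_site_max_gap: int = 50     # absorbs TSD + alignment jitter
    filled_site_tol_frac: float = 0.15
    fill_min_identity: float = 0.7
    allow_unmapped: bool = False


@dataclass
class L1Locus:
    locus_id: str
    species: str
    contig: str
    start: int
    end: int
    strand: str
    sequence: str
    identity: float = 0.0
    full_length: bool = False
    gap_overlap: bool = False
    subfamily: str = "UNASSIGNED"
    specificity: str = "UNCALLED"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FlankPair:
    upstream: str
    downstream: str
    complete: bool


@dataclass
class OrthologyCall:
    locus_id: str
    per_species_evidence: dict[str, str] = field(default_factory=dict)
    final: str = "excluded"


def build_genome_index(genome: dict[str, str], k: int = 16) -> dict[str, KmerIndex]:
    return {contig: KmerIndex(seq, k=k, contig=contig) for contig, seq in genome.items()}


def find_l1_loci(genome: dict[str, str], library: ConsensusLibrary,
                 params: DiscoveryParams = DiscoveryParams(),
                 species: str = "", indexes: dict[str, KmerIndex] | None = None) -> list[L1Locus]:
    """Search every consensus against the genome; merge overlapping hits
    per strand into loci (merge gap ``params.merge_gap``), de-duplicating
    overlaps by keeping the longer locus.  Locus sequences are extracted in
    element orientation (reverse-complemented on '-')."""
    if len(library) == 0:
        raise ValueError("consensus library is empty")
    indexes = indexes or build_genome_index(genome, k=params.k)
    loci: list[L1Locus] = []
    counter = 0
    for contig in sorted(genome):
        idx = indexes[contig]
        hits: list[SearchHit] = []
        for cons in library:
            hits.extend(seed_extend_search(
                cons.sequence, idx, min_identity=params.min_identity,
                min_span=params.min_span))
        merged = _merge_hits(hits, params.merge_gap)
        for start, end, strand, ident in merged:
            seq = genome[contig][start:end]
            if strand == "-":
                seq = revcomp(seq)
            counter += 1
            loci.append(L1Locus(
                locus_id=f"{species or 'genome'}_L{counter:04d}", species=species,
                contig=contig, start=start, end=end, strand=strand,
                sequence=seq, identity=ident))
    return loci


def _merge_hits(hits: list[SearchHit], merge_gap: int):
    """Merge per strand, then drop spans overlapped by a longer span."""
    merged: list[list] = []
    for strand in "+-":
        sh = sorted((h for h in hits if h.strand == strand), key=lambda h: h.start)
        for h in sh:
            if merged and merged[-1][2] == strand and h.start - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], h.end)
                merged[-1][3] = max(merged[-1][3], h.identity)
            else:
                merged.append([h.start, h.end, strand, h.identity])
    merged.sort(key=lambda m: (m[1] - m[0]), reverse=True)
    kept: list[list] = []
    for m in merged:
        if all(min(m[1], g[1]) - max(m[0], g[0]) <= 0 for g in kept):
            kept.append(m)
    kept.sort(key=lambda m: m[0])
    return [(int(s), int(e), st, float(i)) for s, e, st, i in kept]


def apply_full_length_filter(loci: list[L1Locus], min_full_len: int = 5500,
                             gap_mask: dict[str, list[tuple[int, int]]] | None = None):
    """Keep loci >= ``min_full_len`` bp with zero assembly-gap overlap.

    Returns ``(kept, rejects)`` where rejects is a list of ``(locus,
    reason)`` with reason codes ``short`` and/or ``gap_overlap``.
    Idempotent: re-filtering the kept list changes nothing.
    """
    gap_mask = gap_mask or {}
    kept, rejects = [], []
    for loc in loci:
        reasons = []
        if loc.length < min_full_len:
            reasons.append("short")
        for (g0, g1) in gap_mask.get(loc.contig, []):
            if min(loc.end, g1) - max(loc.start, g0) > 0:
                loc.gap_overlap = True
                reasons.append("gap_overlap")
                break
        if reasons:
            rejects.append((loc, ";".join(reasons)))
        else:
            loc.full_length = True
            kept.append(loc)
    return kept, rejects


def extract_flanks(locus: L1Locus, genome: dict[str, str],
                   flank_len: int = 2000) -> FlankPair:
    """Genomic flanks [start-flank_len, start) and [end, end+flank_len);
    ``complete`` is False when a contig edge truncates either flank."""
    seq = genome[locus.contig]
    up0 = max(0, locus.start - flank_len)
    up = seq[up0:locus.start]
    down = seq[locus.end:locus.end + flank_len]
    return FlankPair(up, down, len(up) == flank_len and len(down) == flank_len)


def call_specificity(locus: L1Locus, flanks: FlankPair,
                     other_indexes: dict[str, dict[str, KmerIndex]],
                     library: ConsensusLibrary,
                     params: DiscoveryParams = DiscoveryParams()) -> OrthologyCall:
    """Empty-site/filled-site orthology call for one locus.

    ``other_indexes`` maps other-species name -> {contig: KmerIndex}.
    Incomplete flanks exclude the locus outright.
    """
    if not other_indexes:
        raise ValueError("specificity is undefined without other genomes")
    call = OrthologyCall(locus.locus_id)
    if not flanks.complete:
        call.final = "excluded"
        call.per_species_evidence = {sp: "ambiguous" for sp in other_indexes}
        return call

    min_span = int(params.ortho_min_span_frac * params.flank_len)
    for sp in sorted(other_indexes):
        call.per_species_evidence[sp] = _site_evidence(
            locus, flanks, other_indexes[sp], library, params, min_span)

    ev = set(call.per_species_evidence.values())
    if "ambiguous" in ev or ("unmapped" in ev and not params.allow_unmapped):
        call.final = "excluded"
    elif ev <= {"empty_site", "unmapped"}:
        call.final = "species_specific"
    else:
        call.final = "shared"
    return call


def _site_evidence(locus, flanks, indexes, library, params, min_span) -> str:
    up_hits, down_hits = [], []
    for idx in indexes.values():
        up_hits.extend(seed_extend_search(
            flanks.upstream, idx, min_identity=params.ortho_min_identity,
            min_span=min_span))
        down_hits.extend(seed_extend_search(
            flanks.downstream, idx, min_identity=params.ortho_min_identity,
            min_span=min_span))
    if len(up_hits) > 1 or len(down_hits) > 1:
        return "ambiguous"
    if not up_hits or not down_hits:
        return "unmapped"
    up, down = up_hits[0], down_hits[0]
    if up.target_contig != down.target_contig or up.strand != down.strand:
        return "ambiguous"
    if up.strand == "+":
        d = down.start - up.end
        inner = (up.end, down.start)
    else:
        d = up.start - down.end
        inner = (down.end, up.start)
    if abs(d) <= params.empty_site_max_gap:
        return "empty_site"
    tol = params.filled_site_tol_frac * locus.length
    if abs(d - locus.length) <= tol:
        contig = up.target_contig
        filler = indexes[contig].seq[inner[0]:inner[1]]
        if _looks_like_l1(filler, library, params.fill_min_identity):
            return "filled_site"
    return "ambiguous"


def _looks_like_l1(seq: str, library: ConsensusLibrary, min_identity: float) -> bool:
    if not seq:
        return False
    for cons in library:
        for s in (seq, revcomp(seq)):
            res = edlib.align(_mask_n(s, False), _mask_n(cons.sequence, True),
                              mode="NW", task="distance",
                              k=int((1 - min_identity) * max(len(s), len(cons.sequence))) + 1)
            if res["editDistance"] >= 0:
                ident = 1 - res["editDistance"] / max(len(s), len(cons.sequence))
                if ident >= min_identity:
                    return True
    return False
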