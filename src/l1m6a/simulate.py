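"""Multi-species genome simulator with planted L1 insertions and ground truth.

Emulates the evolutionary scenario behind the lineage analysis: a common
ancestral genome carries *shared* (orthologous) full-length-or-truncated L1
insertions; the ancestor then diverges into N species by substitutions, and
each species additionally acquires *species-specific* insertions.  Each
planted copy gets a target-site duplication (TSD), a random strand, optional
5' truncation, and a per-copy substitution load scaled by the age rank of
its subfamily.  The three 5' UTR m6A sites (defaults A332/A495/A600 in the
youngest-consensus numbering) are planted with controlled DRACH context:
A495/A600 keep a valid motif in every subfamily, while the base after A332
(position 333) is T or C per subfamily, modelling the T333C motif-gain
substitution that separates old (motif-negative) from young (motif-positive)
lineages.

Every planted copy is recorded in a :class:`TruthManifest` with its realized
coordinates, subfamily, specificity, truncation and per-site base states, so
downstream discovery/classification/motif calling can be scored exactly.

All randomness flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` sub-streams (one per species), so identical
configs give byte-identical genomes and manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import seq as sq
from .io_formats import BedInterval, ConsensusLibrary, SubfamilyConsensus, write_bed

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


class CapacityError(ValueError):
    """Genome too small to host the requested insertions."""


@dataclass
class SimConfig:
    """Parameters of one simulation scenario.

    Defaults describe the study scenario the pipeline is validated on:
    4 species diverged by 0.5% substitutions/site from a 1 Mb ancestor,
    5 subfamilies (L1PA5 oldest ... L1Hs youngest) whose consensuses differ
    by 5% per lineage step in serial derivation (L1 5' UTRs turn over fast
    between subfamilies), per-copy substitution load 0.2% x age rank
    (0.2%..1%), 20% 5'-truncation probability and 7-20 bp TSDs.
    Site-333 state is T for L1PA3 and older, C for L1PA2/L1Hs.
    """

    seed: int = 1
    n_species: int = 4
    species_names: tuple[str, ...] | None = None
    ancestral_genome_len: int = 1_000_000
    interspecies_divergence: float = 0.005
    subfamily_names: tuple[str, ...] = ("L1PA5", "L1PA4", "L1PA3", "L1PA2", "L1Hs")
    per_step_consensus_divergence: float = 0.05
    consensus_len: int = 6019
    utr_span: tuple[int, int] = (1, 909)
    sites: tuple[int, ...] = (332, 495, 600)
    site333_state_per_subfamily: dict[str, str] | None = None
    n_shared_insertions: int = 10
    n_specific_insertions_per_species: int = 35
    per_copy_substitution_rate: float = 0.002
    truncation_prob: float = 0.2
    truncation_min_cut: int = 600
    tsd_len_range: tuple[int, int] = (7, 20)
    gap_run_prob: float = 0.02
    gap_run_len: int = 50
    anchor_min_separation: int = 4500
    edge_margin: int = 3000
    contig_name: str = "chr1"

    def __post_init__(self):
        if self.species_names is None:
            self.species_names = tuple(f"sp{i + 1}" for i in range(self.n_species))
        if self.site333_state_per_subfamily is None:
            # motif gain in the two youngest lineages
            k = len(self.subfamily_names)
            self.site333_state_per_subfamily = {
                name: ("C" if i >= k - 2 else "T")
                for i, name in enumerate(self.subfamily_names)
            }
        self.validate()

    def validate(self) -> None:
        probs = (self.interspecies_divergence, self.per_step_consensus_divergence,
                 self.per_copy_substitution_rate, self.truncation_prob,
                 self.gap_run_prob)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities/rates must lie in [0, 1]")
        if min(self.ancestral_genome_len, self.consensus_len) <= 0:
            raise ValueError("lengths must be positive")
        if len(self.subfamily_names) < 2:
            raise ValueError("need at least 2 subfamilies")
        lo, hi = self.utr_span
        if not (1 <= lo <= hi <= self.consensus_len):
            raise ValueError("utr_span must lie within [1, consensus_len]")
        for s in self.sites:
            if not (lo + 2 <= s and s + 2 <= hi):
                raise ValueError(
                    f"utr_span {self.utr_span} too short to contain the motif "
                    f"window of site {s}")
        if set(self.site333_state_per_subfamily) != set(self.subfamily_names):
            raise ValueError("site333_state_per_subfamily must cover every subfamily")
        if any(b not in "ACGT" for b in self.site333_state_per_subfamily.values()):
            raise ValueError("site-333 states must be single bases in ACGT")
        if len(self.species_names) != self.n_species:
            raise ValueError("species_names length must equal n_species")
        t0, t1 = self.tsd_len_range
        if not (0 <= t0 <= t1):
            raise ValueError("invalid tsd_len_range")
        if self.truncation_min_cut >= self.consensus_len - 400:
            raise ValueError("truncation_min_cut leaves no element behind")

    def age_rank(self, subfamily: str) -> int:
        """1 for the youngest subfamily, increasing with age."""
        k = len(self.subfamily_names)
        return k - self.subfamily_names.index(subfamily)


@dataclass
class TruthRecord:
    """Ground truth for one planted insertion copy in one species genome."""

    record_id: str
    species: str
    contig: str
    start: int          # 0-based
    end: int            # half-open
    strand: str
    subfamily: str
    specificity: str    # shared | species_specific
    truncated: bool
    full_length: bool   # 5'-intact
    gap_overlap: bool
    site_states: dict[int, str]   # consensus site -> base, 'N', or '-' (deleted)
    tsd: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthManifest:
    records: list[TruthRecord] = field(default_factory=list)

    def for_species(self, species: str) -> list[TruthRecord]:
        return [r for r in self.records if r.species == species]

    def __len__(self):
        return len(self.records)


def _forced_windows(config: SimConfig) -> list[tuple[int, str | None]]:
    """(window_start_1based, fixed_bases or None-for-variable-333) per site.

    Windows are D R A C/H H = positions site-2 .. site+2; the base at
    site+1 is C for constitutive sites and per-subfamily for the first site.
    """
    out = []
    for i, s in enumerate(config.sites):
        if i == 0:
            out.append((s - 2, None))      # GGA?T with ? per subfamily
        else:
            out.append((s - 2, "GGACT"))
    return out


def _window_mask(config: SimConfig) -> np.ndarray:
    mask = np.zeros(config.consensus_len, dtype=bool)
    for s in config.sites:
        mask[s - 3:s + 2] = True   # 1-based site-2..site+2 -> 0-based slice
    return mask


def build_consensus_lineage(config: SimConfig) -> ConsensusLibrary:
    """Serially derive one consensus per subfamily, oldest to youngest.

    The root is uniform random DNA forced to carry the three motif windows;
    each younger consensus applies exactly ``round(rate * n_eligible)``
    substitutions outside the forced windows, then re-imposes the windows
    (constitutive DRACH at the conserved sites; per-subfamily base at
    position 333).  The youngest consensus is the coordinate reference.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    mask = _window_mask(config)
    windows = _forced_windows(config)

    def impose(arr: np.ndarray, subfamily: str) -> None:
        for (w0, fixed) in windows:
            bases = fixed if fixed is not None else (
                "GGA" + config.site333_state_per_subfamily[subfamily] + "T")
            arr[w0 - 1:w0 - 1 + 5] = sq.encode(bases)

    n_eligible = int((~mask).sum())
    k_subs = int(round(config.per_step_consensus_divergence * n_eligible))

    seqs: list[np.ndarray] = []
    cur = sq.random_dna(rng, config.consensus_len)
    impose(cur, config.subfamily_names[0])
    seqs.append(cur)
    for name in config.subfamily_names[1:]:
        cur = sq.mutate_exact(cur, k_subs, rng, protect=mask)
        impose(cur, name)
        seqs.append(cur)

    records = []
    k = len(config.subfamily_names)
    for i, (name, arr) in enumerate(zip(config.subfamily_names, seqs)):
        records.append(SubfamilyConsensus(
            name=name, age_rank=k - i, sequence=sq.decode(arr),
            utr_span=config.utr_span,
            is_coordinate_reference=(i == k - 1)))
    return ConsensusLibrary(records)


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class _PlannedCopy:
    record_id: str
    anchor: int            # insertion point (coords of the host sequence)
    subfamily: str
    strand: str
    cut: int               # 5' bases removed from the consensus (0 = intact)
    tsd_len: int
    gap: bool
    element: np.ndarray    # consensus-strand element sequence (after subs)
    specificity: str


def _plan_copy(rid: str, anchor: int, subfamily: str, spec: str,
               config: SimConfig, library: ConsensusLibrary,
               rng: np.random.Generator) -> _PlannedCopy:
    cons = sq.encode(library.get(subfamily).sequence)
    strand = "+" if rng.random() < 0.5 else "-"
    truncated = rng.random() < config.truncation_prob
    cut = 0
    if truncated:
        cut = int(rng.integers(config.truncation_min_cut, config.consensus_len - 400))
    tsd_len = int(rng.integers(config.tsd_len_range[0], config.tsd_len_range[1] + 1))
    gap = rng.random() < config.gap_run_prob
    rate = config.per_copy_substitution_rate * config.age_rank(subfamily)
    element = sq.mutate_bernoulli(cons[cut:], rate, rng)
    return _PlannedCopy(rid, anchor, subfamily, strand, cut, tsd_len, gap,
                        element, spec)


def _assemble(host: np.ndarray, copies: list[_PlannedCopy]):
    """Insert copies (with TSD duplication) into host; return new array plus
    {record_id: (elem_start, elem_end, tsd_seq)} in the new coordinates."""
    copies = sorted(copies, key=lambda c: c.anchor)
    pieces: list[np.ndarray] = []
    spans: dict[str, tuple[int, int, str]] = {}
    cur = 0
    offset = 0
    for c in copies:
        p = c.anchor
        tsd = host[p:p + c.tsd_len]
        oriented = c.element if c.strand == "+" else _rc_arr(c.element)
        pieces.append(host[cur:p + c.tsd_len])
        pieces.append(oriented)
        start = p + c.tsd_len + offset
        spans[c.record_id] = (start, start + oriented.size, sq.decode(tsd))
        offset += oriented.size + c.tsd_len
        cur = p   # re-emit host[p:p+tsd_len] downstream: the second TSD copy
    pieces.append(host[cur:])
    return np.concatenate(pieces), spans


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def _shift(pos: int, insert_points: list[tuple[int, int]]) -> int:
    """Shift a coordinate by the total length inserted at or before it.

    ``insert_points`` are (anchor, added_len) pairs in pre-insertion coords.
    """
    return pos + sum(add for a, add in insert_points if a <= pos)


def _recorded_sites(config: SimConfig) -> list[int]:
    # the base after each site (position 333 for A332 etc.) decides
    # followed-by-C motif status, so the truth records it as well
    return sorted(set(config.sites) | {s + 1 for s in config.sites})


def _site_positions(copy: _PlannedCopy, start: int, end: int,
                    config: SimConfig) -> dict[int, int | None]:
    """Genome position of each recorded consensus site for a planted copy
    (or None when the site was removed by 5' truncation)."""
    out: dict[int, int | None] = {}
    for s in _recorded_sites(config):
        idx = s - 1 - copy.cut
        if idx < 0:
            out[s] = None
        elif copy.strand == "+":
            out[s] = start + idx
        else:
            out[s] = end - 1 - idx
    return out


def simulate_genomes(config: SimConfig, library: ConsensusLibrary):
    """Simulate the species genomes; returns ({species: {contig: seq}}, TruthManifest).

    Shared insertions are planted once in the ancestor and inherited (then
    diverged) by every species at the orthologous coordinate; specific
    insertions are planted in exactly one species.  Raises
    :class:`CapacityError` when the ancestral genome cannot host all
    requested insertion anchors at the configured separation.
    """
    rng_bg = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    rng_anchor = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    rng_anc = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(3,)))

    background = sq.random_dna(rng_bg, config.ancestral_genome_len)

    n_total = config.n_shared_insertions + config.n_species * config.n_specific_insertions_per_species
    anchors = _sample_anchors(config, rng_anchor, n_total)
    shared_anchors = anchors[:config.n_shared_insertions]
    specific_anchors = {
        sp: anchors[config.n_shared_insertions + i * config.n_specific_insertions_per_species:
                    config.n_shared_insertions + (i + 1) * config.n_specific_insertions_per_species]
        for i, sp in enumerate(config.species_names)
    }

    k = len(config.subfamily_names)
    shared_copies = [
        _plan_copy(f"shared{i:03d}", int(a), config.subfamily_names[i % k],
                   "shared", config, library, rng_anc)
        for i, a in enumerate(shared_anchors)
    ]
    aws, shared_spans = _assemble(background, shared_copies)
    shared_added = sorted(
        (c.anchor, c.element.size + c.tsd_len) for c in shared_copies)

    genomes: dict[str, dict[str, str]] = {}
    manifest = TruthManifest()
    for si, sp in enumerate(config.species_names):
        rng_sp = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10, si)))
        arr = sq.mutate_bernoulli(aws, config.interspecies_divergence, rng_sp)

        spec_copies = [
            _plan_copy(f"{sp}_specific{i:03d}",
                       _shift(int(a), shared_added),
                       config.subfamily_names[i % k],
                       "species_specific", config, library, rng_sp)
            for i, a in enumerate(specific_anchors[sp])
        ]
        arr, spec_spans = _assemble(arr, spec_copies)
        spec_added = sorted((c.anchor, c.element.size + c.tsd_len) for c in spec_copies)

        all_copies: list[tuple[_PlannedCopy, tuple[int, int, str]]] = []
        for c in shared_copies:
            s0, s1, tsd = shared_spans[c.record_id]
            all_copies.append((c, (_shift(s0, spec_added), _shift(s1 - 1, spec_added) + 1, tsd)))
        for c in spec_copies:
            all_copies.append((c, spec_spans[c.record_id]))

        # assembly gaps: N runs planted mid-element for gap-flagged copies
        for c, (s0, s1, _) in all_copies:
            if c.gap:
                mid = s0 + (s1 - s0) // 2 - config.gap_run_len // 2
                arr[mid:mid + config.gap_run_len] = 4

        for c, (s0, s1, tsd) in sorted(all_copies, key=lambda x: x[1][0]):
            sites = _site_positions(c, s0, s1, config)
            states: dict[int, str] = {}
            for site, pos in sites.items():
                if pos is None:
                    states[site] = "-"
                else:
                    base = sq.decode(arr[pos:pos + 1])
                    states[site] = base if c.strand == "+" else COMPLEMENT[base]
            manifest.records.append(TruthRecord(
                record_id=c.record_id, species=sp, contig=config.contig_name,
                start=s0, end=s1, strand=c.strand, subfamily=c.subfamily,
                specificity=c.specificity, truncated=c.cut > 0,
                full_length=c.cut == 0, gap_overlap=c.gap,
                site_states=states, tsd=tsd))

        genomes[sp] = {config.contig_name: sq.decode(arr)}

    return genomes, manifest


def _sample_anchors(config: SimConfig, rng: np.random.Generator, n_total: int) -> np.ndarray:
    lo = config.edge_margin
    hi = config.ancestral_genome_len - config.edge_margin
    if hi <= lo:
        raise CapacityError("genome shorter than twice the edge margin")
    cand = np.sort(rng.integers(lo, hi, size=max(20 * n_total, 1000)))
    kept: list[int] = []
    last = -10**12
    for p in cand:
        if p - last >= config.anchor_min_separation:
            kept.append(int(p))
            last = int(p)
    if len(kept) < n_total:
        raise CapacityError(
            f"genome of {config.ancestral_genome_len} bp cannot host {n_total} "
            f"insertions at >= {config.anchor_min_separation} bp separation")
    chosen = rng.choice(len(kept), size=n_total, replace=False)
    return np.array(kept, dtype=np.int64)[np.sort(chosen)]


# ---------------------------------------------------------------------------
# truth manifest I/O


def write_truth(manifest: TruthManifest, out_prefix) -> list[Path]:
    """Write one BED per species plus a JSON manifest; returns paths."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    species = sorted({r.species for r in manifest.records})
    for sp in species:
        path = out_prefix.with_name(out_prefix.name + f".{sp}.bed")
        ivs = [BedInterval(r.contig, r.start, r.end, r.subfamily, "0", r.strand)
               for r in manifest.for_species(sp)]
        write_bed(path, ivs, comment="0-based half-open; name=subfamily")
        paths.append(path)
    jpath = out_prefix.with_name(out_prefix.name + ".manifest.json")
    payload = []
    for r in manifest.records:
        d = asdict(r)
        d["site_states"] = {str(k): v for k, v in r.site_states.items()}
        payload.append(d)
    with open(jpath, "w", newline="\n") as fh:
        json.dump({"records": payload}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths.append(jpath)
    return paths


def read_truth(manifest_json_path) -> TruthManifest:
    with open(manifest_json_path) as fh:
        data = json.load(fh)
    records = []
    for d in data["records"]:
        d = dict(d)
        d["site_states"] = {int(k): v for k, v in d["site_states"].items()}
        records.append(TruthRecord(**d))
    return TruthManifest(records)
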