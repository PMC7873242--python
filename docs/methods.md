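# Methods

## The biological model

LINE-1 (L1) is an autonomous retrotransposon whose full-length copies span
about 6 kb: a ~900 bp 5′ UTR, two open reading frames (ORF1, ORF2) and a
short 3′ UTR. In primates the active L1 population has evolved as a single
lineage series — L1PA5 → L1PA4 → L1PA3 → L1PA2 → L1Hs (≈ L1PA1), younger
numbers younger — with repeated turnover of the 5′ UTR. m6A
methyltransferases act on adenosines in the DRACH context; three 5′ UTR
adenosines (A332, A495, A600 in the reference-consensus numbering, 1-based)
form a functional m6A cluster. A332 sits in a context whose following base
is T in old lineages and C in young ones, so a single T→C substitution at
position 333 (T333C) creates the motif; A495 and A600 carry an intact
context in all lineages. The pipeline's central statistic is motif
prevalence per lineage: the fraction of species-specific full-length
elements of each subfamily whose A332 (resp. A495, A600) is
motif-positive.

Species-specificity is decided by insertion presence–absence: an L1 copy
present in one genome whose orthologous locus is *empty* in related
genomes inserted after the species split. This is read out from the 2 kb
flanks of the insertion, located in each other genome by local alignment.

## Motif calling

Two site-status modes are provided:

* `followed_by_C` (default for prevalence): positive iff the element has A
  at the site and C at site+1. This is the operational definition for
  lineage counts — the gain event is precisely the appearance of C after
  the adenosine.
* `full_drach`: positive iff the mapped 5-mer at site−2 … site+2 matches
  D-R-A-C-H (18 accepted 5-mers; DNA alphabet, U ≡ T). Used for peak
  filtering in the coverage module.

A site whose center maps to an alignment deletion is `deleted`; a window
containing N is `ambiguous`. Both remain in prevalence denominators by
default (conservative: an uncallable element is counted as not-positive);
`denominator="callable"` switches to positive+negative only. Percentages
print with one decimal, round-half-up; raw counts and ratios are always
emitted alongside.

Elements are projected onto the reference consensus by *pairwise* global
alignment of their 5′ UTR against the reference 5′ UTR (star mapping); no
multiple alignment is performed, because the site caller only needs each
element's coordinates in the common frame.

## Alignment primitives

`global_align` is a Needleman–Wunsch/Gotoh affine-gap aligner. Convention:
a gap run of length L costs `gap_open + L·gap_extend` (the first gap base
pays open+extend); defaults match +1, mismatch −1, open −3, extend −1.
N never matches anything, including N. Traceback ties prefer diagonal over
vertical (target-consuming) over horizontal moves, so alignments are
deterministic. The implementation is O(n·m) time and memory and intended
for sequences up to a few kb; the test suite checks its scores against an
exhaustive path-enumeration oracle on short pairs.

Alignment identity is matches / aligned columns *including* gap columns
(conservative), switchable to exclude gaps.

`seed_extend_search` finds local hits of a query in a genome: exact k-mer
seeds (default k = 16, N-containing seeds skipped) from a sorted-array
index, grouped by diagonal band (0.15 × query length) and target proximity
(≤ 500 bp gaps), then verified and refined with a banded edit-distance
alignment (edlib, edit limit 35% of the query). Hit identity is
approximated as 1 − editDistance / max(query_len, span_len) — exact for
substitution-only divergence, slightly conservative with indels. Both
strands are searched via the reverse complement. The regime is planted or
orthologous sequence within ~25% divergence, not remote homology.

## Locus discovery and specificity

Hits of all subfamily consensuses are merged per strand (gap ≤ 200 bp) into
loci; overlapping loci keep the longer. The full-length filter keeps loci
≥ 5500 bp — "shorter than 5.5 kb removed" read as an inclusive keep at
exactly 5500 — with zero overlap of assembly-gap (N-run) intervals; rejects
are reported with reason codes, and the filter is idempotent.

For each full-length locus the 2 kb flanks are searched in every other
genome at identity ≥ 0.9 over ≥ 90% of the flank. "Unique" is
operationalized as exactly one passing hit per flank per genome. With one
hit each, on the same contig and strand and collinear, the inner distance d
between flank hits classifies the site:

* |d| ≤ 50 bp → `empty_site` (the slack absorbs the 7–20 bp target-site
  duplication and alignment jitter; d is negative by about the TSD length
  at a clean empty site);
* |d − locus_length| ≤ 15% of locus length, with the intervening sequence
  matching some library consensus at identity ≥ 0.7 → `filled_site`;
* anything else (multiple hits, missing hits, inversions, incoherent
  spacing) → `ambiguous`.

Aggregation: any ambiguous evidence → `excluded`; empty in *every* other
genome → `species_specific`; otherwise (≥ 1 filled site) → `shared`.
Unmapped flanks exclude the locus by default (`allow_unmapped` relaxes
this). All thresholds are `DiscoveryParams` fields: a real comparison used
manual curation at this step, so no fixed tolerance can claim equivalence;
the defaults are chosen to be conservative and are validated by perfect
recovery on simulations.

Subfamily assignment is nearest-consensus by 5′ UTR identity (the
lineage-diagnostic region; full-length mode available). Exact ties are
ambiguous and excluded.

## The simulator

`SimConfig` defaults define the validation scenario: 4 species from a 1 Mb
random ancestor; interspecies divergence 0.005 substitutions/site (each
species independently from the ancestor, so pairwise ≈ 1%); 5 subfamilies
whose consensuses are derived serially with exactly
`round(0.05 × eligible_sites)` substitutions per step — L1 5′ UTRs turn
over fast between subfamilies, and this separation makes nearest-consensus
assignment essentially error-free at ≤ 1% per-copy noise — except the
three 5-bp motif windows, which are set deterministically (GGACT at
A495/A600; GGA·T with the per-subfamily base at 333 for A332, T for L1PA3
and older, C for L1PA2/L1Hs). 10 shared insertions are planted in the
ancestor and inherited by all species at orthologous coordinates; 35
species-specific insertions per species are planted after divergence
(subfamilies assigned round-robin). Each copy gets: a TSD of 7–20 bp
duplicated from the insertion site, a random strand, 5′ truncation with
probability 0.2 removing ≥ 600 bp (so truncated copies always fail the
5500 bp filter), per-site substitutions at 0.002 × age-rank (rank 1 =
L1Hs … 5 = L1PA5, i.e. 0.2–1%), and with probability 0.02 a 50 bp N run
planted mid-element as an assembly gap. Insertion anchors are sampled
jointly across species with ≥ 4.5 kb separation and ≥ 3 kb edge margin so
that every 2 kb flank is element-free background — 1 Mb then hosts ~150
anchors comfortably, giving ≈ 30 full-length elements per subfamily pooled
over the four species. All randomness flows from one seed through named
`SeedSequence` sub-streams (one per species), making genomes and manifests
byte-reproducible.

The truth manifest records every copy's realized coordinates, strand,
subfamily, specificity, truncation, gap flag, TSD, and the realized base at
each motif site *and* the following position, read back from the final
genome — so called prevalence can be compared against planted truth
exactly.

What the simulator does **not** emulate: insertions/deletions other than 5′
truncation (substitution-only divergence), nested or clustered insertions
(anchors are well separated), segmental duplications or repeat-rich
background (flanks are unique by construction), polymorphic insertions, CpG
hypermutation, or lineage-specific rate variation. Perfect recovery on
simulations therefore validates the *logic* of the callers, not their
performance on real genomes, where ambiguity-driven exclusion would be
substantial (a real analysis additionally relied on manual curation, which
is out of scope here).

## Coverage and colocalization

Coverage: depth[i] = number of reads overlapping base i; normalization
divides by total mapped reads. Regional mean coverage counts only reads
that begin *and* end within a region, divided by region length —
boundary-straddling reads count for no region, so the region-weighted sum
is ≤ total reads with equality only when regions tile the consensus and no
read straddles. Default region spans (5′ UTR 0–909, ORF1 909–1926, ORF2
1990–5813, 3′ UTR 5813–end, 0-based half-open) follow standard full-length
L1 annotation and are configuration-supplied, since region coordinates are
assembly-specific. Peak filtering annotates each peak with whether
`scan_drach` finds ≥ 1 motif within the (optionally margin-widened) span;
this sequence-rule filter stands in for trained m6A-site predictors when
narrowing peaks to motif-bearing candidates.

Colocalization: candidate cross-pairs within 330 nm are taken greedily by
ascending Euclidean distance, each punctum used at most once
(`one_to_one`). Greedy maximal matching is not guaranteed optimal — it
recovers at least half the maximum-cardinality matching on any instance and
matches it to within one pair at realistic puncta densities (tested against
a maximum-matching oracle); it is used because nearest-first exclusive
pairing mirrors how puncta are counted. `any_within` reports all pairs for
sensitivity analysis. z enters the distance when present (planar mode
available, since the 330 nm threshold is quoted in lateral pixels); pixel
inputs require an explicit pixel size (110 nm/px makes 3 px = 330 nm).

## Numerical and formatting choices

* Coordinates are 0-based half-open internally and on disk (BED); 1-based
  only when quoting consensus positions (A332 …).
* Writers are deterministic: stable ordering, `%.6g` floats, LF endings;
  the run manifest records config, seed, version and SHA-256 digests of all
  outputs but no wall-clock timestamps, so identical config+seed reruns
  produce byte-identical run directories.
* FASTA input is uppercased; IUPAC ambiguity codes are converted to N with
  a logged count. Duplicate ids and empty files are hard errors; malformed
  BED lines report their line number.
* Statistical validation of prevalence uses exact binomial central
  intervals at the two-sided 3σ level (α = 0.0027): at the per-lineage
  sample sizes involved, expected motif-loss counts are far below 5 and
  the normal approximation is invalid.

## Problem sizes

The shipped validation scenario (4 × ~1.2 Mb genomes, ~180 planted copies,
~150 full-length) runs the full pipeline in well under a minute on one CPU;
unit tests use a reduced geometry (700 bp consensus, 80 kb genomes) chosen
so that every code path — truncation, TSDs, gaps, strand, orthology —
still exercises at full fidelity.

## Known limitations

* Published genome-scale counts (hundreds of human-specific elements,
  lineage percentages from real primate assemblies) require reference
  genomes and curated locus lists; the package reproduces the analysis
  logic and its desk-scale validation, not those exact numbers.
* Hit identity from edit distance is an approximation under indels.
* The aligner's O(n·m) memory restricts `global_align` to few-kb inputs;
  genome-scale search always goes through `seed_extend_search`.
* No indel model between subfamily consensuses: consensus coordinates are
  colinear across lineages in simulation, which real L1 5′ UTR turnover
  violates; the coordinate-map machinery handles indels, but simulated
  tests do not stress large structural divergence.
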