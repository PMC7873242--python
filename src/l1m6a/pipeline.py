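"""End-to-end drivers tying the stages together, plus truth-vs-called
evaluation on simulated genomes.

``run_all`` performs: simulate -> discover loci -> full-length/gap filter
-> flank-orthology specificity -> subfamily classification -> consensus
coordinate mapping -> m6A-site calls -> prevalence table and logo matrix ->
evaluation against the truth manifest.  Every stage writes its artifacts
into the run directory; a deterministic run manifest records the config,
seed, package version and SHA-256 digests of every output, so identical
config+seed reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .discover import (DiscoveryParams, L1Locus, apply_full_length_filter,
                       build_genome_index, call_specificity, extract_flanks,
                       find_l1_loci)
from .io_formats import (BedInterval, ConsensusLibrary, dump_json, write_bed,
                         write_fasta, write_tsv)
from .motif import (call_site_motif, classify_subfamily, extract_window,
                    map_onto_reference, position_frequency_matrix,
                    prevalence_table, round_pct)
from .seq import find_n_runs
from .simulate import (SimConfig, TruthManifest, build_consensus_lineage,
                       simulate_genomes, write_truth)


def discover_and_call(genomes: dict[str, dict[str, str]],
                      library: ConsensusLibrary,
                      params: DiscoveryParams = DiscoveryParams()):
    """Discovery + filters + specificity for every species genome.

    Returns ``(loci_by_species, rejects_by_species)`` where loci carry
    final specificity calls ('excluded' loci are retained, flagged).
    """
    indexes = {sp: build_genome_index(g, k=params.k) for sp, g in genomes.items()}
    loci_by_sp: dict[str, list[L1Locus]] = {}
    rejects_by_sp: dict[str, list] = {}
    calls = {}
    for sp in sorted(genomes):
        loci = find_l1_loci(genomes[sp], library, params, species=sp,
                            indexes=indexes[sp])
        gap_mask = {contig: find_n_runs(seq)
                    for contig, seq in genomes[sp].items()}
        kept, rejects = apply_full_length_filter(loci, params.min_full_len, gap_mask)
        others = {osp: indexes[osp] for osp in genomes if osp != sp}
        for loc in kept:
            flanks = extract_flanks(loc, genomes[sp], params.flank_len)
            call = call_specificity(loc, flanks, others, library, params)
            loc.specificity = call.final
            calls[loc.locus_id] = call
        loci_by_sp[sp] = kept
        rejects_by_sp[sp] = rejects
    return loci_by_sp, rejects_by_sp, calls


def classify_and_call_sites(loci_by_sp: dict[str, list[L1Locus]],
                            library: ConsensusLibrary,
                            sites: tuple[int, ...] = (332, 495, 600),
                            mode: str = "followed_by_C",
                            pfm_span: tuple[int, int] | None = None):
    """Subfamily assignment + site calls for every full-length locus.

    Returns ``(site_calls, loci_meta, windows)``: the flat list of
    SiteMotifCalls, locus metadata for prevalence aggregation, and the
    logo windows around the first site.
    """
    if pfm_span is None:
        pfm_span = (sites[0] - 4, sites[0] + 4)
    site_calls = []
    loci_meta: dict[str, tuple[str, str]] = {}
    windows: list[str] = []
    for sp in sorted(loci_by_sp):
        for loc in loci_by_sp[sp]:
            name, _ = classify_subfamily(loc.sequence, library)
            loc.subfamily = name or "UNASSIGNED"
            if name is None:
                continue
            query_utr, cmap = map_onto_reference(loc.sequence, library)
            loci_meta[loc.locus_id] = (sp, name)
            for s in sites:
                site_calls.append(call_site_motif(query_utr, cmap, s, mode=mode,
                                                  locus_id=loc.locus_id))
            w = extract_window(query_utr, cmap, pfm_span)
            if w is not None:
                windows.append(w)
    return site_calls, loci_meta, windows, pfm_span


# ---------------------------------------------------------------------------
# evaluation against the truth manifest


def _match_truth(loc: L1Locus, truth_by_sp: dict[str, list]):
    best, best_ov = None, 0
    for rec in truth_by_sp.get(loc.species, []):
        if rec.contig != loc.contig:
            continue
        ov = min(loc.end, rec.end) - max(loc.start, rec.start)
        if ov > best_ov:
            best, best_ov = rec, ov
    if best is not None and best_ov >= 0.5 * (best.end - best.start):
        return best
    return None


def evaluate_run(loci_by_sp: dict[str, list[L1Locus]], truth: TruthManifest,
                 config: SimConfig, min_full_len: int,
                 site_calls, loci_meta) -> dict:
    """Score called loci against planted truth.

    Recall/precision are computed over *eligible* truth records: 5'-intact,
    >= min_full_len, not overlapping a planted assembly gap.  Subfamily and
    motif accuracy are computed over called loci matched to truth.
    """
    truth_by_sp: dict[str, list] = {}
    for r in truth.records:
        truth_by_sp.setdefault(r.species, []).append(r)

    eligible = [r for r in truth.records
                if r.full_length and not r.gap_overlap
                and (r.end - r.start) >= min_full_len]
    eligible_specific = {(r.species, r.record_id) for r in eligible
                         if r.specificity == "species_specific"}
    eligible_shared = {(r.species, r.record_id) for r in eligible
                       if r.specificity == "shared"}

    called_specific = set()
    called_shared = set()
    n_subfam_match = n_subfam_total = 0
    n_motif_match = n_motif_total = 0
    matched_ids = set()
    calls_by_locus: dict[str, dict[int, str]] = {}
    for c in site_calls:
        calls_by_locus.setdefault(c.locus_id, {})[c.site] = c.status

    for sp, loci in loci_by_sp.items():
        for loc in loci:
            rec = _match_truth(loc, truth_by_sp)
            if rec is None:
                continue
            matched_ids.add((sp, rec.record_id))
            if loc.specificity == "species_specific":
                called_specific.add((sp, rec.record_id))
            elif loc.specificity == "shared":
                called_shared.add((sp, rec.record_id))
            if loc.subfamily != "UNASSIGNED":
                n_subfam_total += 1
                n_subfam_match += loc.subfamily == rec.subfamily
            for site, status in calls_by_locus.get(loc.locus_id, {}).items():
                a = rec.site_states.get(site)
                c_next = rec.site_states.get(site + 1)
                if a in (None, "-", "N") or c_next in ("N",):
                    continue
                expected = "positive" if (a == "A" and c_next == "C") else "negative"
                if status in ("positive", "negative"):
                    n_motif_total += 1
                    n_motif_match += status == expected
    tp = len(called_specific & eligible_specific)
    fp = len(called_specific - eligible_specific)

    report = {
        "n_truth_eligible": len(eligible),
        "n_truth_specific": len(eligible_specific),
        "n_truth_shared": len(eligible_shared),
        "n_called_specific": len(called_specific),
        "specificity_recall": tp / len(eligible_specific) if eligible_specific else None,
        "specificity_precision": tp / (tp + fp) if (tp + fp) else None,
        "shared_recall": (len(called_shared & eligible_shared) / len(eligible_shared)
                          if eligible_shared else None),
        "subfamily_accuracy": n_subfam_match / n_subfam_total if n_subfam_total else None,
        "motif_status_accuracy": n_motif_match / n_motif_total if n_motif_total else None,
        "locus_recall_all_eligible": (len(matched_ids & {(r.species, r.record_id) for r in eligible})
                                      / len(eligible) if eligible else None),
    }
    return report


def truth_prevalence(truth: TruthManifest, config: SimConfig,
                     min_full_len: int) -> pd.DataFrame:
    """Prevalence table computed directly from planted truth states of
    species-specific full-length elements (followed-by-C rule), the oracle
    for the called table."""
    rows = {}
    for r in truth.records:
        if (not r.full_length or r.gap_overlap
                or (r.end - r.start) < min_full_len
                or r.specificity != "species_specific"):
            continue
        key = (r.species, r.subfamily)
        b = rows.setdefault(key, {"species": r.species, "subfamily": r.subfamily,
                                  **{f"n_total_{s}": 0 for s in config.sites},
                                  **{f"n_positive_{s}": 0 for s in config.sites}})
        for s in config.sites:
            pos = (r.site_states.get(s) == "A"
                   and r.site_states.get(s + 1) == "C")
            b[f"n_total_{s}"] += 1
            b[f"n_positive_{s}"] += pos
    df = pd.DataFrame(sorted(rows.values(), key=lambda x: (x["species"], x["subfamily"])))
    for s in config.sites:
        df[f"pct_{s}"] = (100 * df[f"n_positive_{s}"] / df[f"n_total_{s}"]).map(round_pct)
    return df


# ---------------------------------------------------------------------------
# full run


def run_all(config: SimConfig, outdir,
            params: DiscoveryParams = DiscoveryParams(),
            mode: str = "followed_by_C") -> dict:
    """Full pipeline on simulated genomes; returns the evaluation report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    library = build_consensus_lineage(config)
    genomes, truth = simulate_genomes(config, library)

    library.to_fasta(outdir / "consensus_library.fa")
    for sp in sorted(genomes):
        write_fasta(outdir / f"genome.{sp}.fa", genomes[sp])
    write_truth(truth, outdir / "truth")

    loci_by_sp, rejects_by_sp, ortho_calls = discover_and_call(genomes, library, params)
    site_calls, loci_meta, windows, pfm_span = classify_and_call_sites(
        loci_by_sp, library, sites=config.sites, mode=mode)

    for sp in sorted(loci_by_sp):
        write_bed(outdir / f"loci.{sp}.bed",
                  [BedInterval(l.contig, l.start, l.end, f"{l.subfamily}|{l.specificity}",
                               "0", l.strand) for l in loci_by_sp[sp]],
                  comment="full-length loci; name=subfamily|specificity")
        rej = pd.DataFrame([{"locus_id": l.locus_id, "contig": l.contig,
                             "start": l.start, "end": l.end, "length": l.length,
                             "reason": reason} for l, reason in rejects_by_sp[sp]])
        write_tsv(rej, outdir / f"rejects.{sp}.tsv")
    dump_json({lid: {"final": c.final, "evidence": c.per_species_evidence}
               for lid, c in sorted(ortho_calls.items())}, outdir / "orthology_calls.json")

    calls_df = pd.DataFrame([{
        "locus_id": c.locus_id, "species": loci_meta[c.locus_id][0],
        "subfamily": loci_meta[c.locus_id][1], "site": c.site,
        "status": c.status, "window": c.window} for c in site_calls])
    write_tsv(calls_df, outdir / "site_calls.tsv")

    young = [n for n, st in config.site333_state_per_subfamily.items() if st == "C"]
    old = [n for n, st in config.site333_state_per_subfamily.items() if st == "T"]
    # the lineage analysis is over species-specific full-length elements
    specific_ids = {l.locus_id for sp in loci_by_sp for l in loci_by_sp[sp]
                    if l.specificity == "species_specific"}
    prev = prevalence_table([c for c in site_calls if c.locus_id in specific_ids],
                            loci_meta,
                            groups={"young_pooled": young, "old_pooled": old})
    write_tsv(prev, outdir / "prevalence.tsv")

    pfm = position_frequency_matrix(windows, pfm_span)
    write_tsv(pfm, outdir / "pfm_site332_region.tsv")

    report = evaluate_run(loci_by_sp, truth, config, params.min_full_len,
                          site_calls, loci_meta)
    report["prevalence_truth_vs_called_max_abs_pct_diff"] = _prev_diff(
        truth_prevalence(truth, config, params.min_full_len), prev, config)
    dump_json(report, outdir / "evaluation.json")

    _write_manifest(config, params, outdir)
    return report


def _prev_diff(truth_df: pd.DataFrame, called_df: pd.DataFrame, config: SimConfig):
    merged = truth_df.merge(called_df, on=["species", "subfamily"],
                            suffixes=("_truth", "_called"))
    if merged.empty:
        return None
    diffs = []
    for s in config.sites:
        diffs.append((merged[f"pct_{s}_truth"] - merged[f"pct_{s}_called"]).abs().max())
    return float(max(diffs))


def _write_manifest(config: SimConfig, params: DiscoveryParams, outdir: Path) -> None:
    digests = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "run_manifest.json":
            digests[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "params": dataclasses.asdict(params),
        "output_digests": digests,
    }
    dump_json(manifest, outdir / "run_manifest.json")
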