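"""Simulator ground truth: lineage construction, planting, determinism."""

import dataclasses

import numpy as np
import pytest

import edlib
from l1m6a.seq import revcomp
from l1m6a.simulate import (CapacityError, SimConfig, TruthManifest,
                            TruthRecord, build_consensus_lineage, read_truth,
                            simulate_genomes, write_truth)


def _cfg(**kw):
    base = dict(seed=5, n_species=3, ancestral_genome_len=80_000,
                consensus_len=700, utr_span=(1, 650),
                n_shared_insertions=3, n_specific_insertions_per_species=4,
                truncation_min_cut=150)
    base.update(kw)
    return SimConfig(**base)


def _window_free_positions(cfg):
    mask = np.ones(cfg.consensus_len, dtype=bool)
    for s in cfg.sites:
        mask[s - 3:s + 2] = False
    return mask


class TestConsensusLineage:
    def test_zero_rate_gives_identical_consensuses_outside_forced_windows(self):
        cfg = _cfg(per_step_consensus_divergence=0.0)
        lib = build_consensus_lineage(cfg)
        free = _window_free_positions(cfg)
        seqs = [np.frombuffer(r.sequence.encode(), dtype="S1") for r in lib]
        for a, b in zip(seqs, seqs[1:]):
            assert (a[free] == b[free]).all()

    def test_exact_substitution_count_between_adjacent_consensuses(self):
        cfg = _cfg(per_step_consensus_divergence=0.02)
        lib = build_consensus_lineage(cfg)
        free = _window_free_positions(cfg)
        expected = round(0.02 * free.sum())
        seqs = [np.frombuffer(r.sequence.encode(), dtype="S1") for r in lib]
        for a, b in zip(seqs, seqs[1:]):
            assert (a[free] != b[free]).sum() == expected

    def test_site333_state_controls_motif_of_raw_consensus(self):
        cfg = _cfg()
        lib = build_consensus_lineage(cfg)
        for rec in lib:
            state = cfg.site333_state_per_subfamily[rec.name]
            window = rec.sequence[329:334]          # 1-based 330..334
            assert window == "GGA" + state + "T"
            # conserved sites always keep a valid DRACH
            assert rec.sequence[492:497] == "GGACT"
            assert rec.sequence[597:602] == "GGACT"

    def test_youngest_is_coordinate_reference(self):
        lib = build_consensus_lineage(_cfg())
        assert lib.reference.name == "L1Hs"
        assert lib.reference.age_rank == 1

    def test_utr_too_short_for_sites_is_invalid(self):
        with pytest.raises(ValueError):
            _cfg(utr_span=(1, 500))   # site 600 window would fall outside


class TestSimulatedGenomes:
    def test_zero_noise_elements_equal_their_consensus(self, ):
        cfg = _cfg(truncation_prob=0.0, per_copy_substitution_rate=0.0,
                   interspecies_divergence=0.0, gap_run_prob=0.0)
        lib = build_consensus_lineage(cfg)
        genomes, truth = simulate_genomes(cfg, lib)
        assert len(truth.records) > 0
        for r in truth.records:
            seq = genomes[r.species][r.contig][r.start:r.end]
            if r.strand == "-":
                seq = revcomp(seq)
            assert seq == lib.get(r.subfamily).sequence

    def test_forced_truncation_leaves_no_full_length_element(self):
        cfg = SimConfig(seed=2, n_species=2, ancestral_genome_len=60_000,
                        truncation_prob=1.0, truncation_min_cut=600,
                        n_shared_insertions=2, n_specific_insertions_per_species=3)
        lib = build_consensus_lineage(cfg)
        _, truth = simulate_genomes(cfg, lib)
        # 6019 - 600 = 5419 < 5500: everything fails the full-length bar
        assert all(r.length <= 5419 for r in truth.records)
        assert not any(r.full_length for r in truth.records)

    def test_shared_records_form_orthologous_tuples(self, small_config, small_sim):
        _, truth = small_sim
        shared = [r for r in truth.records if r.specificity == "shared"]
        assert len(shared) == small_config.n_shared_insertions * small_config.n_species
        by_id = {}
        for r in shared:
            by_id.setdefault(r.record_id, []).append(r)
        assert len(by_id) == small_config.n_shared_insertions
        for recs in by_id.values():
            assert len({r.species for r in recs}) == small_config.n_species
            assert len({(r.subfamily, r.strand, r.truncated) for r in recs}) == 1

    def test_total_insertion_conservation(self, small_config, small_sim):
        _, truth = small_sim
        expected = (small_config.n_shared_insertions * small_config.n_species
                    + small_config.n_specific_insertions_per_species
                    * small_config.n_species)
        assert len(truth.records) == expected

    def test_planted_spans_within_genome_and_non_overlapping(self, small_sim):
        genomes, truth = small_sim
        for sp in genomes:
            recs = sorted(truth.for_species(sp), key=lambda r: r.start)
            glen = len(genomes[sp]["chr1"])
            for r in recs:
                assert 0 <= r.start < r.end <= glen
            for a, b in zip(recs, recs[1:]):
                assert a.end <= b.start

    def test_determinism_identical_config_identical_output(self):
        cfg1, cfg2 = _cfg(), _cfg()
        lib1, lib2 = build_consensus_lineage(cfg1), build_consensus_lineage(cfg2)
        g1, t1 = simulate_genomes(cfg1, lib1)
        g2, t2 = simulate_genomes(cfg2, lib2)
        assert g1 == g2
        assert [dataclasses.asdict(r) for r in t1.records] == \
               [dataclasses.asdict(r) for r in t2.records]

    def test_capacity_error_when_genome_too_small(self):
        with pytest.raises(CapacityError):
            cfg = _cfg(ancestral_genome_len=20_000,
                       n_specific_insertions_per_species=20)
            simulate_genomes(cfg, build_consensus_lineage(cfg))

    def test_realized_per_copy_divergence_tracks_configured_rate(self):
        """Mean realized divergence within 3 binomial SE of rate x age rank."""
        cfg = SimConfig(seed=13, n_species=1, ancestral_genome_len=700_000,
                        subfamily_names=("L1PA2", "L1Hs"),
                        consensus_len=700, utr_span=(1, 650),
                        truncation_min_cut=150,
                        n_shared_insertions=0,
                        n_specific_insertions_per_species=120,
                        per_copy_substitution_rate=0.01,
                        interspecies_divergence=0.0,
                        truncation_prob=0.0, gap_run_prob=0.0)
        lib = build_consensus_lineage(cfg)
        genomes, truth = simulate_genomes(cfg, lib)
        for fam in cfg.subfamily_names:
            recs = [r for r in truth.records if r.subfamily == fam]
            assert len(recs) >= 50
            cons = lib.get(fam).sequence
            n_mismatch = n_sites = 0
            for r in recs:
                seq = genomes[r.species][r.contig][r.start:r.end]
                if r.strand == "-":
                    seq = revcomp(seq)
                n_mismatch += sum(x != y for x, y in zip(seq, cons))
                n_sites += len(cons)
            rate = 0.01 * cfg.age_rank(fam)
            se = (rate * (1 - rate) / n_sites) ** 0.5
            assert abs(n_mismatch / n_sites - rate) <= 3 * se

    def test_orthologous_flank_identity_bounded_by_divergence(self, small_config, small_sim):
        """±2 kb flanks of shared insertions align across species at
        identity >= 1 - 2 x interspecies divergence (expectation bound)."""
        genomes, truth = small_sim
        div = small_config.interspecies_divergence
        shared = {}
        for r in truth.records:
            if r.specificity == "shared":
                shared.setdefault(r.record_id, []).append(r)
        checked = 0
        for recs in list(shared.values())[:3]:
            a, b = recs[0], recs[1]
            for side in ("up", "down"):
                if side == "up":
                    fa = genomes[a.species][a.contig][a.start - 2000:a.start]
                    fb = genomes[b.species][b.contig][b.start - 2000:b.start]
                else:
                    fa = genomes[a.species][a.contig][a.end:a.end + 2000]
                    fb = genomes[b.species][b.contig][b.end:b.end + 2000]
                dist = edlib.align(fa, fb, mode="NW", task="distance")["editDistance"]
                ident = 1 - dist / 2000
                assert ident >= 1 - 2 * div - 0.01   # small sampling slack
                checked += 1
        assert checked == 6


class TestTruthIO:
    def test_bed_line_format(self, tmp_path):
        rec = TruthRecord("r1", "human", "chr1", 100, 6219, "+", "L1Hs",
                          "species_specific", False, True, False,
                          {332: "A"}, "AACCGGT")
        paths = write_truth(TruthManifest([rec]), tmp_path / "truth")
        bed = next(p for p in paths if p.suffix == ".bed")
        lines = [l for l in bed.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["chr1\t100\t6219\tL1Hs\t0\t+"]

    def test_empty_manifest_round_trips(self, tmp_path):
        paths = write_truth(TruthManifest([]), tmp_path / "truth")
        jpath = next(p for p in paths if p.suffix == ".json")
        assert read_truth(jpath).records == []

    def test_round_trip_is_lossless(self, tmp_path, small_sim):
        _, truth = small_sim
        paths = write_truth(truth, tmp_path / "truth")
        jpath = next(p for p in paths if p.suffix == ".json")
        back = read_truth(jpath)
        assert [dataclasses.asdict(r) for r in back.records] == \
               [dataclasses.asdict(r) for r in truth.records]
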