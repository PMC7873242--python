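"""DRACH scanning, site calls, subfamily assignment, prevalence, logo counts."""

import itertools
import re
from collections import Counter

import numpy as np
import pytest

from l1m6a.align import map_consensus_coords, global_align
from l1m6a.motif import (DRACH_KMERS, call_site_motif, classify_subfamily,
                         extract_window, map_onto_reference,
                         position_frequency_matrix, prevalence_table,
                         round_pct, scan_drach, SiteMotifCall)
from l1m6a.io_formats import ConsensusLibrary, SubfamilyConsensus

DRACH_RE = re.compile(r"(?=([GAT][GA]AC[TCA]))")


class TestScanDrach:
    @pytest.mark.parametrize("seq,expected", [
        ("GGACT", [3]),
        ("GGATT", []),        # A not followed by C
        ("AAAAAA", []),       # no C at +1
        ("TTGGACTTT", [5]),
        ("GGACTGGACT", [3, 8]),
    ])
    def test_examples(self, seq, expected):
        assert scan_drach(seq) == expected

    def test_accepted_5mer_set_has_exactly_18_members(self):
        # independent enumeration: regex over all 1024 5-mers
        accepted = ["".join(t) for t in itertools.product("ACGT", repeat=5)
                    if re.fullmatch(r"[GAT][GA]AC[TCA]", "".join(t))]
        assert len(accepted) == 18
        assert {k for k in accepted} == set(DRACH_KMERS)
        for kmer in accepted:
            assert scan_drach(kmer) == [3]

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), 200))
            oracle = [m.start() + 3 for m in DRACH_RE.finditer(seq)]
            assert scan_drach(seq) == oracle


@pytest.fixture(scope="module")
def library(small_library):
    return small_library


def _with_base(seq: str, pos1: int, base: str) -> str:
    return seq[:pos1 - 1] + base + seq[pos1:]


class TestCallSiteMotif:
    def test_t333c_gain_and_t333g_control(self, library):
        """C after A332 -> motif positive; T or G -> negative, both modes."""
        young = library.get("L1Hs")
        for base, expected in [("C", "positive"), ("T", "negative"),
                               ("G", "negative")]:
            query, cmap = map_onto_reference(
                _with_base(young.sequence, 333, base), library)
            for mode in ("followed_by_C", "full_drach"):
                call = call_site_motif(query, cmap, 332, mode=mode)
                assert call.status == expected, (base, mode)

    def test_old_lineage_consensus_negative_young_positive(self, library):
        # raw consensuses: site-333 state decides 332 status per subfamily
        for rec in library:
            query, cmap = map_onto_reference(rec.sequence, library)
            call = call_site_motif(query, cmap, 332)
            state = {"C": "positive", "T": "negative"}
            assert call.status == state["C" if rec.name in ("L1Hs", "L1PA2") else "T"]
            # conserved sites positive in every subfamily
            assert call_site_motif(query, cmap, 495).status == "positive"
            assert call_site_motif(query, cmap, 600).status == "positive"

    def test_deleted_center_counts_as_deleted(self, library):
        young = library.get("L1Hs")
        query = young.sequence[:331] + young.sequence[332:]   # drop base 332
        q, cmap = map_onto_reference(query, library)
        assert call_site_motif(q, cmap, 332).status == "deleted"

    def test_n_in_window_is_ambiguous(self, library):
        young = library.get("L1Hs")
        q, cmap = map_onto_reference(_with_base(young.sequence, 331, "N"), library)
        assert call_site_motif(q, cmap, 332).status == "ambiguous"

    def test_site_outside_map_is_an_error(self, library):
        q, cmap = map_onto_reference(library.get("L1Hs").sequence, library)
        with pytest.raises(ValueError):
            call_site_motif(q, cmap, 5000)

    def test_positive_full_drach_consistent_with_scan(self, library):
        for rec in library:
            q, cmap = map_onto_reference(rec.sequence, library)
            for site in (332, 495, 600):
                call = call_site_motif(q, cmap, site, mode="full_drach")
                if call.status == "positive":
                    assert scan_drach(call.window) == [3]


class TestClassifySubfamily:
    def test_pristine_copy_assigned_with_identity_one(self, library):
        name, idents = classify_subfamily(library.get("L1PA4").sequence, library)
        assert name == "L1PA4"
        assert idents["L1PA4"] == 1.0
        assert all(v < 1.0 for k, v in idents.items() if k != "L1PA4")

    def test_robust_to_one_percent_substitutions(self, library):
        """Copies at 1% divergence stay correctly assigned when consensuses
        differ by far more per lineage step."""
        rng = np.random.default_rng(14)
        names = [r.name for r in library]
        for _ in range(100):
            true = names[int(rng.integers(len(names)))]
            seq = list(library.get(true).sequence)
            for i in rng.choice(len(seq), max(1, len(seq) // 100), replace=False):
                seq[i] = "ACGT"[("ACGT".index(seq[i]) + 1) % 4]
            name, _ = classify_subfamily("".join(seq), library)
            assert name == true

    def test_exact_tie_is_ambiguous(self):
        seq = "ACGT" * 250
        lib = ConsensusLibrary([
            SubfamilyConsensus("A", 2, seq, (1, 900)),
            SubfamilyConsensus("B", 1, seq, (1, 900), is_coordinate_reference=True),
        ])
        name, idents = classify_subfamily(seq, lib)
        assert name is None
        assert idents["A"] == idents["B"]


class TestPrevalence:
    def _calls(self, n_pos, n_neg, site=332, status_extra=()):
        calls = []
        meta = {}
        for i in range(n_pos + n_neg):
            lid = f"e{i}"
            status = "positive" if i < n_pos else "negative"
            calls.append(SiteMotifCall(lid, site, status, "GGACT"))
            meta[lid] = ("human", "L1PA3")
        for j, status in enumerate(status_extra):
            lid = f"x{j}"
            calls.append(SiteMotifCall(lid, site, status, "GG-CT"))
            meta[lid] = ("human", "L1PA3")
        return calls, meta

    def test_paper_style_percentage(self):
        calls, meta = self._calls(15, 106)     # 15 of 121
        df = prevalence_table(calls, meta)
        row = df.iloc[0]
        assert row["n_total_332"] == 121 and row["n_positive_332"] == 15
        assert row["pct_332"] == 12.4

    def test_all_positive_is_100(self):
        calls, meta = self._calls(7, 0)
        assert prevalence_table(calls, meta).iloc[0]["pct_332"] == 100.0

    def test_zero_denominator_is_na_not_zero(self):
        calls, meta = self._calls(0, 0, status_extra=["deleted", "ambiguous"])
        df = prevalence_table(calls, meta, denominator="callable")
        assert df.iloc[0]["n_total_332"] == 0
        assert np.isnan(df.iloc[0]["pct_332"])

    def test_deleted_counts_in_total_but_not_positive_by_default(self):
        calls, meta = self._calls(3, 1, status_extra=["deleted"])
        row = prevalence_table(calls, meta).iloc[0]
        assert row["n_total_332"] == 5 and row["n_positive_332"] == 3

    def test_pooled_group_rows(self):
        calls, meta = self._calls(4, 0)
        extra = [SiteMotifCall("y0", 332, "negative", "GGATT")]
        meta["y0"] = ("human", "L1PA2")
        df = prevalence_table(calls + extra, meta,
                              groups={"young": ["L1PA2", "L1PA3"]})
        grp = df[df["subfamily"] == "young"].iloc[0]
        assert grp["n_total_332"] == 5 and grp["n_positive_332"] == 4
        assert grp["pct_332"] == 80.0

    def test_round_half_up_one_decimal(self):
        assert round_pct(12.35) == 12.4
        assert round_pct(92.85) == 92.9
        assert round_pct(100.0) == 100.0


class TestPositionFrequencyMatrix:
    def test_identical_windows_give_unit_frequencies(self):
        df = position_frequency_matrix(["GGACTGGAC"] * 10, (328, 336))
        for j, ch in enumerate("GGACTGGAC"):
            row = df.iloc[j]
            assert row[f"count_{ch}"] == 10
            assert row[f"freq_{ch}"] == 1.0

    def test_frequencies_sum_to_one_and_counts_match_brute_tally(self):
        rng = np.random.default_rng(6)
        windows = ["".join(rng.choice(list("ACGT-"), 9)) for _ in range(200)]
        df = position_frequency_matrix(windows, (328, 336))
        freq_cols = [c for c in df.columns if c.startswith("freq_")]
        assert np.allclose(df[freq_cols].sum(axis=1), 1.0, atol=1e-9)
        for j in range(9):
            tally = Counter(w[j] for w in windows)
            for ch in "ACGT":
                assert df.iloc[j][f"count_{ch}"] == tally.get(ch, 0)
            assert df.iloc[j]["count_gap"] == tally.get("-", 0)

    def test_window_extraction_via_coordinate_map(self, library):
        young = library.get("L1Hs")
        q, cmap = map_onto_reference(young.sequence, library)
        w = extract_window(q, cmap, (328, 336))
        assert w == young.sequence[327:336]
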