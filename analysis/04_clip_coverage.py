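#!/usr/bin/env python
"""Stage 4 — CLIP-style coverage computations on the L1 consensus.

Generates a seeded synthetic read set emulating a 5'-UTR-binding protein
(70% of fragments drawn from the 5' UTR) mapped to the reference consensus
from stage 1, then computes the normalized per-base coverage track, the
begin-and-end-within regional mean coverage of 5'UTR/ORF1/ORF2/3'UTR, and
filters synthetic peak intervals for DRACH motif content.

Run after 01:  python analysis/04_clip_coverage.py [--seed N]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from l1m6a.coverage import (Peak, ReadAln, RegionTable, coverage_track,
                            peak_motif_filter, regional_mean_coverage)
from l1m6a.io_formats import (BedInterval, ConsensusLibrary, write_bed,
                              write_bedgraph, write_tsv)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--simdir", type=Path, default=Path("results/01_simulation"))
    ap.add_argument("--outdir", type=Path, default=Path("results/04_coverage"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    library = ConsensusLibrary.from_fasta(args.simdir / "consensus_library.fa")
    cons = library.reference.sequence
    L = len(cons)
    utr_end = library.reference.utr_span[1]
    regions = RegionTable([("5UTR", 0, utr_end), ("ORF1", utr_end, 1926),
                           ("ORF2", 1990, 5813), ("3UTR", 5813, L)])

    rng = np.random.default_rng(args.seed + 400)
    reads = []
    for i in range(4000):
        lo, hi = (0, utr_end) if rng.random() < 0.7 else (0, L)
        length = int(rng.integers(20, 40))
        s = int(rng.integers(lo, hi - length))
        reads.append(ReadAln(f"r{i}", s, s + length))

    track = coverage_track(reads, L, normalize=True)
    write_bedgraph(args.outdir / "coverage.bedgraph", library.reference.name,
                   track, comment="depth / total mapped reads")
    means = regional_mean_coverage(reads, regions)
    write_tsv(pd.DataFrame([{"region": k, "reads_per_bp": v}
                            for k, v in means.items()]),
              args.outdir / "regional_mean_coverage.tsv")

    # synthetic peak intervals around the three m6A sites + two controls
    peaks = [Peak(300, 360), Peak(470, 520), Peak(580, 630),
             Peak(2500, 2560), Peak(5900, 5960)]
    peak_motif_filter(peaks, cons)
    write_bed(args.outdir / "peaks_motif.bed",
              [BedInterval(library.reference.name, p.start, p.end,
                           "motif" if p.has_motif else "no_motif")
               for p in peaks])

    print("regional mean coverage (reads fully inside region / region bp):")
    for name, _, _ in regions:
        print(f"  {name}: {means[name]:.3f}")
    print(f"5'UTR / ORF2 enrichment: {means['5UTR'] / means['ORF2']:.1f}x "
          "(the synthetic protein binds the 5' UTR)")
    n_motif = sum(p.has_motif for p in peaks)
    print(f"{n_motif}/{len(peaks)} peaks contain a DRACH motif "
          "(the three m6A-site peaks pass, the controls depend on background sequence)")
    print(f"outputs -> {args.outdir}")


if __name__ == "__main__":
    main()
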