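"""Readers and writers for on-disk artifacts: FASTA, BED, bedGraph, TSV,
JSON/YAML config, and the subfamily consensus library.

Coordinate conventions: 0-based half-open everywhere on disk and in memory
(BED native); 1-based positions appear only when quoting consensus sites
(A332 etc.).  All writers are deterministic: stable ordering, ``%.6g``
floats, LF line endings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} dict.

    Sequences are upper-cased; characters outside {A,C,G,T,N} (IUPAC
    ambiguity codes etc.) are converted to N, with a logged count.
    Empty files and duplicate ids are hard errors.
    """
    path = Path(path)
    records: dict[str, str] = {}
    n_other = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = [c for c in set(seq) if c not in _VALID]
        if bad:
            for c in bad:
                n_other += seq.count(c)
                seq = seq.replace(c, "N")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"{path}: empty or not a FASTA file")
    if n_other:
        logger.info("read_fasta(%s): converted %d non-ACGTN characters to N",
                    path, n_other)
    return records


def write_fasta(path, records: dict[str, str], width: int = 80,
                descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in records.items():
            desc = f" {descriptions[name]}" if descriptions and name in descriptions else ""
            fh.write(f">{name}{desc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


class BedInterval(NamedTuple):
    contig: str
    start: int
    end: int
    name: str = "."
    score: str = "0"
    strand: str = "+"


def read_bed(path) -> list[BedInterval]:
    """Read a 3-6 column BED file (0-based half-open; strand defaults '+')."""
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})")
            name = f[3] if len(f) > 3 else "."
            score = f[4] if len(f) > 4 else "0"
            strand = f[5] if len(f) > 5 else "+"
            if strand not in "+-.":
                raise ValueError(f"{path}: line {lineno}: bad strand {strand!r}")
            out.append(BedInterval(f[0], start, end, name, score, strand))
    return out


def write_bed(path, intervals, comment: str | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n")


def write_bedgraph(path, contig: str, values, comment: str | None = None) -> None:
    """Write a per-base value vector as run-length bedGraph lines."""
    with open(path, "w", newline="\n") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                v = values[run_start]
                fh.write(f"{contig}\t{run_start}\t{i}\t{v:.6g}\n")
                run_start = i


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def load_config(path) -> dict:
    """Load a YAML or JSON config file (YAML is a JSON superset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def dump_json(obj, path) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# subfamily consensus library


@dataclass
class SubfamilyConsensus:
    """A named L1 lineage consensus with age rank and 5' UTR span.

    ``age_rank`` is 1 for the youngest lineage and increases with age;
    ``utr_span`` is 1-based inclusive on the consensus.  Exactly one library
    member is the coordinate reference in which sites (A332 ...) are quoted.
    """

    name: str
    age_rank: int
    sequence: str
    utr_span: tuple[int, int]
    is_coordinate_reference: bool = False

    @property
    def utr(self) -> str:
        lo, hi = self.utr_span
        return self.sequence[lo - 1:hi]


@dataclass
class ConsensusLibrary:
    records: list[SubfamilyConsensus] = field(default_factory=list)

    def __post_init__(self):
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("consensus library: duplicate subfamily names")
        refs = [r for r in self.records if r.is_coordinate_reference]
        if len(refs) != 1:
            raise ValueError("consensus library: exactly one coordinate "
                             f"reference required, found {len(refs)}")
        ranks = [r.age_rank for r in self.records]
        if len(set(ranks)) != len(ranks):
            raise ValueError("consensus library: age ranks must be distinct")

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def get(self, name: str) -> SubfamilyConsensus:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def reference(self) -> SubfamilyConsensus:
        return next(r for r in self.records if r.is_coordinate_reference)

    def to_fasta(self, path) -> None:
        recs = {r.name: r.sequence for r in self.records}
        descs = {r.name: (f"age_rank={r.age_rank} "
                          f"utr={r.utr_span[0]}-{r.utr_span[1]} "
                          f"ref={int(r.is_coordinate_reference)}")
                 for r in self.records}
        write_fasta(path, recs, descriptions=descs)

    @classmethod
    def from_fasta(cls, path) -> "ConsensusLibrary":
        seqs = read_fasta(path)
        meta: dict[str, dict] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith(">"):
                    parts = line[1:].split()
                    kv = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
                    meta[parts[0]] = kv
        records = []
        for name, seq in seqs.items():
            kv = meta.get(name, {})
            if "age_rank" not in kv or "utr" not in kv:
                raise ValueError(f"consensus {name}: missing age_rank/utr metadata "
                                 "in FASTA description")
            lo, hi = kv["utr"].split("-")
            records.append(SubfamilyConsensus(
                name=name, age_rank=int(kv["age_rank"]), sequence=seq,
                utr_span=(int(lo), int(hi)),
                is_coordinate_reference=bool(int(kv.get("ref", "0")))))
        return cls(records)
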