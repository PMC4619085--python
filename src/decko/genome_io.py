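"""Sequence and interval I/O: FASTA, BED6 and coordinate-safe extraction.

All coordinates are 0-based half-open internally (BED-native). Any 1-based
display is labelled where it occurs. Genomes may contain N bases; downstream
guide filters reject protospacers that include them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
STRANDS = frozenset({"+", "-", "."})


class GenomeIOError(ValueError):
    """Malformed sequence input or an interval that cannot be resolved."""


@dataclass(frozen=True)
class GenomeRegion:
    """Half-open genomic interval [start, end) on a named sequence.

    strand "." means unstranded; extraction treats it like "+".
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise GenomeIOError("region chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise GenomeIOError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise GenomeIOError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A, C, G, T, N}, case-normalized to upper."""

    id: str
    seq: str = field(repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise GenomeIOError("sequence id must be non-empty")
        seq = self.seq.upper()
        if not seq:
            raise GenomeIOError(f"empty sequence for record {self.id!r}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise GenomeIOError(
                f"record {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string; N is self-complementary."""
    s = s.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise GenomeIOError(f"cannot reverse-complement non-DNA characters {sorted(bad)}")
    return str(Seq(s).reverse_complement())


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into SequenceRecords, order preserved.

    Sequences are uppercased and whitespace is stripped by the parser.
    Duplicate identifiers and empty sequences are reported as errors.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeIOError(f"duplicate identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise GenomeIOError(f"empty sequence for record {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise GenomeIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                descriptions: Mapping[str, str] | None = None) -> None:
    recs = []
    for r in records:
        desc = descriptions.get(r.id, "") if descriptions else ""
        recs.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    SeqIO.write(recs, str(Path(path)), "fasta")


def as_genome_dict(genome: Iterable[SequenceRecord] | SequenceRecord) -> dict[str, SequenceRecord]:
    if isinstance(genome, SequenceRecord):
        return {genome.id: genome}
    return {r.id: r for r in genome}


def extract_region(genome: Iterable[SequenceRecord] | SequenceRecord,
                   region: GenomeRegion) -> str:
    """Sequence of `region` from `genome`; minus strand returns the reverse complement."""
    recs = as_genome_dict(genome)
    if region.chrom not in recs:
        raise GenomeIOError(f"unknown chrom {region.chrom!r}")
    seq = recs[region.chrom].seq
    if region.end > len(seq):
        raise GenomeIOError(
            f"region end {region.end} exceeds length {len(seq)} of {region.chrom!r}"
        )
    sub = seq[region.start:region.end]
    if region.strand == "-":
        return reverse_complement(sub)
    return sub


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str | Path) -> list[tuple[str, GenomeRegion]]:
    """Read BED (3-6 columns) into (name, region) pairs; unnamed rows get row indices."""
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"BED file not found: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise GenomeIOError(f"BED file {path} has fewer than 3 columns")
    out = []
    for i, row in df.iterrows():
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name = row[3] if df.shape[1] > 3 and pd.notna(row[3]) else f"region_{i}"
        strand = row[5] if df.shape[1] > 5 and str(row[5]) in STRANDS else "."
        out.append((name, GenomeRegion(chrom, start, end, strand)))
    return out


def write_bed(entries: Iterable[tuple[str, GenomeRegion]], path: str | Path,
              header_lines: Iterable[str] = ()) -> None:
    """Write (name, region) pairs as BED6 with optional '#' header lines."""
    rows = [
        {"chrom": r.chrom, "start": r.start, "end": r.end, "name": name,
         "score": 0, "strand": r.strand if r.strand != "." else "."}
        for name, r in entries
    ]
    df = pd.DataFrame(rows, columns=BED6_COLUMNS)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def sequence_checksum(seq: str) -> str:
    """Short stable checksum used in order sheets and provenance headers."""
    return hashlib.sha1(seq.encode()).hexdigest()[:10]
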