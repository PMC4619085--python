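"""SpCas9 guide candidate enumeration, filtering, cut-site prediction and scoring.

A guide candidate is a 20-nt protospacer immediately 5' of an NGG PAM. The
Cas9 blunt cut falls 3 bp 5' of the PAM, i.e. between protospacer nucleotides
17 and 18 counted from the PAM-distal end. Scanning covers both strands;
minus-strand candidates report the protospacer as read 5'->3' on the minus
strand but keep plus-strand genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import (GenomeRegion, SequenceRecord, as_genome_dict,
                        reverse_complement)

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN  # 23
# Blunt cut 3 bp 5' of the PAM: between nt 17 and 18 from the PAM-distal end.
CUT_OFFSET_FROM_PAM = 3

BSMBI_SITE = "CGTCTC"
BSMBI_SITE_RC = "GAGACG"
POLY_T = "TTTT"

# Off-target mismatch weights for the default specificity score.
MISMATCH_WEIGHTS = {0: 10.0, 1: 3.0, 2: 1.0, 3: 0.2}


class GuideError(ValueError):
    pass


def _flags(protospacer: str) -> frozenset[str]:
    flags = set()
    if protospacer.startswith("G"):
        flags.add("starts_with_G")
    if BSMBI_SITE in protospacer or BSMBI_SITE_RC in protospacer:
        flags.add("contains_bsmbi")
    if POLY_T in protospacer:
        flags.add("contains_polyT")
    if "N" in protospacer:
        flags.add("contains_N")
    return frozenset(flags)


@dataclass(frozen=True)
class GuideCandidate:
    """A protospacer + PAM site with its predicted blunt-cut coordinate.

    `region` spans the 20-nt protospacer in plus-strand genomic coordinates;
    `cut_pos` is a 0-based gap coordinate strictly inside that interval.
    """

    region: GenomeRegion
    strand: str
    protospacer: str
    pam: str
    cut_pos: int
    score: float | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise GuideError(f"protospacer must be {PROTOSPACER_LEN} nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise GuideError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in {"+", "-"}:
            raise GuideError(f"guide strand must be + or -, got {self.strand!r}")
        if not (self.region.start < self.cut_pos < self.region.end):
            raise GuideError(
                f"cut_pos {self.cut_pos} outside protospacer "
                f"[{self.region.start}, {self.region.end})"
            )
        # flags are a pure function of the protospacer; always derive them
        object.__setattr__(self, "flags", _flags(self.protospacer))

    @property
    def starts_with_g(self) -> bool:
        return "starts_with_G" in self.flags


def cut_site(c: GuideCandidate) -> int:
    """Plus-strand gap coordinate of the blunt cut, 3 bp 5' of the PAM."""
    return c.cut_pos


def _cut_coordinate(proto_start: int, strand: str) -> int:
    # + strand: protospacer [s, s+20), PAM at [s+20, s+23); cut at s+20-3 = s+17.
    # - strand: PAM at [s-3, s) in genomic coords; cut at s+3 (mirror).
    if strand == "+":
        return proto_start + PROTOSPACER_LEN - CUT_OFFSET_FROM_PAM
    return proto_start + CUT_OFFSET_FROM_PAM


def find_protospacers(seq: SequenceRecord, search: GenomeRegion) -> list[GuideCandidate]:
    """Enumerate every NGG-adjacent 20-mer whose full 23-nt site lies in `search`.

    Returns candidates from both strands, sorted by protospacer start, then
    strand (+ before -). Windows shorter than 23 nt yield an empty list.
    """
    if search.chrom != seq.id:
        raise GuideError(f"search region chrom {search.chrom!r} != sequence id {seq.id!r}")
    if search.end > len(seq):
        raise GuideError(f"search region end {search.end} exceeds sequence length {len(seq)}")
    s = seq.seq
    out: list[GuideCandidate] = []
    for site_start in range(search.start, search.end - SITE_LEN + 1):
        site = s[site_start:site_start + SITE_LEN]
        # plus strand: [protospacer 20][N G G]
        if site[21] == "G" and site[22] == "G":
            proto = site[:PROTOSPACER_LEN]
            out.append(GuideCandidate(
                region=GenomeRegion(seq.id, site_start, site_start + PROTOSPACER_LEN, "+"),
                strand="+",
                protospacer=proto,
                pam=site[PROTOSPACER_LEN:],
                cut_pos=_cut_coordinate(site_start, "+"),
            ))
        # minus strand: plus-strand CCN prefix is the reverse-complemented PAM
        if site[0] == "C" and site[1] == "C":
            proto_start = site_start + PAM_LEN
            proto = reverse_complement(s[proto_start:proto_start + PROTOSPACER_LEN])
            out.append(GuideCandidate(
                region=GenomeRegion(seq.id, proto_start, proto_start + PROTOSPACER_LEN, "-"),
                strand="-",
                protospacer=proto,
                pam=reverse_complement(site[:PAM_LEN]),
                cut_pos=_cut_coordinate(proto_start, "-"),
            ))
    out.sort(key=lambda c: (c.region.start, c.strand))
    return out


def filter_candidates(candidates: Iterable[GuideCandidate], *,
                      exclude_bsmbi: bool = True,
                      exclude_polyt: bool = True,
                      exclude_n: bool = True) -> list[GuideCandidate]:
    """Drop candidates unusable for cloning or Pol III transcription.

    BsmBI sites inside the protospacer would be re-cleaved during cloning;
    TTTT acts as a Pol III terminator; N means unknown sequence. G-start
    status stays a flag — slot assignment, not filtering, decides on it.
    """
    kept = []
    for c in candidates:
        if exclude_bsmbi and "contains_bsmbi" in c.flags:
            continue
        if exclude_polyt and "contains_polyT" in c.flags:
            continue
        if exclude_n and "contains_N" in c.flags:
            continue
        kept.append(c)
    return kept


_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3, 78: 4}  # A C G T N


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _site_windows(arr: np.ndarray):
    if len(arr) < SITE_LEN:
        return None
    return np.lib.stride_tricks.sliding_window_view(arr, SITE_LEN)


def specificity_score(c: GuideCandidate,
                      genome: Iterable[SequenceRecord] | SequenceRecord,
                      max_mm: int = 3) -> float:
    """Mismatch-weighted off-target specificity in [0, 1].

    Exhaustively scans both strands of the genome for NGG-adjacent sites
    matching the protospacer with <= max_mm mismatches (ungapped, protospacer
    only; the PAM must still be NGG). The on-target site itself is excluded.
    score = 1 / (1 + sum over off-target sites of w(mismatches)) with
    w(0)=10, w(1)=3, w(2)=1, w(3)=0.2; 1.0 iff no off-target neighbour exists.
    """
    recs = as_genome_dict(genome)
    proto = _encode(c.protospacer)
    proto_rc = _encode(reverse_complement(c.protospacer))
    G, C = ord("G"), ord("C")
    weight_sum = 0.0
    on_target_seen = False
    for rec in recs.values():
        arr = _encode(rec.seq)
        win = _site_windows(arr)
        if win is None:
            continue
        starts = np.arange(win.shape[0])
        # plus strand: window = protospacer + NGG
        plus_pam = (win[:, 21] == G) & (win[:, 22] == G)
        mm_plus = (win[:, :PROTOSPACER_LEN] != proto).sum(axis=1)
        hit_plus = plus_pam & (mm_plus <= max_mm)
        for i in starts[hit_plus]:
            is_on = (rec.id == c.region.chrom and c.strand == "+"
                     and i == c.region.start)
            if is_on:
                on_target_seen = True
            else:
                weight_sum += MISMATCH_WEIGHTS[int(mm_plus[i])]
        # minus strand: window = CCN + revcomp(protospacer)
        minus_pam = (win[:, 0] == C) & (win[:, 1] == C)
        mm_minus = (win[:, PAM_LEN:] != proto_rc).sum(axis=1)
        hit_minus = minus_pam & (mm_minus <= max_mm)
        for i in starts[hit_minus]:
            is_on = (rec.id == c.region.chrom and c.strand == "-"
                     and i + PAM_LEN == c.region.start)
            if is_on:
                on_target_seen = True
            else:
                weight_sum += MISMATCH_WEIGHTS[int(mm_minus[i])]
    if not on_target_seen:
        raise GuideError(
            f"on-target site for {c.protospacer} at {c.region.chrom}:"
            f"{c.region.start} ({c.strand}) not found in genome"
        )
    return 1.0 / (1.0 + weight_sum)


def annotate_scores(candidates: Sequence[GuideCandidate],
                    genome: Iterable[SequenceRecord] | SequenceRecord,
                    max_mm: int = 3) -> list[GuideCandidate]:
    return [replace(c, score=specificity_score(c, genome, max_mm)) for c in candidates]


def candidates_to_table(candidates: Sequence[GuideCandidate]) -> pd.DataFrame:
    """Candidate table (TSV-ready): one row per guide."""
    return pd.DataFrame([
        {
            "chrom": c.region.chrom,
            "start": c.region.start,
            "end": c.region.end,
            "strand": c.strand,
            "protospacer": c.protospacer,
            "pam": c.pam,
            "cut_pos": c.cut_pos,
            "score": c.score,
            "flags": ",".join(sorted(c.flags)) or ".",
        }
        for c in candidates
    ])
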