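"""Seeded synthetic loci and clone allele sets (deletion, inversion, indels).

Emulates the raw material of a paired-guide deletion experiment: a locus
with valid SpCas9 sites flanking a deletable element, and the allele sets of
derived cell clones at configurable ploidy. NHEJ repair of the paired cut
yields a clean junction by default; junction indels (a few extra or missing
bases, as observed at real deletion points) and whole-fragment inversions
are available per allele. All randomness flows through explicit integer
seeds, so every call is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome_io import GenomeRegion, SequenceRecord, reverse_complement
from .guide_finder import filter_candidates, find_protospacers

MAX_JUNCTION_INDEL = 20
_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of a clone: wild type, deleted (with optional junction
    indel: >0 inserted bp, <0 extra resected bp), or inverted."""

    kind: str  # WT | DEL | INV
    junction_indel: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"WT", "DEL", "INV"}:
            raise SimulationError(f"unknown allele kind {self.kind!r}")
        if self.kind != "DEL" and self.junction_indel != 0:
            raise SimulationError("junction_indel applies to DEL alleles only")
        if abs(self.junction_indel) > MAX_JUNCTION_INDEL:
            raise SimulationError(
                f"|junction_indel| must be <= {MAX_JUNCTION_INDEL}"
            )


@dataclass(frozen=True)
class CloneSpec:
    """A clone: one AlleleSpec per allele, list length equal to ploidy."""

    ploidy: int
    alleles: tuple[AlleleSpec, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.ploidy <= 4:
            raise SimulationError("ploidy must be in [1, 4]")
        if len(self.alleles) != self.ploidy:
            raise SimulationError(
                f"clone has {len(self.alleles)} alleles for ploidy {self.ploidy}"
            )

    @property
    def true_category(self) -> str:
        """Genotype category the allele set should be classified as."""
        kinds = [a.kind for a in self.alleles]
        if "INV" in kinds:
            return "INV_HET" if "WT" in kinds else "INV_HOM"
        if all(k == "WT" for k in kinds):
            return "WT"
        if "WT" in kinds:
            return "HET"
        return "HOM_KO"


def _random_protospacer_site(rng: np.random.Generator) -> str:
    """A 23-nt G-start protospacer + AGG PAM free of filter-tripping motifs."""
    while True:
        proto = "G" + "".join(rng.choice(_BASES, size=19))
        site = proto + "AGG"
        if "TTTT" in site or "CGTCTC" in site or "GAGACG" in site:
            continue
        return site


def make_synthetic_locus(seed: int, length: int = 5000, gc: float = 0.5,
                         target: GenomeRegion | None = None,
                         window_bp: int = 200,
                         chrom: str | None = None) -> SequenceRecord:
    """Reproducible random locus with guide sites guaranteed in both windows.

    Draws bases i.i.d. at the requested GC content, then injects one
    engineered G-start protospacer+PAM site inside the design window at each
    target boundary (placed so its blunt cut flanks the target) and verifies
    by scanning that each window holds at least one usable candidate. The
    same seed always returns the identical sequence.
    """
    if target is None:
        target = GenomeRegion("synthetic_locus", (length - 600) // 2,
                              (length + 600) // 2, ".")
    chrom = chrom or target.chrom
    margin = window_bp // 2 + 30
    if target.start < margin or target.end + margin > length:
        raise SimulationError(
            "impossible geometry: target too close to the locus ends for the "
            "design windows"
        )
    if not 0.0 < gc < 1.0:
        raise SimulationError("gc must be a fraction in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    seq = rng.choice(_BASES, size=length, p=p)

    # Engineered sites: cuts just outside each boundary, well inside the window.
    for boundary, offset in ((target.start, -40), (target.end, +18)):
        site = _random_protospacer_site(rng)
        start = boundary + offset - 17  # cut (start+17) lands at boundary+offset
        seq[start:start + 23] = list(site)
    record = SequenceRecord(id=chrom, seq="".join(seq))

    half = window_bp // 2
    for side, boundary in (("left", target.start), ("right", target.end)):
        window = GenomeRegion(chrom, boundary - half, boundary + half, ".")
        if not filter_candidates(find_protospacers(record, window)):
            raise SimulationError(f"no usable candidate in the {side} window")
    return record


def _junction_insert(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_BASES, size=n))


def apply_deletion(locus: SequenceRecord | str, pair, spec: AlleleSpec) -> str:
    """Deleted allele: join the flanks at the predicted cut coordinates.

    junction_indel > 0 inserts that many random bases (seeded) at the
    junction; junction_indel < 0 resects extra bases from the right flank.
    Resulting length = locus - deletion_len + junction_indel.
    """
    if spec.kind != "DEL":
        raise SimulationError("apply_deletion requires a DEL allele spec")
    seq = locus.seq if isinstance(locus, SequenceRecord) else locus
    left, right = pair.deletion.start, pair.deletion.end
    indel = spec.junction_indel
    if indel > 0:
        return seq[:left] + _junction_insert(indel, spec.seed) + seq[right:]
    return seq[:left] + seq[right - indel:]


def apply_inversion(locus: SequenceRecord | str, pair) -> str:
    """Inverted allele: the fragment between the cuts, reverse-complemented
    in place. Length is conserved and the operation is an involution."""
    seq = locus.seq if isinstance(locus, SequenceRecord) else locus
    left, right = pair.deletion.start, pair.deletion.end
    return seq[:left] + reverse_complement(seq[left:right]) + seq[right:]


def simulate_allele(locus: SequenceRecord | str, pair, spec: AlleleSpec) -> str:
    seq = locus.seq if isinstance(locus, SequenceRecord) else locus
    if spec.kind == "WT":
        return seq
    if spec.kind == "DEL":
        return apply_deletion(seq, pair, spec)
    return apply_inversion(seq, pair)


def simulate_clone(locus: SequenceRecord | str, pair,
                   clone: CloneSpec) -> list[str]:
    """One sequence per allele, deterministic under each allele's seed."""
    return [simulate_allele(locus, pair, spec) for spec in clone.alleles]


def sample_clone_spec(seed: int, ploidy: int = 2,
                      kinds: Sequence[str] = ("WT", "DEL", "INV"),
                      indel_range: int = 0) -> CloneSpec:
    """Random CloneSpec for stress tests; indel_range > 0 draws DEL junction
    indels uniformly from [-indel_range, indel_range] (default: clean cuts)."""
    rng = np.random.default_rng(seed)
    alleles = []
    for i in range(ploidy):
        kind = str(rng.choice(list(kinds)))
        indel = 0
        if kind == "DEL" and indel_range > 0:
            indel = int(rng.integers(-indel_range, indel_range + 1))
        alleles.append(AlleleSpec(kind=kind, junction_indel=indel,
                                  seed=int(rng.integers(0, 2**31 - 1))))
    return CloneSpec(ploidy=ploidy, alleles=tuple(alleles))
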