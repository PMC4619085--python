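"""Diagnostic PCR prediction and genotype classification for deletion clones.

Three reactions genotype a clone:

* PCR 1 — external primers flanking the deletion: wild-type alleles give a
  long product, deleted alleles a short one (short = long - deletion length
  for a clean junction).
* PCR 2 — one external primer plus a primer internal to the deleted region:
  amplifies wild-type alleles only. It is the authority on WT-allele
  presence, because short deletion templates can outcompete the long
  wild-type template in PCR 1 and mask a heterozygote as homozygous.
* PCR 3 — one external primer plus the internal primer in inverted
  orientation: amplifies only alleles carrying the target fragment
  re-ligated in reverse. Inverted alleles look wild-type-sized in PCR 1,
  so without PCR 3 they would be miscalled.

Band intensities are deliberately ignored — relative allele populations
cannot be inferred from them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import SequenceRecord, reverse_complement
from .allele_sim import AlleleSpec, CloneSpec, simulate_allele, simulate_clone

MIN_PRIMER_LEN = 15
REACTIONS = ("pcr1", "pcr2", "pcr3")


class GenotypingError(ValueError):
    pass


def default_tolerance(expected_bp: int) -> float:
    """Band-size tolerance mimicking agarose resolution: max(10 bp, 5 %)."""
    return max(10.0, 0.05 * expected_bp)


def in_silico_pcr(templates: Mapping[str, str] | Sequence[str] | str,
                  fwd: str, rev: str, max_len: int = 10000
                  ) -> list[tuple[str, int]]:
    """Exact-match PCR products of (fwd, rev) on each template.

    Primers must sit on opposite strands; the product is the inclusive span
    between the outermost primer 5' ends. One product per valid orientation
    pair per template; products longer than max_len are dropped (they would
    not amplify). No binding yields an empty list, never an error.
    """
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < MIN_PRIMER_LEN or len(rev) < MIN_PRIMER_LEN:
        raise GenotypingError(f"primers must be >= {MIN_PRIMER_LEN} nt")
    if isinstance(templates, str):
        templates = {"template": templates}
    elif not isinstance(templates, Mapping):
        templates = {f"template_{i}": t for i, t in enumerate(templates)}
    products: list[tuple[str, int]] = []
    for tid, tmpl in templates.items():
        tmpl = tmpl.upper()
        for a, b in ((fwd, rev), (rev, fwd)):
            # a binds the plus strand, b the minus strand downstream of it
            b_rc = reverse_complement(b)
            a_pos = tmpl.find(a)
            while a_pos >= 0:
                b_pos = tmpl.find(b_rc, a_pos + len(a))
                if b_pos >= 0:
                    size = b_pos + len(b_rc) - a_pos
                    if size <= max_len:
                        products.append((tid, size))
                        break  # one product per orientation pair per template
                a_pos = tmpl.find(a, a_pos + 1)
    return products


@dataclass(frozen=True)
class PrimerSet:
    """Primers of the three-reaction genotyping scheme.

    ext_fwd / ext_rev flank the deletion on opposite strands (PCR 1);
    int_primer lies strictly inside the deleted region, oriented against
    ext_fwd (PCR 2); inv_primer is the internal primer in inverted
    orientation (PCR 3) and defaults to the reverse complement of
    int_primer.
    """

    ext_fwd: str
    ext_rev: str
    int_primer: str
    inv_primer: str = ""

    def __post_init__(self) -> None:
        for name in ("ext_fwd", "ext_rev", "int_primer"):
            p = getattr(self, name).upper()
            if len(p) < MIN_PRIMER_LEN:
                raise GenotypingError(f"{name} must be >= {MIN_PRIMER_LEN} nt")
            object.__setattr__(self, name, p)
        inv = (self.inv_primer or reverse_complement(self.int_primer)).upper()
        object.__setattr__(self, "inv_primer", inv)


@dataclass(frozen=True)
class GenotypingPlan:
    """Expected amplicon sizes for one targeting construct.

    Mirrors the bench worksheet for a construct: nominal length of cut,
    position relative to the TSS (free text, 1-based display convention),
    and expected wild-type / knockout PCR sizes, plus the internal- and
    inversion-reaction products the worksheet leaves implicit.
    """

    name: str
    deletion_len: int
    wt_size: int
    ko_size: int
    internal_size: int
    inv_size: int | None = None
    nominal_cut_len: int | None = None
    position_to_tss: str = ""
    tolerance_bp: float | None = None

    def __post_init__(self) -> None:
        if self.ko_size >= self.wt_size:
            raise GenotypingError("expected KO amplicon must be shorter than WT")

    def tolerance(self, expected: int) -> float:
        if self.tolerance_bp is not None:
            return self.tolerance_bp
        return default_tolerance(expected)


@dataclass(frozen=True)
class BandPattern:
    """Observed fragment sizes per reaction (bp)."""

    bands: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        clean = {}
        for rxn, sizes in self.bands.items():
            sizes = tuple(float(s) for s in sizes)
            if any(s <= 0 for s in sizes):
                raise GenotypingError("band sizes must be positive")
            clean[rxn] = sizes
        object.__setattr__(self, "bands", clean)

    def reaction(self, rxn: str) -> tuple[float, ...]:
        return self.bands.get(rxn, ())


@dataclass(frozen=True)
class GenotypeCall:
    category: str  # WT | HET | HOM_KO | INV_HET | INV_HOM | AMBIGUOUS
    evidence: Mapping[str, bool] = field(default_factory=dict)


def resolve_internal_partner(alleles: Mapping[str, str], primers: PrimerSet,
                             max_len: int = 10000) -> tuple[str, int]:
    """External primer for the internal (wild-type-only) reaction: must give
    a product on the wild-type allele and none on the deleted allele."""
    wt = {"WT": alleles["WT"]}
    ko = {"DEL": alleles["DEL"]}
    for partner in ("ext_fwd", "ext_rev"):
        ext = getattr(primers, partner)
        on_wt = dict(in_silico_pcr(wt, ext, primers.int_primer, max_len=max_len))
        on_ko = in_silico_pcr(ko, ext, primers.int_primer, max_len=max_len)
        if "WT" in on_wt and not on_ko:
            return partner, on_wt["WT"]
    raise GenotypingError(
        "int_primer gives no wild-type-only product with either external "
        "primer; it must lie inside the deleted region"
    )


def resolve_inversion_partner(alleles: Mapping[str, str], primers: PrimerSet,
                              max_len: int = 10000) -> tuple[str, int]:
    """Pick the external primer for the inversion reaction.

    The inverted internal primer points the same way as one of the external
    primers on the wild-type allele (no product) and opposes it only when
    the fragment is inverted. The usable partner is the external primer
    that yields a product on the inverted allele and none on wild-type or
    deleted alleles; pairing the other external primer with inv_primer
    would amplify wild type and is rejected.
    """
    inv_only = {"INV": alleles["INV"]}
    others = {k: v for k, v in alleles.items() if k != "INV"}
    for partner in ("ext_fwd", "ext_rev"):
        ext = getattr(primers, partner)
        on_inv = dict(in_silico_pcr(inv_only, ext, primers.inv_primer,
                                    max_len=max_len))
        on_rest = in_silico_pcr(others, ext, primers.inv_primer, max_len=max_len)
        if "INV" in on_inv and not on_rest:
            return partner, on_inv["INV"]
    raise GenotypingError(
        "inv_primer yields no inversion-specific product with either "
        "external primer"
    )


def predict_amplicons(locus: SequenceRecord | str, pair, primers: PrimerSet,
                      name: str = "construct",
                      nominal_cut_len: int | None = None,
                      position_to_tss: str = "",
                      tolerance_bp: float | None = None,
                      max_len: int = 10000) -> GenotypingPlan:
    """Run the three reactions on simulated WT/deleted/inverted alleles.

    Enforces the size arithmetic (KO = WT - deletion length for a clean
    junction; the inverted allele is WT-sized in PCR 1 and is the only
    allele giving a PCR 3 product) and errors naming the offending primer
    when a reaction does not behave as the scheme requires.
    """
    seq = locus.seq if isinstance(locus, SequenceRecord) else locus
    wt = seq
    ko = simulate_allele(seq, pair, AlleleSpec(kind="DEL"))
    inv = simulate_allele(seq, pair, AlleleSpec(kind="INV"))
    alleles = {"WT": wt, "DEL": ko, "INV": inv}

    def sizes(fwd, rev):
        prods = in_silico_pcr(alleles, fwd, rev, max_len=max_len)
        return {tid: size for tid, size in prods}

    p1 = sizes(primers.ext_fwd, primers.ext_rev)
    if "WT" not in p1:
        raise GenotypingError("external primer pair (ext_fwd/ext_rev) fails to "
                              "amplify the wild-type allele")
    if "DEL" not in p1:
        raise GenotypingError("external primer pair fails on the deleted allele; "
                              "a primer likely overlaps the deletion")
    wt_size, ko_size = p1["WT"], p1["DEL"]
    if ko_size != wt_size - pair.deletion_len:
        raise GenotypingError(
            f"KO amplicon {ko_size} != WT amplicon {wt_size} - deletion "
            f"length {pair.deletion_len}"
        )
    if p1.get("INV") != wt_size:
        raise GenotypingError("inverted allele should give a wild-type-sized "
                              "product with the external primers")

    _, internal_size = resolve_internal_partner(alleles, primers, max_len=max_len)

    partner, inv_size = resolve_inversion_partner(alleles, primers, max_len=max_len)

    return GenotypingPlan(name=name, deletion_len=pair.deletion_len,
                          wt_size=wt_size, ko_size=ko_size,
                          internal_size=internal_size, inv_size=inv_size,
                          nominal_cut_len=nominal_cut_len,
                          position_to_tss=position_to_tss,
                          tolerance_bp=tolerance_bp)


def _matches(sizes: Iterable[float], expected: int | None, tol: float) -> bool:
    if expected is None:
        return False
    return any(abs(s - expected) <= tol for s in sizes)


def extract_evidence(plan: GenotypingPlan, bands: BandPattern) -> dict[str, bool]:
    """Reduce observed bands to the four diagnostic booleans."""
    p1 = bands.reaction("pcr1")
    return {
        "long": _matches(p1, plan.wt_size, plan.tolerance(plan.wt_size)),
        "short": _matches(p1, plan.ko_size, plan.tolerance(plan.ko_size)),
        "internal": _matches(bands.reaction("pcr2"), plan.internal_size,
                             plan.tolerance(plan.internal_size)),
        "inversion": _matches(bands.reaction("pcr3"), plan.inv_size,
                              plan.tolerance(plan.inv_size or 0))
        if plan.inv_size is not None else len(bands.reaction("pcr3")) > 0,
    }


def classify_evidence(long: bool, short: bool, internal: bool,
                      inversion: bool) -> str:
    """Pure truth table over the four evidence booleans.

    The inversion reaction is evaluated first (it is the only evidence for
    inverted alleles, which mimic wild type elsewhere): with an internal
    band the clone still carries a wild-type allele (INV_HET); with a
    flanking band but no internal band every allele is disrupted (INV_HOM).
    Otherwise: long+internal without short = WT; long+short+internal = HET;
    short alone without internal = HOM_KO. Anything else is AMBIGUOUS.
    """
    if inversion:
        if internal:
            return "INV_HET"
        if short or long:
            return "INV_HOM"
        return "AMBIGUOUS"
    if long and internal and not short:
        return "WT"
    if long and short and internal:
        return "HET"
    if short and not long and not internal:
        return "HOM_KO"
    return "AMBIGUOUS"


def classify_genotype(plan: GenotypingPlan, bands: BandPattern) -> GenotypeCall:
    """Total classification: every band pattern yields a call, never a crash."""
    ev = extract_evidence(plan, bands)
    category = classify_evidence(ev["long"], ev["short"], ev["internal"],
                                 ev["inversion"])
    return GenotypeCall(category=category, evidence=ev)


def simulate_bands(locus: SequenceRecord | str, pair, primers: PrimerSet,
                   clone: CloneSpec, max_len: int = 10000) -> BandPattern:
    """Band pattern a clone's allele set would produce in the three reactions."""
    seq = locus.seq if isinstance(locus, SequenceRecord) else locus
    reference = {
        "WT": seq,
        "DEL": simulate_allele(seq, pair, AlleleSpec(kind="DEL")),
        "INV": simulate_allele(seq, pair, AlleleSpec(kind="INV")),
    }
    inv_partner, _ = resolve_inversion_partner(reference, primers, max_len=max_len)
    int_partner, _ = resolve_internal_partner(reference, primers, max_len=max_len)
    alleles = {f"allele_{i}": s
               for i, s in enumerate(simulate_clone(locus, pair, clone))}
    bands: dict[str, tuple[float, ...]] = {}
    for rxn, (fwd, rev) in {
        "pcr1": (primers.ext_fwd, primers.ext_rev),
        "pcr2": (getattr(primers, int_partner), primers.int_primer),
        "pcr3": (getattr(primers, inv_partner), primers.inv_primer),
    }.items():
        sizes = sorted({size for _, size in
                        in_silico_pcr(alleles, fwd, rev, max_len=max_len)})
        if sizes:
            bands[rxn] = tuple(float(s) for s in sizes)
    return BandPattern(bands=bands)


# --------------------------------------------------------------------------
# Optional naive primer picker (primers are user-supplied by default).
# --------------------------------------------------------------------------

def _gc_frac(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


def _unique_in_locus(seq: str, primer: str) -> bool:
    return seq.count(primer) + seq.count(reverse_complement(primer)) == 1


def _pick_unique(seq: str, lo: int, hi: int, length: int, revcomp: bool,
                 gc_lo: float = 0.40, gc_hi: float = 0.60) -> str:
    """First unique GC-balanced k-mer starting in [lo, hi); relaxes GC bounds
    rather than failing on GC-skewed loci."""
    for relax in (0.0, 0.1, 0.5):
        for start in range(lo, hi - length):
            p = seq[start:start + length]
            if "N" in p:
                continue
            if not (gc_lo - relax <= _gc_frac(p) <= gc_hi + relax):
                continue
            if _unique_in_locus(seq, p):
                return reverse_complement(p) if revcomp else p
    raise GenotypingError(f"no unique primer in [{lo}, {hi})")


def pick_primers(locus: SequenceRecord | str, pair, length: int = 20,
                 flank_offset: int = 60) -> PrimerSet:
    """Naive genotyping primer picker for a designed pair.

    ext_fwd starts about flank_offset bp upstream of the left cut, ext_rev
    the mirror downstream of the right cut, and the internal primer sits at
    the middle of the deleted region (reverse orientation, opposing
    ext_fwd). Uniqueness is exact-match within the locus, both strands.
    """
    seq = locus.seq if isinstance(locus, SequenceRecord) else locus
    left, right = pair.deletion.start, pair.deletion.end
    if left < flank_offset + length or right + flank_offset + length > len(seq):
        raise GenotypingError("locus too short for flanking primers")
    ext_fwd = _pick_unique(seq, left - flank_offset - length, left - length,
                           length, revcomp=False)
    ext_rev = _pick_unique(seq, right + flank_offset, right + flank_offset
                           + 2 * length, length, revcomp=True)
    mid = (left + right) // 2
    lo = max(left, mid - 40)
    hi = min(right - length, mid + 40)
    if hi <= lo:
        raise GenotypingError("deleted region too short for an internal primer")
    int_primer = _pick_unique(seq, lo, hi + 1, length, revcomp=True)
    return PrimerSet(ext_fwd=ext_fwd, ext_rev=ext_rev, int_primer=int_primer)


def plans_to_table(plans: Sequence[GenotypingPlan]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "name": p.name,
            "nominal_cut_len": p.nominal_cut_len,
            "position_to_tss": p.position_to_tss,
            "deletion_len": p.deletion_len,
            "expected_wt_bp": p.wt_size,
            "expected_ko_bp": p.ko_size,
            "expected_internal_bp": p.internal_size,
            "expected_inversion_bp": p.inv_size,
        }
        for p in plans
    ])


def read_bands_tsv(path) -> BandPattern:
    """Bands from a TSV with columns (reaction, size_bp)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"reaction", "size_bp"} <= set(df.columns):
        raise GenotypingError("band TSV needs columns: reaction, size_bp")
    bands: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        bands.setdefault(str(row["reaction"]), []).append(float(row["size_bp"]))
    return BandPattern(bands={k: tuple(v) for k, v in bands.items()})
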