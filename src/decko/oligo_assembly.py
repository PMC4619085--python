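"""Insert-1 oligo assembly and in-silico simulation of the two-step cloning.

The dual-gRNA construct is cloned from a single 165-nt starting oligo
("Insert-1") carrying both 20-nt targeting regions. Step 1 inserts the oligo
into a BsmBI-opened parental backbone by Gibson assembly; step 2 opens the
intermediate at the two BsmBI sites inside the oligo's central cassette and
ligates the universal Insert-2 (gRNA scaffold completion + H1 promoter),
removing both BsmBI recognition sites. The final construct expresses two
guides from independent U6 and H1 Pol III promoters.

The default template shipped with the package is a synthetic stand-in for
the published design (see data/insert1_default_synthetic.template); the
parental backbone here is likewise a minimal abstract model of the real
lentiviral vector, not its full sequence.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import DNA_ALPHABET, reverse_complement, sequence_checksum
from .guide_finder import BSMBI_SITE, BSMBI_SITE_RC, PROTOSPACER_LEN

# BsmBI: recognition CGTCTC, cleaves 1 nt (top) / 5 nt (bottom) downstream,
# leaving 4-nt 5' overhangs.
BSMBI_TOP_OFFSET = 1
BSMBI_BOTTOM_OFFSET = 5
OVERHANG_LEN = 4

DEFAULT_TEMPLATE_RESOURCE = "insert1_default_synthetic.template"
DEFAULT_CONSTANT_TOTAL = 125
SEGMENT_ORDER = ("gibson5", "grna1_target", "scaffold_frag", "bsmbi_cassette",
                 "grna2_target", "h1_frag", "gibson3")
CONSTANT_SEGMENTS = ("gibson5", "scaffold_frag", "bsmbi_cassette", "h1_frag", "gibson3")


class AssemblyError(ValueError):
    pass


class CloningError(AssemblyError):
    """A hard failure of the simulated cloning (residual site, lost insert)."""


def _count_bsmbi(seq: str) -> int:
    return seq.count(BSMBI_SITE) + seq.count(BSMBI_SITE_RC)


@dataclass(frozen=True)
class InsertTemplate:
    """Constant segments of the Insert-1 oligo plus the gRNA2 orientation.

    t2_orientation: "sense" places the second targeting sequence as-is;
    "revcomp" places its reverse complement (the second expression cassette
    may run on the opposite strand; parsing is orientation-aware either way).
    """

    gibson5: str
    scaffold_frag: str
    bsmbi_cassette: str
    h1_frag: str
    gibson3: str
    t2_orientation: str = "sense"

    def __post_init__(self) -> None:
        for name in CONSTANT_SEGMENTS:
            seg = getattr(self, name)
            if not seg or set(seg) - DNA_ALPHABET:
                raise AssemblyError(f"template segment {name!r} is not a DNA string")
        if self.t2_orientation not in {"sense", "revcomp"}:
            raise AssemblyError(
                f"t2_orientation must be sense or revcomp, got {self.t2_orientation!r}"
            )
        cass = self.bsmbi_cassette
        if cass.count(BSMBI_SITE) != 1 or cass.count(BSMBI_SITE_RC) != 1:
            raise AssemblyError(
                "bsmbi_cassette must contain CGTCTC exactly once and GAGACG exactly once"
            )
        for name in CONSTANT_SEGMENTS:
            if name == "bsmbi_cassette":
                continue
            if _count_bsmbi(getattr(self, name)) != 0:
                raise AssemblyError(f"template segment {name!r} contains a BsmBI site")

    @property
    def constant_total(self) -> int:
        return sum(len(getattr(self, n)) for n in CONSTANT_SEGMENTS)

    def oligo_length(self) -> int:
        return self.constant_total + 2 * PROTOSPACER_LEN


def _parse_template_text(text: str) -> dict[str, str]:
    values: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise AssemblyError(f"template line {lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        values[key.strip()] = val.strip().upper() if key.strip() != "t2_orientation" \
            else val.strip().lower()
    return values


def load_template(path: str | Path | None = None,
                  expect_constant_total: int | None = None) -> InsertTemplate:
    """Load an Insert-1 template from a key=sequence text file.

    With path=None the packaged default is loaded and its constant segments
    are required to sum to 125 nt (so the assembled oligo is 165 nt).
    """
    if path is None:
        text = (importlib.resources.files("decko.data")
                / DEFAULT_TEMPLATE_RESOURCE).read_text()
        if expect_constant_total is None:
            expect_constant_total = DEFAULT_CONSTANT_TOTAL
    else:
        text = Path(path).read_text()
    values = _parse_template_text(text)
    missing = [k for k in CONSTANT_SEGMENTS if k not in values]
    if missing:
        raise AssemblyError(f"template missing segments: {missing}")
    tpl = InsertTemplate(
        gibson5=values["gibson5"],
        scaffold_frag=values["scaffold_frag"],
        bsmbi_cassette=values["bsmbi_cassette"],
        h1_frag=values["h1_frag"],
        gibson3=values["gibson3"],
        t2_orientation=values.get("t2_orientation", "sense"),
    )
    if expect_constant_total is not None and tpl.constant_total != expect_constant_total:
        raise AssemblyError(
            f"template constant segments sum to {tpl.constant_total} nt, "
            f"expected {expect_constant_total}"
        )
    return tpl


def default_template() -> InsertTemplate:
    return load_template(None)


@dataclass(frozen=True)
class Insert1Oligo:
    """An assembled Insert-1 oligo with its named segment map."""

    seq: str
    segment_map: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        pos = 0
        for name, start, end in self.segment_map:
            if start != pos or end <= start:
                raise AssemblyError("segment map must tile the oligo contiguously")
            pos = end
        if pos != len(self.seq):
            raise AssemblyError("segment map does not cover the full oligo")

    def __len__(self) -> int:
        return len(self.seq)

    def segment(self, name: str) -> str:
        for seg, start, end in self.segment_map:
            if seg == name:
                return self.seq[start:end]
        raise KeyError(name)


def _check_targeting(t: str, label: str) -> str:
    t = t.upper()
    if len(t) != PROTOSPACER_LEN:
        raise AssemblyError(f"{label} must be {PROTOSPACER_LEN} nt, got {len(t)}")
    if set(t) - (DNA_ALPHABET - {"N"}):
        raise AssemblyError(f"{label} must be over A/C/G/T")
    if _count_bsmbi(t):
        raise AssemblyError(
            f"{label} contains a BsmBI site and would be cleaved during cloning"
        )
    return t


def assemble_insert1(t_u6: str, t_h1: str,
                     tpl: InsertTemplate | None = None) -> Insert1Oligo:
    """Build the Insert-1 oligo from the two 20-nt targeting sequences.

    seq = gibson5 + t_u6 + scaffold_frag + bsmbi_cassette + t2' + h1_frag +
    gibson3 where t2' is t_h1 or its reverse complement per the template's
    t2_orientation. With the default template the result is 165 nt. Refuses
    targeting sequences of the wrong length or containing a BsmBI site, and
    oligos where a junction creates a stray BsmBI site.
    """
    tpl = tpl or default_template()
    t_u6 = _check_targeting(t_u6, "U6 targeting sequence")
    t_h1 = _check_targeting(t_h1, "H1 targeting sequence")
    t2 = t_h1 if tpl.t2_orientation == "sense" else reverse_complement(t_h1)
    parts = [tpl.gibson5, t_u6, tpl.scaffold_frag, tpl.bsmbi_cassette,
             t2, tpl.h1_frag, tpl.gibson3]
    seq = "".join(parts)
    if seq.count(BSMBI_SITE) != 1 or seq.count(BSMBI_SITE_RC) != 1:
        raise AssemblyError(
            "assembled oligo must carry exactly one BsmBI site per strand; a "
            "targeting sequence or segment junction introduces an extra site"
        )
    segmap, pos = [], 0
    for name, part in zip(SEGMENT_ORDER, parts):
        segmap.append((name, pos, pos + len(part)))
        pos += len(part)
    return Insert1Oligo(seq=seq, segment_map=tuple(segmap))


def parse_insert1(oligo: str | Insert1Oligo,
                  tpl: InsertTemplate | None = None) -> tuple[str, str]:
    """Recover (t_u6, t_h1) from an Insert-1 oligo, undoing t2 orientation.

    Constant regions are verified at their expected offsets; the first
    mismatching segment is named in the error.
    """
    tpl = tpl or default_template()
    seq = oligo.seq if isinstance(oligo, Insert1Oligo) else oligo.upper()
    if len(seq) != tpl.oligo_length():
        raise AssemblyError(
            f"oligo length {len(seq)} != template length {tpl.oligo_length()}"
        )
    pos = 0
    variable: dict[str, str] = {}
    for name in SEGMENT_ORDER:
        if name in ("grna1_target", "grna2_target"):
            variable[name] = seq[pos:pos + PROTOSPACER_LEN]
            pos += PROTOSPACER_LEN
            continue
        const = getattr(tpl, name)
        if seq[pos:pos + len(const)] != const:
            raise AssemblyError(f"constant segment {name!r} does not match template")
        pos += len(const)
    t_u6 = variable["grna1_target"]
    t2 = variable["grna2_target"]
    t_h1 = t2 if tpl.t2_orientation == "sense" else reverse_complement(t2)
    return t_u6, t_h1


@dataclass(frozen=True)
class Fragment:
    """A digestion product: top-strand span [start, end) of the input.

    left_overhang is this fragment's 4-nt 5' overhang at its left end (None
    at an uncut molecule end); right_overhang is the overhang generated by
    the cut at its right end, carried on the top strand of the next fragment.
    """

    seq: str
    start: int
    end: int
    left_overhang: str | None = None
    right_overhang: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


def _bsmbi_cut_gaps(seq: str, circular: bool) -> list[int]:
    """Top-strand cut gap coordinates for every BsmBI site, either strand."""
    n = len(seq)
    scan = seq + seq[:10] if circular else seq
    gaps = []
    for m in re.finditer(BSMBI_SITE, scan):
        q = m.start()
        if q >= n:
            continue
        top = q + 6 + BSMBI_TOP_OFFSET
        if circular:
            gaps.append(top % n)
        elif top + OVERHANG_LEN <= n:
            gaps.append(top)
    for m in re.finditer(BSMBI_SITE_RC, scan):
        p = m.start()
        if p >= n:
            continue
        top = p - BSMBI_BOTTOM_OFFSET
        if circular:
            gaps.append(top % n)
        elif top >= 0:
            gaps.append(top)
    return sorted(set(gaps))


def bsmbi_digest(seq: str, circular: bool = False) -> list[Fragment]:
    """Cut `seq` at every BsmBI site (both strands), annotating 5' overhangs.

    Each site cleaves the top strand 1 nt and the bottom strand 5 nt
    downstream of the recognition sequence, producing 4-nt 5' overhangs
    (mirror arithmetic for sites on the bottom strand). A linear molecule
    with n sites yields n+1 fragments, a circular one n fragments; zero
    sites return the input as a single uncut fragment.
    """
    seq = seq.upper()
    n = len(seq)
    gaps = _bsmbi_cut_gaps(seq, circular)
    if not gaps:
        return [Fragment(seq=seq, start=0, end=n)]
    doubled = seq + seq

    def overhang(g: int) -> str:
        return doubled[g:g + OVERHANG_LEN] if circular else seq[g:g + OVERHANG_LEN]

    frags: list[Fragment] = []
    if circular:
        for i, g in enumerate(gaps):
            nxt = gaps[(i + 1) % len(gaps)]
            end = nxt if nxt > g else nxt + n
            frags.append(Fragment(seq=doubled[g:end], start=g, end=end % n or n,
                                  left_overhang=overhang(g),
                                  right_overhang=overhang(nxt)))
    else:
        bounds = [0] + gaps + [n]
        for i in range(len(bounds) - 1):
            g0, g1 = bounds[i], bounds[i + 1]
            frags.append(Fragment(
                seq=seq[g0:g1], start=g0, end=g1,
                left_overhang=overhang(g0) if g0 in gaps else None,
                right_overhang=overhang(g1) if g1 in gaps else None,
            ))
    return frags


# ---------------------------------------------------------------------------
# Abstract construct model and backbone constants.
#
# Promoter and scaffold sequences below are standard, publicly used vector
# parts (human U6 and H1 Pol III promoters, SpCas9 sgRNA scaffold); the
# vector body is a minimal synthetic stand-in for the real lentiviral
# backbone, whose full sequence is out of scope.
# ---------------------------------------------------------------------------

U6_CORE = (
    "GAGGGCCTATTTCCCATGATTCCTTCATATTTGCATATACGATACAAGGCTGTTAGAGAGATAATTGGAATTAA"
    "TTTGACTGTAAACACAAAGATATTAGTACAAAATACGTGACGTAGAAAGTAATAATTTCTTGGGTAGTTTGCAG"
    "TTTTAAAATTATGTTTTAAAATGGACTATCATATGCTTACCGTAACTTGAAAGTATTTCGATTTCTTGGCTTTA"
    "TA"
)  # U6 promoter body; the template's gibson5 arm is its final 25 nt

SGRNA_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

POL3_TERMINATOR = "TTTTTT"

H1_PROMOTER_CORE = (
    "GAACGCTGACGTCATCAACCCGCTCCAAGGAATCGCGGGCCCAGTGTCACTAGGCGGGAACACCCAGCGCGCGT"
    "GCGCCCTGGCAGGAAGATGGCTGTGAG"
)

PURO_STANDIN = (
    "ATGACCGAGTACAAGCCCACGGTGCGCCTCGCCACCCGCGACGACGTCCCCAGGGCCGTA"
)  # selection-marker stand-in for the vector body

# Stuffer removed from the parental plasmid in cloning step 1; carries the
# two BsmBI sites that open the backbone.
PARENTAL_STUFFER = "TCGTCTCAGGCCTTAAGGAGACGA"


@dataclass(frozen=True)
class ConstructModel:
    """Ordered named elements of a (partially) assembled construct."""

    stage: str  # parental | intermediate | final
    elements: tuple[tuple[str, str], ...]

    @property
    def seq(self) -> str:
        return "".join(s for _, s in self.elements)

    @property
    def element_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.elements)

    def bsmbi_site_count(self) -> int:
        return _count_bsmbi(self.seq)


def make_parental_backbone(tpl: InsertTemplate | None = None) -> ConstructModel:
    """Minimal circular parental backbone: U6 promoter, BsmBI stuffer, vector body."""
    tpl = tpl or default_template()
    return ConstructModel(stage="parental", elements=(
        ("U6_promoter", U6_CORE + tpl.gibson5),
        ("bsmbi_stuffer", PARENTAL_STUFFER),
        ("vector_body", tpl.gibson3 + SGRNA_SCAFFOLD + POL3_TERMINATOR + PURO_STANDIN),
    ))


def _insert2_seq(tpl: InsertTemplate) -> str:
    """Universal Insert-2: completes the first scaffold and adds the H1 promoter."""
    scaffold_completion = SGRNA_SCAFFOLD[len(tpl.scaffold_frag):]
    if not SGRNA_SCAFFOLD.startswith(tpl.scaffold_frag):
        scaffold_completion = SGRNA_SCAFFOLD
    return scaffold_completion + POL3_TERMINATOR + H1_PROMOTER_CORE


def simulate_cloning(t_u6_or_pair, t_h1: str | None = None,
                     tpl: InsertTemplate | None = None,
                     backbone: ConstructModel | None = None) -> ConstructModel:
    """Simulate both cloning steps and return the validated final construct.

    Accepts a GuidePair or two explicit 20-nt targeting sequences. Step 1
    (Gibson) replaces the parental stuffer with the assembled Insert-1;
    step 2 excises the oligo's BsmBI cassette and ligates Insert-2. Hard
    failures: a residual BsmBI site in the final sequence, or a targeting
    sequence absent or duplicated. Final element order is U6 promoter, gRNA1
    target, scaffold, H1 promoter, gRNA2 target, scaffold; small constant
    junction remnants are folded into the adjacent constant elements.
    """
    if t_h1 is None:
        pair = t_u6_or_pair
        t_u6, t_h1 = pair.u6_guide.protospacer, pair.h1_guide.protospacer
    else:
        t_u6 = t_u6_or_pair
    tpl = tpl or default_template()
    backbone = backbone or make_parental_backbone(tpl)
    oligo = assemble_insert1(t_u6, t_h1, tpl)

    parental_seq = backbone.seq
    if parental_seq.count(BSMBI_SITE) != 1 or parental_seq.count(BSMBI_SITE_RC) != 1:
        raise CloningError("parental backbone must carry one BsmBI site per strand")

    # Step 1: Gibson assembly via the two homology arms.
    i5 = parental_seq.find(tpl.gibson5)
    i3 = parental_seq.find(tpl.gibson3, i5 + len(tpl.gibson5))
    if i5 < 0 or i3 < 0:
        raise CloningError("backbone lacks a Gibson homology arm matching the template")
    intermediate_seq = parental_seq[:i5] + oligo.seq + parental_seq[i3 + len(tpl.gibson3):]
    if intermediate_seq.count(BSMBI_SITE) != 1 or intermediate_seq.count(BSMBI_SITE_RC) != 1:
        raise CloningError("intermediate plasmid must carry exactly the cassette's BsmBI sites")

    # Step 2: BsmBI digestion of the (circular) intermediate and Insert-2 ligation.
    gaps = _bsmbi_cut_gaps(intermediate_seq, circular=True)
    if len(gaps) != 2:
        raise CloningError(f"expected 2 BsmBI cuts in the intermediate, found {len(gaps)}")
    lo, hi = gaps
    excised = intermediate_seq[lo:hi]
    if _count_bsmbi(excised) != 2:
        raise CloningError("BsmBI recognition sites not removed by cassette excision")
    final_seq = intermediate_seq[:lo] + _insert2_seq(tpl) + intermediate_seq[hi:]

    if _count_bsmbi(final_seq) != 0:
        raise CloningError("residual BsmBI site in final construct")
    t2 = oligo.segment("grna2_target")
    for label, t in (("gRNA1", t_u6), ("gRNA2", t2)):
        hits = final_seq.count(t)
        if hits != 1:
            raise CloningError(
                f"{label} targeting sequence occurs {hits} times in the final "
                f"construct (expected exactly once)"
            )

    # Element decomposition (remnants folded into adjacent constant elements).
    cass_end = oligo.segment_map[3][2]
    tail = oligo.seq[hi - i5:cass_end]  # cassette remainder left after excision
    insert2 = _insert2_seq(tpl)
    scaffold1 = tpl.scaffold_frag + insert2[:-len(H1_PROMOTER_CORE)]
    elements = (
        ("U6_promoter", U6_CORE + tpl.gibson5),
        ("gRNA1_target", t_u6),
        ("scaffold", scaffold1),
        ("H1_promoter", H1_PROMOTER_CORE + tail),
        ("gRNA2_target", t2),
        ("scaffold", tpl.h1_frag + tpl.gibson3 + SGRNA_SCAFFOLD
         + POL3_TERMINATOR + PURO_STANDIN),
    )
    model = ConstructModel(stage="final", elements=elements)
    if model.seq != final_seq:
        raise CloningError("element decomposition inconsistent with spliced sequence")
    return model


def write_oligo_pool(oligos: dict[str, Insert1Oligo],
                     fasta_path: str | Path, tsv_path: str | Path,
                     header_lines: Iterable[str] = ()) -> None:
    """Emit an oligo pool as FASTA plus a TSV order sheet with checksums."""
    from .genome_io import SequenceRecord, write_fasta
    write_fasta([SequenceRecord(id=name, seq=o.seq) for name, o in oligos.items()],
                fasta_path)
    rows = [
        {"name": name, "sequence": o.seq, "length": len(o),
         "checksum": sequence_checksum(o.seq)}
        for name, o in oligos.items()
    ]
    with open(tsv_path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
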