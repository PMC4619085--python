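# Methods

## The design problem

Deleting a non-coding element with CRISPR requires two simultaneous Cas9
cuts flanking the element; non-homologous end joining (NHEJ) then re-ligates
the chromosome, removing the intervening fragment (or, commonly,
re-inserting it inverted). This toolkit models the full dry-lab pipeline:
guide selection, single-oligo cloning of the dual-guide vector, and the PCR
logic used to genotype derived clones.

## Guide model

A guide candidate is a 20-nt protospacer immediately 5′ of an NGG PAM
(SpCas9). Scanning enumerates every 23-nt window on both strands;
minus-strand candidates are reported as read 5′→3′ on the minus strand with
plus-strand genomic coordinates. The blunt double-strand cut is placed 3 bp
5′ of the PAM, i.e. between protospacer nucleotides 17 and 18 counted from
the PAM-distal end; the minus-strand rule is the exact mirror, so designs on
a reverse-complemented sequence give mirrored coordinates (property-tested).

Candidates are removed if the protospacer contains a BsmBI recognition site
(`CGTCTC`/`GAGACG` — it would be cleaved during cloning), a `TTTT` run
(both guide genes are Pol III transcripts and T-runs terminate Pol III;
this filter goes beyond the original published rules and is configurable),
or an N. Starting with G is recorded as a flag, not a filter: slot
assignment decides (below).

### Specificity score

The original workflow delegated scoring to an external web tool. Here the
default scorer is a deterministic, desk-scale stand-in: an exhaustive
ungapped scan of the supplied genome (both strands, PAM must still be NGG)
for sites within `max_mm` (default 3) mismatches of the protospacer,
excluding the on-target site, combined as

```
score = 1 / (1 + Σ_offtargets w(m)),   w(0)=10, w(1)=3, w(2)=1, w(3)=0.2
```

so a perfectly unique guide scores 1.0 and every additional neighbour
monotonically lowers the score (property-tested). The weights express that
a perfect off-target duplicate is far worse than a 3-mismatch neighbour;
they are package constants, not fitted quantities. Bulges and alternative
PAMs are out of scope. The scorer is a plain function, so externally
computed scores can be substituted by annotating candidates directly.

## Pair design

Candidates are drawn from a window (default 200 bp) at each boundary of the
region to delete. The window is **centered** on the boundary by default
(±100 bp): published constructs place cuts straddling the boundary (e.g.
"−70/+30" relative to a TSS), which an inside- or outside-only window could
not reproduce; both alternatives remain available as `window_mode`.

A kept pair must have the left cut strictly before the right cut,
non-overlapping protospacers, and a deletion interval — the span between
the two blunt-cut coordinates — that contains the target midpoint. Full
coverage of the target interior is not required: with centered windows a
cut may legitimately fall up to half a window inside the target, so
midpoint containment is the strongest guarantee compatible with the window
model. The realized deletion length differs from the requested size because
cuts are constrained to PAM positions; no attempt is made to force exact
nominal lengths.

Slotting: the U6 promoter conventionally initiates on G, so the G-starting
guide takes the U6 cassette and the other guide the H1 cassette (H1 accepts
any start). If both start with G the left guide takes U6; if neither does
the pair is rejected, unless `allow_prepend_g` is set, in which case the U6
transcript is modeled with a prepended G while the oligo keeps the exact
20-nt genomic match.

Ranking: `pair_score = min(member scores)` — a deletion fails if either cut
fails, so the weaker guide dominates (a product would let one excellent
guide mask a poor partner). Ties break toward deletion lengths closest to
the requested size, then by genomic position, making design fully
deterministic (re-runs are byte-identical).

## Insert-1 and the cloning simulation

The vector is cloned from a single 165-nt oligo:

```
gibson5 (25) | t_U6 (20) | scaffold_frag (25) | bsmbi_cassette (30) |
t_H1 (20) | h1_frag (25) | gibson3 (20)
```

Constant segments sum to 125 nt, enforced at template load, so any two
20-nt targeting sequences yield exactly 165 nt. The shipped default
template (`data/insert1_default_synthetic.template`) is a **synthetic
stand-in** that satisfies every structural constraint of the published
design — the cassette carries exactly one `CGTCTC` and one `GAGACG`,
oriented so that digestion excises both recognition sites, and no other
segment contains a BsmBI site; the exact published sequence is not
reproduced here. Templates are data, not code: any file with the same keys
loads, and a custom template with different segment lengths changes the
oligo length additively. The orientation of the second targeting segment is
a template option (`t2_orientation`, default `sense`); parsing is
orientation-aware, so round-trip correctness does not depend on the choice.
Assembly refuses targeting sequences containing a BsmBI site and oligos
where a segment junction happens to create one (both would be cleaved in
step 2).

BsmBI is modeled exactly: recognition `CGTCTC`, top-strand cut 1 nt and
bottom-strand cut 5 nt downstream, leaving 4-nt 5′ overhangs; bottom-strand
sites use the mirror arithmetic. Linear molecules with n sites give n+1
fragments, circular give n; fragment lengths always sum to the input.

The cloning simulation is element/sequence-level (no thermodynamics, no
transformation efficiency). The parental backbone is a minimal abstract
circular model — U6 promoter, a BsmBI stuffer, and a vector body whose ends
carry the Gibson homology arms — because the real lentiviral backbone's
full sequence is not needed for any computed result. Step 1 replaces the
stuffer with Insert-1 via the homology arms; step 2 digests the
intermediate at the cassette's two sites and ligates Insert-2, modeled as
the universal constant (scaffold completion + Pol III terminator + H1
promoter). Hard failures: any residual BsmBI site, or a targeting sequence
absent or duplicated in the final sequence. The final element order is
U6 promoter, gRNA1 target, scaffold, H1 promoter, gRNA2 target, scaffold;
small constant junction remnants are folded into adjacent constant
elements.

## Genotyping model

In-silico PCR uses exact primer matching on opposite strands; the product
is the inclusive span between the outermost primer 5′ ends, with one
product per orientation pair per template and a `max_len` cutoff (default
10 kb). Exact matching is deliberate: primer thermodynamics are out of
scope, and the classifier needs sizes, not yields.

Three reactions: (1) external flanking primers — long product from
wild-type alleles, short from deleted ones, with KO = WT − deletion length
enforced for clean junctions; (2) one external primer plus an internal
primer inside the deleted region — wild-type-only, and authoritative for
WT-allele presence because short templates can outcompete long ones in
reaction 1; (3) one external primer plus the internal primer in inverted
orientation — positive only on inversion alleles, which are wild-type-sized
in reaction 1. Which external primer partners the internal/inverted primer
is resolved automatically by requiring the diagnostic behaviour (product on
the intended allele class, none on the others); pairing the inverted primer
with the wrong external primer would amplify wild type.

Classification reduces bands to four booleans (long, short, internal,
inversion band, each matched within a tolerance of max(10 bp, 5 % of the
expected size) — agarose-gel resolution) and applies a total truth table:
inversion evidence is evaluated first (INV_HET with an internal band,
INV_HOM with flanking evidence but no internal band), then
long∧internal∧¬short → WT, long∧short∧internal → HET,
short∧¬long∧¬internal → HOM_KO, anything else AMBIGUOUS. Mixed
deletion+inversion clones on more than two alleles have no defined
category; with no wild-type allele present they fall under INV_HOM (no
intact allele remains), and genuinely uninterpretable patterns return
AMBIGUOUS with the evidence attached rather than a guess. Band intensities
are ignored throughout: amplification efficiency differences make them
unreliable estimators of allele ratios.

## Synthetic data

`make_synthetic_locus` draws i.i.d. bases at a requested GC content
(default 0.50, length 5 kb, 600-bp target — a typical promoter-deletion
geometry) and injects one engineered G-start protospacer+PAM site inside
each boundary window, with cuts landing 40 bp outside the left boundary and
18 bp outside the right, then verifies by scanning that each window holds a
usable candidate. Junction indels on deleted alleles default to a point
mass at 0 (clean NHEJ junction) with an optional uniform ±k range —
observed junctions in real clones include single-base insertions and
shifts of up to ~15 bp, but no distribution over them is established, so
the conservative default avoids inventing one. Inserted junction bases are
seeded-random. Ploidy runs 1–4 (pseudo-triploid lines are common among
transformed cells; default 2).

What the simulator does **not** emulate: chromatin or sequence effects on
cutting efficiency, repeat structure and homology (primer uniqueness is far
easier on i.i.d. sequence than in real genomes), bulk-population allele
mixtures, sequencing noise. Passing closed-loop tests therefore shows the
pipeline's internal consistency — designs, amplicon arithmetic and
classification agree — not that guide activity or PCR will succeed on any
particular real locus.

## Numerical and scale choices

All randomness flows through explicit integer seeds (numpy Generator); no
call is nondeterministic, and identical configuration reruns are
byte-identical. Test and acceptance problem sizes — 100 × 1-kb scans,
1000 assembly round trips, 25–100 designed 2.4-kb loci, exhaustive clone
sets at ploidy 2–3 — were chosen as the smallest sizes that exercise every
code path and strand case; the whole suite runs in seconds on one CPU.

The comparative-Ct implementation uses the standard sign convention
2^−ΔΔCt (one extra cycle to threshold = half the template). Worksheets
sometimes print the expression as `2^(Ct−Cc)`; taken literally that sign
would report less RNA as higher expression, so the literal form is kept
only behind `as_printed=True` for comparison against such worksheets.

## Known limitations

No on-target efficiency model (Doench-style scores can be plugged in as
external scores); off-target search is desk-scale, not genome-wide at human
scale; no gapped/bulged off-target matching; primer picking is a naive
uniqueness/GC heuristic, not a thermodynamic design; deletions are capped
in practice by PCR-able amplicon sizes, and multi-target library design is
greedy per-target with no cross-target optimization.
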