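# decko

Design toolkit for **paired-guide CRISPR deletion** of genomic elements —
promoters, enhancers, lncRNA loci and other non-coding regions that cannot be
disrupted by a single frameshift-inducing cut. It implements the
single-oligo dual-gRNA strategy (Double Excision CRISPR Knockout): two SpCas9
guides flanking the target are cloned from **one 165-nt starting
oligonucleotide**, making the design scalable from single loci to pooled
libraries.

The package covers the complete dry-lab side of such an experiment:

* **Guide finding** — enumerate every 20-nt protospacer adjacent to an NGG
  PAM on both strands, predict the blunt Cas9 cut 3 bp 5′ of the PAM
  (between protospacer nucleotides 17 and 18), filter candidates that carry
  BsmBI sites, T-runs (Pol III terminators) or Ns, and score specificity by
  exhaustive mismatch-weighted off-target counting:
  `score = 1 / (1 + Σ_sites w(m))` with `w(0..3) = 10, 3, 1, 0.2`.
* **Pair design** — draw candidates from 200-bp windows at the two target
  boundaries, slot the G-starting guide into the U6 cassette (H1 takes any
  start), and rank pairs by the weaker member's score; the predicted
  deletion is the interval between the two cut coordinates.
* **Oligo assembly & cloning simulation** — build the 165-nt Insert-1
  (`gibson5 | t₁ | scaffold-fragment | BsmBI cassette | t₂ | H1-fragment |
  gibson3`), then simulate both cloning steps: Gibson insertion into the
  parental backbone and Type IIS (BsmBI, `CGTCTC(1/5)`) excision/ligation of
  the universal Insert-2. The final construct is verified BsmBI-free with
  each targeting sequence present exactly once downstream of its promoter.
* **Genotyping** — in-silico PCR predicts the wild-type, knockout and
  inversion amplicons for the three diagnostic reactions (flanking PCR,
  wild-type-only internal PCR, inversion PCR), and a total truth-table
  classifier calls clones WT / HET / HOM_KO / INV_HET / INV_HOM / AMBIGUOUS
  from band patterns.
* **Allele simulation** — seeded synthetic loci with guaranteed guide sites,
  plus clone allele sets (deletion ± junction indels, inversions) at ploidy
  1–4, closing the loop for testing without any external data.
* **Quantification** — comparative-Ct fold changes (`2^−ΔΔCt`) and the
  flow-cytometry stain index `(mean_pos − mean_bg) / (2·SD_bg)`.

## Worked example

Generate a 5-kb synthetic locus with a 600-bp deletable element, design
guide pairs, and emit the cloning oligo and genotyping plan:

```python
from decko import *
from decko.genome_io import write_fasta, write_bed

target = GenomeRegion("chrS", 2200, 2800)
locus  = make_synthetic_locus(seed=7, length=5000, target=target, chrom="chrS")
write_fasta([locus], "genome.fasta")
write_bed([("promA", target)], "targets.bed")
```

```bash
decko design --genome genome.fasta --targets targets.bed --out out --seed 7
```

Top row of `out/design_report.tsv`:

```
target  rank  u6_protospacer        ...  u6_cut  h1_protospacer        h1_cut  deletion_start  deletion_end  deletion_len  pair_score
promA   1     GGTCCGAGAAGTTCAGCCTG  ...  2839    ATTGAGGCCACACTAGTCGA  2239    2239            2839          600           1.0
```

Both guides score 1.0 (no off-target neighbour within 3 mismatches in the
locus); their cuts at 2239 and 2839 delete 600 bp spanning the target.
`out/oligos.fasta` holds the 165-nt Insert-1 for this pair, and
`out/genotyping_plans.tsv` the expected amplicons:

```
name   deletion_len  expected_wt_bp  expected_ko_bp  expected_internal_bp  expected_inversion_bp
promA  600           760             160             360                   420
```

Note the arithmetic the classifier relies on: KO = WT − deletion length
(160 = 760 − 600). A clone showing bands 760 + 160 in PCR 1 and 360 in
PCR 2 is called heterozygous:

```bash
decko genotype --plan out/genotyping_plans.tsv --bands bands.tsv
# promA  HET  long=True;short=True;internal=True;inversion=False
```

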