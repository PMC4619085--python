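"""In-silico PCR, amplicon-plan arithmetic, the genotype truth table (checked
exhaustively against an independent oracle) and the closed loop from
simulated clone alleles back to their true genotype category."""

import itertools

import pytest

from decko.allele_sim import AlleleSpec, CloneSpec, apply_deletion
from decko.genome_io import reverse_complement
from decko.genotyping import (BandPattern, GenotypingError, GenotypingPlan,
                              PrimerSet, classify_evidence, classify_genotype,
                              in_silico_pcr, pick_primers, predict_amplicons,
                              simulate_bands)


class TestInSilicoPcr:
    def test_full_span_product(self):
        tmpl = "GATTACAGGCATCCATTCAG" + "C" * 260 + "TGCCGAATTGACTGGACTAC"
        fwd = tmpl[:20]
        rev = reverse_complement(tmpl[-20:])
        assert in_silico_pcr({"t": tmpl}, fwd, rev) == [("t", 300)]

    def test_same_strand_primers_give_nothing(self):
        tmpl = "GATTACAGGCATCCATTCAG" + "C" * 260 + "TGCCGAATTGACTGGACTAC"
        assert in_silico_pcr({"t": tmpl}, tmpl[:20], tmpl[-20:]) == []

    def test_swapped_primer_order_still_amplifies(self):
        tmpl = "GATTACAGGCATCCATTCAG" + "C" * 260 + "TGCCGAATTGACTGGACTAC"
        fwd = tmpl[:20]
        rev = reverse_complement(tmpl[-20:])
        assert in_silico_pcr({"t": tmpl}, rev, fwd) == [("t", 300)]

    def test_max_len_drops_long_products(self):
        tmpl = "GATTACAGGCATCCATTCAG" + "C" * 460 + "TGCCGAATTGACTGGACTAC"
        fwd, rev = tmpl[:20], reverse_complement(tmpl[-20:])
        assert in_silico_pcr({"t": tmpl}, fwd, rev, max_len=400) == []

    def test_short_primers_rejected(self):
        with pytest.raises(GenotypingError):
            in_silico_pcr({"t": "ACGT" * 30}, "ACGTACGT", "ACGTACGTACGTACGT")

    def test_deletion_allele_product_shrinks_by_deletion_len(
            self, fixture_locus, designed_pair, fixture_primers):
        wt = in_silico_pcr({"wt": fixture_locus.seq}, fixture_primers.ext_fwd,
                           fixture_primers.ext_rev)
        ko_seq = apply_deletion(fixture_locus, designed_pair,
                                AlleleSpec(kind="DEL"))
        ko = in_silico_pcr({"ko": ko_seq}, fixture_primers.ext_fwd,
                           fixture_primers.ext_rev)
        assert wt[0][1] - ko[0][1] == designed_pair.deletion_len


class TestPredictAmplicons:
    def test_ko_equals_wt_minus_deletion(self, fixture_plan, designed_pair):
        assert fixture_plan.ko_size == fixture_plan.wt_size - designed_pair.deletion_len

    def test_inversion_allele_wt_sized_in_pcr1(self, fixture_locus,
                                               designed_pair, fixture_primers):
        from decko.allele_sim import apply_inversion
        inv = apply_inversion(fixture_locus, designed_pair)
        prods = in_silico_pcr({"inv": inv}, fixture_primers.ext_fwd,
                              fixture_primers.ext_rev)
        wt = in_silico_pcr({"wt": fixture_locus.seq}, fixture_primers.ext_fwd,
                           fixture_primers.ext_rev)
        assert prods[0][1] == wt[0][1]

    def test_internal_primer_outside_deletion_errors(self, fixture_locus,
                                                     designed_pair,
                                                     fixture_primers):
        # Internal primer replaced by a site upstream of the deletion
        left = designed_pair.deletion.start
        outside = reverse_complement(fixture_locus.seq[left - 160:left - 140])
        bad = PrimerSet(ext_fwd=fixture_primers.ext_fwd,
                        ext_rev=fixture_primers.ext_rev, int_primer=outside)
        with pytest.raises(GenotypingError, match="int_primer"):
            predict_amplicons(fixture_locus, designed_pair, bad)


def oracle_truth_table(long, short, internal, inv):
    """Independent statement of the three-reaction decision rules."""
    if inv and internal:
        return "INV_HET"
    if inv and (short or long):
        return "INV_HOM"
    if inv:
        return "AMBIGUOUS"
    if long and internal and not short:
        return "WT"
    if long and short and internal:
        return "HET"
    if short and not long and not internal:
        return "HOM_KO"
    return "AMBIGUOUS"


class TestClassify:
    def test_all_evidence_combinations_match_oracle(self):
        for ev in itertools.product([False, True], repeat=4):
            assert classify_evidence(*ev) == oracle_truth_table(*ev)

    def test_het_from_worksheet_sizes(self):
        """Both flanking products plus an internal band: heterozygote."""
        plan = GenotypingPlan(name="MALAT1_A", deletion_len=112, wt_size=278,
                              ko_size=166, internal_size=150, inv_size=200)
        bands = BandPattern({"pcr1": (278, 166), "pcr2": (150,)})
        assert classify_genotype(plan, bands).category == "HET"

    def test_wt_call(self):
        plan = GenotypingPlan(name="x", deletion_len=112, wt_size=278,
                              ko_size=166, internal_size=150, inv_size=200)
        bands = BandPattern({"pcr1": (278,), "pcr2": (150,)})
        assert classify_genotype(plan, bands).category == "WT"

    def test_totality_on_garbage_bands(self):
        plan = GenotypingPlan(name="x", deletion_len=112, wt_size=278,
                              ko_size=166, internal_size=150, inv_size=200)
        call = classify_genotype(plan, BandPattern({"pcr1": (999, 1234)}))
        assert call.category == "AMBIGUOUS"

    def test_tolerance_window_matches_nearby_band(self):
        plan = GenotypingPlan(name="x", deletion_len=112, wt_size=278,
                              ko_size=166, internal_size=150, inv_size=200)
        bands = BandPattern({"pcr1": (285,), "pcr2": (155,)})  # within max(10, 5%)
        assert classify_genotype(plan, bands).category == "WT"

    def test_invalid_plan_rejected(self):
        with pytest.raises(GenotypingError):
            GenotypingPlan(name="x", deletion_len=10, wt_size=100,
                           ko_size=100, internal_size=50)


class TestClosedLoop:
    @pytest.mark.parametrize("ploidy", [2, 3])
    def test_every_allele_combination_recovered(self, ploidy, fixture_locus,
                                                designed_pair, fixture_primers,
                                                fixture_plan):
        """Simulated clones of every genotype classify back to their true
        category for ploidy 2 and 3 (exhaustive over WT/DEL/INV alleles)."""
        for kinds in itertools.product(("WT", "DEL", "INV"), repeat=ploidy):
            clone = CloneSpec(ploidy=ploidy, alleles=tuple(
                AlleleSpec(kind=k, seed=i) for i, k in enumerate(kinds)))
            bands = simulate_bands(fixture_locus, designed_pair,
                                   fixture_primers, clone)
            call = classify_genotype(fixture_plan, bands)
            assert call.category == clone.true_category, (kinds, bands.bands)

    def test_small_junction_indels_tolerated(self, fixture_locus, designed_pair,
                                             fixture_primers, fixture_plan):
        """Junction indels below the band tolerance do not change the call."""
        for indel in (-8, -3, 1, 5, 8):
            clone = CloneSpec(ploidy=2, alleles=(
                AlleleSpec(kind="WT"),
                AlleleSpec(kind="DEL", junction_indel=indel, seed=99)))
            bands = simulate_bands(fixture_locus, designed_pair,
                                   fixture_primers, clone)
            assert classify_genotype(fixture_plan, bands).category == "HET"


class TestPickPrimers:
    def test_picked_primers_are_unique_and_usable(self, fixture_locus,
                                                  designed_pair,
                                                  fixture_primers):
        seq = fixture_locus.seq
        for p in (fixture_primers.ext_fwd, fixture_primers.ext_rev,
                  fixture_primers.int_primer):
            assert seq.count(p) + seq.count(reverse_complement(p)) == 1

    def test_locus_too_short_errors(self, designed_pair):
        with pytest.raises(GenotypingError):
            pick_primers("ACGT" * 30, designed_pair)
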