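"""Insert-1 assembly/parsing round trips, BsmBI digestion arithmetic and the
two-step cloning simulation with its final-construct invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decko.genome_io import reverse_complement
from decko.oligo_assembly import (AssemblyError, CloningError, InsertTemplate,
                                  assemble_insert1, bsmbi_digest,
                                  default_template, load_template,
                                  parse_insert1, simulate_cloning)

TPL = default_template()
T_U6 = "GACCTACGGATCCTAGACCT"
T_H1 = "ATTGCCATGCAAGTCCAGAC"

safe_20mer = st.text(alphabet="ACGT", min_size=20, max_size=20).filter(
    lambda s: "CGTCTC" not in s and "GAGACG" not in s)


class TestTemplate:
    def test_default_constants_sum_to_125(self):
        assert TPL.constant_total == 125
        assert TPL.oligo_length() == 165

    def test_cassette_has_one_site_per_strand(self):
        assert TPL.bsmbi_cassette.count("CGTCTC") == 1
        assert TPL.bsmbi_cassette.count("GAGACG") == 1

    def test_other_segments_site_free(self):
        for seg in (TPL.gibson5, TPL.scaffold_frag, TPL.h1_frag, TPL.gibson3):
            assert "CGTCTC" not in seg and "GAGACG" not in seg

    def test_load_rejects_wrong_constant_total(self, tmp_path):
        p = tmp_path / "short.template"
        p.write_text(
            f"gibson5 = {TPL.gibson5}\nscaffold_frag = {TPL.scaffold_frag}\n"
            f"bsmbi_cassette = {TPL.bsmbi_cassette}\nh1_frag = AAC\n"
            f"gibson3 = {TPL.gibson3}\n")
        with pytest.raises(AssemblyError, match="sum"):
            load_template(p, expect_constant_total=125)

    def test_cassette_without_sites_rejected(self):
        with pytest.raises(AssemblyError):
            InsertTemplate(gibson5="ACGT", scaffold_frag="ACGT",
                           bsmbi_cassette="AAAACCCC", h1_frag="ACGT",
                           gibson3="ACGT")


class TestAssemble:
    def test_default_length_165(self):
        assert len(assemble_insert1(T_U6, T_H1, TPL)) == 165

    def test_round_trip(self):
        oligo = assemble_insert1(T_U6, T_H1, TPL)
        assert parse_insert1(oligo, TPL) == (T_U6, T_H1)

    def test_custom_template_length_additivity(self):
        short = InsertTemplate(gibson5=TPL.gibson5,
                               scaffold_frag=TPL.scaffold_frag,
                               bsmbi_cassette=TPL.bsmbi_cassette,
                               h1_frag=TPL.h1_frag[:-10], gibson3=TPL.gibson3)
        assert len(assemble_insert1(T_U6, T_H1, short)) == 155

    def test_revcomp_orientation_round_trips(self):
        tpl = InsertTemplate(gibson5=TPL.gibson5, scaffold_frag=TPL.scaffold_frag,
                             bsmbi_cassette=TPL.bsmbi_cassette,
                             h1_frag=TPL.h1_frag, gibson3=TPL.gibson3,
                             t2_orientation="revcomp")
        oligo = assemble_insert1(T_U6, T_H1, tpl)
        assert oligo.segment("grna2_target") == reverse_complement(T_H1)
        assert parse_insert1(oligo, tpl) == (T_U6, T_H1)

    @pytest.mark.parametrize("bad", ["ACGT", "GACCTACGGATCCTAGACCTA"])
    def test_wrong_length_refused(self, bad):
        with pytest.raises(AssemblyError, match="20"):
            assemble_insert1(bad, T_H1, TPL)

    def test_bsmbi_in_targeting_sequence_refused(self):
        with pytest.raises(AssemblyError, match="BsmBI"):
            assemble_insert1("GCGTCTCAAACCATTACCTA", T_H1, TPL)

    @given(safe_20mer, safe_20mer)
    @settings(max_examples=200, deadline=None)
    def test_round_trip_property(self, a, b):
        try:
            oligo = assemble_insert1(a, b, TPL)
        except AssemblyError:
            return  # junction-created BsmBI site: assembly correctly refuses
        assert len(oligo) == 165
        assert parse_insert1(oligo, TPL) == (a, b)


class TestParse:
    def test_mismatch_names_segment(self):
        oligo = assemble_insert1(T_U6, T_H1, TPL)
        mutated = ("A" if oligo.seq[0] != "A" else "C") + oligo.seq[1:]
        with pytest.raises(AssemblyError, match="gibson5"):
            parse_insert1(mutated, TPL)

    def test_truncated_oligo_length_error(self):
        oligo = assemble_insert1(T_U6, T_H1, TPL)
        with pytest.raises(AssemblyError, match="length"):
            parse_insert1(oligo.seq[:-5], TPL)


class TestBsmbiDigest:
    def test_linear_single_forward_site(self):
        # CGTCTC at [3,9): top cut at gap 10, 4-nt 5' overhang
        frags = bsmbi_digest("AAACGTCTCATTTTGGGCCC")
        assert [f.seq for f in frags] == ["AAACGTCTCA", "TTTTGGGCCC"]
        assert frags[1].left_overhang == "TTTT"
        assert frags[0].right_overhang == "TTTT"

    def test_no_site_returns_uncut(self):
        frags = bsmbi_digest("ACGTACGTACGTACGT")
        assert len(frags) == 1 and frags[0].left_overhang is None

    def test_reverse_site_mirror_arithmetic(self):
        # GAGACG at [10,16): bottom-strand site, top cut at gap 10-5=5
        seq = "AAAATTCCAAGAGACGTTTT"
        frags = bsmbi_digest(seq)
        assert [f.seq for f in frags] == [seq[:5], seq[5:]]
        assert frags[1].left_overhang == seq[5:9]

    def test_fragment_lengths_sum_to_input(self):
        oligo = assemble_insert1(T_U6, T_H1, TPL)
        frags = bsmbi_digest(oligo.seq)
        assert sum(len(f) for f in frags) == len(oligo)
        assert len(frags) == 3  # two sites in the cassette -> 3 linear fragments

    def test_circular_two_sites_two_fragments(self):
        oligo = assemble_insert1(T_U6, T_H1, TPL)
        frags = bsmbi_digest(oligo.seq, circular=True)
        assert len(frags) == 2
        assert sum(len(f) for f in frags) == len(oligo)


class TestSimulateCloning:
    def test_final_construct_invariants(self):
        final = simulate_cloning(T_U6, T_H1, TPL)
        assert final.stage == "final"
        assert final.bsmbi_site_count() == 0
        assert final.seq.count(T_U6) == 1
        assert final.seq.count(T_H1) == 1

    def test_final_element_order(self):
        final = simulate_cloning(T_U6, T_H1, TPL)
        assert final.element_names == ("U6_promoter", "gRNA1_target",
                                       "scaffold", "H1_promoter",
                                       "gRNA2_target", "scaffold")

    def test_targeting_sequences_downstream_of_promoters(self):
        final = simulate_cloning(T_U6, T_H1, TPL)
        names = list(final.element_names)
        assert names.index("gRNA1_target") == names.index("U6_promoter") + 1
        assert names.index("gRNA2_target") == names.index("H1_promoter") + 1

    def test_targeting_with_bsmbi_refused_before_cloning(self):
        with pytest.raises(AssemblyError):
            simulate_cloning("GCGTCTCAAACCATTACCTA", T_H1, TPL)

    def test_stray_backbone_site_is_hard_failure(self):
        # A backbone carrying an extra BsmBI site would leave a residual site.
        from decko.oligo_assembly import ConstructModel, make_parental_backbone
        bad = make_parental_backbone(TPL)
        bad = ConstructModel(stage="parental", elements=bad.elements +
                             (("stray", "AACGTCTCAA"),))
        with pytest.raises(CloningError):
            simulate_cloning(T_U6, T_H1, TPL, backbone=bad)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_pairs_yield_valid_constructs(self, seed):
        rng = np.random.default_rng(seed)
        a, b = ("".join(rng.choice(list("ACGT"), size=20)) for _ in range(2))
        try:
            final = simulate_cloning(a, b, TPL)
        except AssemblyError:
            return  # targeting sequence itself trips the BsmBI refusal
        assert final.bsmbi_site_count() == 0
        assert final.seq.count(a) == 1
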