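"""Barcode and construct design: rule checks against independent oracles."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from evscreen.errors import ConfigError, DesignError, ValidationError
from evscreen.sequence_design import (
    EXO_MOTIF,
    DesignConstraints,
    HairpinConfig,
    assemble_hairpin,
    assemble_mature,
    build_cassette,
    check_barcode,
    design_barcodes,
    make_mismatch_variants,
    min_pairwise_hamming,
)

from conftest import naive_barcode_ok, naive_min_pairwise_hamming, verify_barcode_set

dna = st.text(alphabet="ACGT", min_size=15, max_size=15)


class TestCheckBarcode:
    @pytest.mark.parametrize(
        "seq, reason",
        [
            ("AAAACGTGCATGCAT", "homopolymer"),
            ("ATATATATATATATA", "gc_content"),
            ("GAATTCGTACGTCAG", "forbidden_site"),  # EcoRI
            ("CAATTGGTACGTCAG", "forbidden_site"),  # MfeI
            ("GCTGAGCTACGTCAG", "forbidden_site"),  # BlpI via GCTNAGC
            ("ACGTACGTACGT", "length"),
            ("GGGGATATATATCGC", "homopolymer"),  # GC 6/15, run of 4 Gs
        ],
    )
    def test_rejections_carry_first_failed_rule(self, seq, reason):
        v = check_barcode(seq)
        assert not v and v.reason == reason

    def test_accepts_a_clean_barcode(self):
        v = check_barcode("ACGTCATGCAGTCAT")  # GC 7/15, max run 1
        assert v.accepted and v.reason is None

    def test_non_acgt_raises(self):
        with pytest.raises(DesignError):
            check_barcode("ACGTNATGCAGTCAT")

    @given(dna)
    def test_agrees_with_independent_rule_scan(self, seq):
        c = DesignConstraints()
        assert bool(check_barcode(seq, c)) == naive_barcode_ok(seq, c)

    def test_gc_boundaries_are_inclusive(self):
        # 6/15 = 0.40 and 9/15 = 0.60 exactly
        assert check_barcode("GCGCGCATATATATA").reason != "gc_content"  # 6 GC
        assert check_barcode("GCGCGCGCGTATATA").reason != "gc_content"  # 9 GC


class TestDesignBarcodes:
    def test_single_barcode(self, fast_constraints):
        bcs = design_barcodes(1, fast_constraints)
        assert len(bcs) == 1 and naive_barcode_ok(bcs[0], fast_constraints)

    def test_fifty_barcodes_pass_brute_force_verifier(self, fast_constraints):
        bcs = design_barcodes(50, fast_constraints)
        assert len(bcs) == 50
        verify_barcode_set(bcs, fast_constraints)
        assert naive_min_pairwise_hamming(list(bcs)) >= 4

    def test_reproducible_given_seed(self, fast_constraints):
        a = design_barcodes(100, fast_constraints)
        b = design_barcodes(100, fast_constraints)
        assert list(a) == list(b)

    def test_tightening_min_hamming_never_grows_the_set(self):
        sizes = []
        for h in (1, 4, 8):
            c = DesignConstraints(min_hamming=h, rng_seed=11, candidate_budget=4000)
            sizes.append(len(design_barcodes(None, c)))
        assert sizes == sorted(sizes, reverse=True)

    def test_partial_set_with_feasibility_report_on_tiny_budget(self):
        c = DesignConstraints(rng_seed=11, candidate_budget=50)
        bcs = design_barcodes(1000, c)
        assert len(bcs) < 1000
        assert not bcs.report.complete
        assert bcs.report.candidates_tried <= 50

    def test_invalid_n_rejected(self, fast_constraints):
        with pytest.raises(DesignError):
            design_barcodes(0, fast_constraints)

    def test_fast_min_hamming_matches_naive(self, fast_constraints):
        bcs = design_barcodes(40, fast_constraints)
        assert min_pairwise_hamming(list(bcs)) == naive_min_pairwise_hamming(list(bcs))

    def test_rc_strict_mode_also_separates_reverse_complements(self):
        c = DesignConstraints(rng_seed=2, candidate_budget=20_000, rc_hamming=True)
        bcs = design_barcodes(30, c)
        from evscreen._encoding import revcomp
        from conftest import naive_hamming
        for i, a in enumerate(bcs):
            for j, b in enumerate(bcs):
                if i != j:
                    assert naive_hamming(a, revcomp(b)) >= 4


class TestHairpins:
    def test_mature_is_barcode_plus_exo_motif(self):
        m = assemble_mature("ACGTCATGCAGTCAT")
        assert m == "ACGTCATGCAGTCATGGAGGAG" and len(m) == 22
        assert m.endswith(EXO_MOTIF)

    def test_empty_barcode_rejected(self):
        with pytest.raises(DesignError):
            assemble_mature("")

    def test_perfect_stem_is_exact_reverse_complement(self):
        hp = assemble_hairpin("ACGTCATGCAGTCAT")
        from evscreen._encoding import revcomp
        sense = hp.barcode + EXO_MOTIF
        assert revcomp(sense) in hp.full_sequence
        assert hp.full_sequence == (hp.context_5p + sense + hp.loop_seq
                                    + revcomp(sense) + hp.context_3p)

    @pytest.mark.parametrize("barcode, variant, sub", [
        ("ACGTCATGCAGTCAT", "AC", "C"),
        ("TCGTCATGCAGTCAA", "TC", "C"),
        ("GCGTCATGCAGTCAT", "GA", "A"),
        ("CAGTCATGCAGTCAT", "CA", "A"),
    ])
    def test_auto_variant_changes_exactly_the_stem_base_pair(self, barcode, variant, sub):
        from evscreen._encoding import revcomp
        (hp,) = make_mismatch_variants(barcode, "auto")
        assert hp.mismatch_variant == variant
        sense = barcode + EXO_MOTIF
        perfect = revcomp(sense)
        passenger_start = hp.full_sequence.index(hp.loop_seq) + len(hp.loop_seq)
        passenger = hp.full_sequence[passenger_start:passenger_start + len(sense)]
        diffs = [i for i, (a, b) in enumerate(zip(perfect, passenger)) if a != b]
        assert diffs == [len(sense) - 1] and passenger[-1] == sub

    def test_variant_never_changes_mature_sequence(self):
        for which in ("none", "auto"):
            (hp,) = make_mismatch_variants("GATCGATCGCAGTCA", which)
            assert hp.mature_sequence == "GATCGATCGCAGTCA" + EXO_MOTIF

    def test_both_doubles_the_library(self, fast_constraints):
        bcs = design_barcodes(20, fast_constraints)
        constructs = [hp for b in bcs for hp in make_mismatch_variants(b, "both")]
        assert len(constructs) == 40
        assert {hp.mature_sequence for hp in constructs} == {b + EXO_MOTIF for b in bcs}

    def test_incompatible_variant_rejected(self):
        with pytest.raises(DesignError):
            make_mismatch_variants("ACGTCATGCAGTCAT", ["GA"])

    def test_missing_loop_config_rejected(self):
        with pytest.raises(ConfigError):
            HairpinConfig(loop_seq="")


class TestCassette:
    def test_module_order_in_oligo(self):
        hp = assemble_hairpin("ACGTCATGCAGTCAT")
        cas = build_cassette("GTTTGCAGTCATCGATCGAT", hp)
        oligo = cas.full_oligo
        i_sg = oligo.index(cas.sgrna_seq)
        i_blp = oligo.index(cas.site_blpI, i_sg)
        i_eco = oligo.index(cas.site_ecoRI, i_blp)
        i_hp = oligo.index(hp.full_sequence)
        assert i_sg < i_blp < i_eco < i_hp

    def test_empty_flanks_give_minimal_oligo(self):
        hp = assemble_hairpin("ACGTCATGCAGTCAT")
        cas = build_cassette("GTTTGCAGTCATCGATCGAT", hp)
        assert cas.full_oligo == (cas.sgrna_seq + cas.site_blpI + cas.site_ecoRI
                                  + hp.full_sequence)

    def test_stray_internal_site_raises_in_strict_mode(self):
        hp = assemble_hairpin("ACGTCATGCAGTCAT",
                              HairpinConfig(loop_seq="GAATTCAA"))  # EcoRI inside loop
        with pytest.raises(ValidationError, match="EcoRI"):
            build_cassette("GTTTGCAGTCATCGATCGAT", hp, strict=True)
        cas = build_cassette("GTTTGCAGTCATCGATCGAT", hp, strict=False)
        assert any(name == "EcoRI" for name, _ in cas.stray_sites)

    def test_designated_sites_are_not_flagged(self):
        hp = assemble_hairpin("ACGTCATGCAGTCAT")
        cas = build_cassette("GTTTGCAGTCATCGATCGAT", hp, strict=True)
        assert cas.stray_sites == ()


class TestExport:
    def test_fasta_and_table_round_trip_construct_content(self, fast_constraints, tmp_path):
        from Bio import SeqIO
        from evscreen.sequence_design import constructs_to_frame, write_constructs_fasta

        bcs = design_barcodes(5, fast_constraints)
        constructs = {f"el{i}": make_mismatch_variants(b, "auto")[0]
                      for i, b in enumerate(bcs)}
        fa = tmp_path / "mature.fa"
        write_constructs_fasta(constructs, fa, which="mature")
        recs = {r.id: str(r.seq) for r in SeqIO.parse(str(fa), "fasta")}
        assert recs == {eid: hp.mature_sequence for eid, hp in constructs.items()}
        df = constructs_to_frame(constructs)
        assert list(df.columns) == ["element_id", "barcode", "mature", "hairpin", "variant"]
        assert (df["mature"].str.len() == 22).all()
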