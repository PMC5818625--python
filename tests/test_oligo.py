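"""Duplex chemistry model: parser, seed operations, design interventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from seedtox.oligo import (
    ModifiedNucleotide,
    OligoStrand,
    ParseError,
    SeedSpec,
    SiRNADuplex,
    extract_seed,
    mod_composition,
    parse_strand,
    place_gna,
    reverse_complement,
    seed_site,
    serialize_strand,
    set_cap,
    swap_seed,
)

from .conftest import make_duplex, random_duplex


class TestParser:
    @pytest.mark.parametrize(
        "text, n_res, checks",
        [
            ("mU*fU*mAfCmGfCmAfUmA", 9, {"sugars": ["2OMe", "2F"] * 4 + ["2OMe"],
                                          "ps_linkages": [0, 1]}),
            ("[iB]mUfUmA", 3, {"cap": "iB"}),
            ("mUfU(gna)AmC", 4, {"residue3": ("A", "GNA")}),
            ("AUGC", 4, {"sugars": ["ribo"] * 4}),
            ("mGfCmAfUmG*fC*mA[GalNAc]", 7, {"conjugate": "GalNAc"}),
        ],
    )
    def test_examples(self, text, n_res, checks):
        s = parse_strand(text)
        assert len(s.residues) == n_res
        if "sugars" in checks:
            assert [r.sugar for r in s.residues] == checks["sugars"]
        if "ps_linkages" in checks:
            ps = [i for i, r in enumerate(s.residues[:-1]) if r.linkage_3prime == "PS"]
            assert ps == checks["ps_linkages"]
        if "cap" in checks:
            assert s.cap_5prime == checks["cap"]
        if "conjugate" in checks:
            assert s.conjugate_3prime == checks["conjugate"]
        if "residue3" in checks:
            r = s.residues[2]
            assert (r.base, r.sugar) == checks["residue3"]

    @pytest.mark.parametrize(
        "bad",
        ["", "mU[iB]fU", "qU", "*mU", "mU**fA", "[GalNAc]mU", "[iB]", "m"],
    )
    def test_errors_name_token_and_position(self, bad):
        with pytest.raises(ParseError):
            parse_strand(bad)

    @given(
        hst.lists(
            hst.tuples(
                hst.sampled_from(["", "m", "f", "d", "l", "(gna)"]),
                hst.sampled_from("ACGU"),
                hst.booleans(),
            ),
            min_size=1,
            max_size=30,
        ),
        hst.sampled_from(["", "[iB]", "[mor]", "[5d]"]),
        hst.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_roundtrip_identity(self, tokens, cap, galnac):
        text = cap + "".join(
            f"{sugar}{base}{'*' if ps else ''}" for sugar, base, ps in tokens
        )
        if galnac:
            text += "[GalNAc]"
        strand = parse_strand(text)
        canonical = serialize_strand(strand)
        assert serialize_strand(parse_strand(canonical)) == canonical


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq, alphabet, expected",
        [("UACGCAU", "DNA", "ATGCGTA"), ("A", "RNA", "U"), ("AAAAAAA", "DNA", "TTTTTTT"),
         ("ATGN", "RNA", "NCAU")],
    )
    def test_examples(self, seq, alphabet, expected):
        assert reverse_complement(seq, alphabet) == expected

    @given(hst.text(alphabet="ACGTUN", min_size=1, max_size=60),
           hst.sampled_from(["RNA", "DNA"]))
    @settings(max_examples=200, deadline=None)
    def test_involution(self, seq, alphabet):
        rc = reverse_complement(seq, alphabet)
        rc2 = reverse_complement(rc, alphabet)
        # involution up to U/T spelling of the chosen alphabet
        canon = seq.replace("U", "T") if alphabet == "DNA" else seq.replace("T", "U")
        assert rc2 == canon

    def test_rejects_non_bases(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGQ")
        with pytest.raises(ValueError):
            reverse_complement("")


class TestSeedExtraction:
    def test_antisense_window(self, example_duplex):
        assert extract_seed(example_duplex, SeedSpec("antisense", 2, 8)) == "UACGCAU"

    def test_sense_window(self, example_duplex):
        expected = example_duplex.sense.bases[1:8]
        assert extract_seed(example_duplex, SeedSpec("sense", 2, 8)) == expected

    def test_window_out_of_range(self, example_duplex):
        with pytest.raises(ValueError):
            extract_seed(example_duplex, SeedSpec("antisense", 2, 25))

    def test_site_is_reverse_complement_dna(self, example_duplex):
        assert seed_site(example_duplex, SeedSpec("antisense", 2, 8)) == "ATGCGTA"

    def test_site_length_equals_window(self, rng):
        for _ in range(20):
            d = random_duplex(rng)
            start = int(rng.integers(1, 10))
            end = start + int(rng.integers(5, 9))
            spec = SeedSpec("antisense", start, end)
            assert len(seed_site(d, spec)) == end - start + 1


class TestSwapSeed:
    def test_bases_and_pairing_updated(self, example_duplex):
        donor = make_duplex("AGGGGGGGCCAUAGUCAAGAA")
        swapped = swap_seed(example_duplex, donor)
        assert extract_seed(swapped, SeedSpec()) == "GGGGGGG"
        p = swapped.paired_length
        for i in range(2, 9):
            assert swapped.sense.bases[p - i] == "C"

    def test_base_level_involution(self, example_duplex):
        donor = make_duplex("AGCUAGCUAGCAUAGUCAAGA")
        back = swap_seed(swap_seed(example_duplex, donor), example_duplex)
        assert back.antisense.bases == example_duplex.antisense.bases
        assert back.sense.bases == example_duplex.sense.bases

    def test_modification_pattern_untouched(self, example_duplex):
        donor = make_duplex("AGCUAGCUAGCAUAGUCAAGA")
        swapped = swap_seed(example_duplex, donor)
        for before, after in zip(
            example_duplex.antisense.residues, swapped.antisense.residues
        ):
            assert (before.sugar, before.linkage_3prime) == (after.sugar, after.linkage_3prime)
        assert swapped.antisense.cap_5prime == example_duplex.antisense.cap_5prime
        assert swapped.sense.conjugate_3prime == example_duplex.sense.conjugate_3prime

    def test_sense_strand_spec_rejected(self, example_duplex):
        with pytest.raises(ValueError):
            swap_seed(example_duplex, example_duplex, SeedSpec("sense", 2, 8))


class TestPlaceGNA:
    def test_position_seven(self, example_duplex):
        modified = place_gna(example_duplex, 7)
        r = modified.antisense.residues[6]
        assert r.sugar == "GNA"
        assert r.base == example_duplex.antisense.residues[6].base

    def test_seed_bases_unchanged(self, example_duplex):
        assert extract_seed(place_gna(example_duplex, 7), SeedSpec()) == "UACGCAU"

    @pytest.mark.parametrize("pos", [0, -1, 22])
    def test_out_of_range(self, example_duplex, pos):
        with pytest.raises(ValueError):
            place_gna(example_duplex, pos)


class TestSetCap:
    def test_antisense_cap_blocks_risc_loading(self, example_duplex):
        assert example_duplex.risc_loading_competent
        capped = set_cap(example_duplex, "antisense", "iB")
        assert not capped.risc_loading_competent

    def test_sense_cap_alone_leaves_competence(self, example_duplex):
        capped = set_cap(example_duplex, "sense", "iB")
        assert capped.risc_loading_competent

    def test_uncapping_restores_competence(self, example_duplex):
        capped = set_cap(example_duplex, "antisense", "morpholino")
        assert set_cap(capped, "antisense", "none").risc_loading_competent

    def test_unknown_cap_symbol(self, example_duplex):
        with pytest.raises(ValueError):
            set_cap(example_duplex, "antisense", "weird")


class TestModComposition:
    def test_even_split(self):
        s = parse_strand("mAfCmGfUmAfCmGfUmAfC")
        comp = mod_composition(s)
        assert comp.percent == pytest.approx({"2OMe": 50.0, "2F": 50.0})

    def test_all_ome(self):
        comp = mod_composition(parse_strand("mAmCmGmU" * 3))
        assert comp.percent == pytest.approx({"2OMe": 100.0})

    def test_21mer_with_four_2f(self):
        text = "fA" + "mC" * 10 + "fG" + "mU" * 6 + "fAfC" + "mG"
        s = parse_strand(text)
        assert len(s.residues) == 21
        comp = mod_composition(s)
        assert comp.percent["2F"] == pytest.approx(400 / 21)

    def test_percentages_sum_to_100_and_cap_invariant(self, rng):
        for _ in range(50):
            d = random_duplex(rng)
            comp = mod_composition(d.antisense)
            assert sum(comp.percent.values()) == pytest.approx(100.0, abs=1e-9)
            capped = set_cap(d, "antisense", "iB")
            assert mod_composition(capped.antisense).percent == comp.percent


class TestDuplexInvariants:
    def test_non_complementary_rejected(self):
        with pytest.raises(ValueError):
            SiRNADuplex(
                antisense=parse_strand("AAAAAAAAAA"),
                sense=parse_strand("AAAAAAAAAA"),
                overhang_length=2,
            )

    def test_u_t_equivalence_in_pairing(self):
        # DNA-style T on the sense strand pairs antisense A
        d = SiRNADuplex(
            antisense=parse_strand("AAAAGGGG"),
            sense=parse_strand("CCCCTTTT"),
            overhang_length=0,
        )
        assert d.paired_length == 8

    def test_complementarity_preserved_by_design_ops(self, rng):
        # constructing SiRNADuplex re-validates pairing, so surviving
        # construction after each op is the invariant
        for _ in range(200):
            d = random_duplex(rng)
            donor = random_duplex(rng)
            swapped = swap_seed(d, donor)
            assert isinstance(swapped, SiRNADuplex)
            pos = int(rng.integers(1, len(d.antisense) + 1))
            assert isinstance(place_gna(d, pos), SiRNADuplex)
            assert isinstance(set_cap(d, "sense", "5deoxy"), SiRNADuplex)

    def test_abasic_only_terminal(self):
        with pytest.raises(ValueError):
            OligoStrand(
                tuple(ModifiedNucleotide(b) for b in "AXA"),
            )
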