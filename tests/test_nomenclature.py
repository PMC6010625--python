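"""CE-compatible naming, length-based naming and designation round-trips."""

import numpy as np
import pytest

from ystrmps.decompose import decompose_array
from ystrmps.nomenclature import (
    NamingError,
    ce_name,
    length_based_name,
    mps_name,
    name_allele,
    parse_flank_descriptor,
    parse_mps_name,
)
from ystrmps.simulate import random_legal_vector


def from_designation(catalog, locus_name, designation):
    return parse_mps_name(designation, catalog[locus_name]), catalog[locus_name]


class TestUncountedBlockRules:
    @pytest.mark.parametrize("designation, expected", [
        ("CE15_AAGG[5]GAAA[16]", "15"),   # n-1
        ("CE18_AAGG[7]GAAA[17]", "18"),   # n+1
        ("CE16_AAGG[8]GAAA[14]", "16"),   # n+2
        ("CE14_AAGG[6]GAAA[14]", "14"),   # canonical
    ])
    def test_dys385_aagg_shifts(self, catalog, designation, expected):
        d, locus = from_designation(catalog, "DYS385a,b", designation)
        assert ce_name(d, locus) == expected
        assert length_based_name(d, locus) == expected

    @pytest.mark.parametrize("designation, expected", [
        ("CE27_CTG[0]CTT[28]", "27"),
        ("CE21_CTG[2]CTT[20]", "21"),
        ("CE23_CTG[1]CTT[23]", "23"),
    ])
    def test_dys481_ctg_shifts(self, catalog, designation, expected):
        d, locus = from_designation(catalog, "DYS481", designation)
        assert ce_name(d, locus) == expected

    def test_dys390_trailing_taga(self, catalog):
        d, locus = from_designation(
            catalog, "DYS390", "CE24_TAGA[4]CAGA[1]TAGA[10]CAGA[10]TAGA[1]")
        assert ce_name(d, locus) == "24"

    def test_dys19_ccta_absent_is_a_plus_b_minus_1(self, catalog):
        locus = catalog["DYS19"]
        d = decompose_array("TCTA" * 13, locus)
        assert ce_name(d, locus) == "12"
        # with the ccta present, no shift
        d2 = decompose_array("TCTA" * 10 + "CCTA" + "TCTA" * 3, locus)
        assert ce_name(d2, locus) == "13"

    def test_intermediate_allele_partial_residue(self, catalog):
        d, locus = from_designation(
            catalog, "DYS448", "CE20.4_AGAGAT[3]AGAT[1]AGAGAT[9]N[42]AGAGAT[8]")
        assert ce_name(d, locus) == "20.4"

    def test_nonpositive_name_rejected(self, catalog):
        locus = catalog["DYS481"]
        d = decompose_array("CTT" * 1, locus)
        with pytest.raises(NamingError):
            ce_name(d, locus)


class TestLengthBasedName:
    def test_reference_alleles_name_reference_ce(self, catalog):
        for locus in catalog:
            d = locus.reference_allele()
            assert length_based_name(d, locus) == str(locus.reference_ce)
            assert ce_name(d, locus) == str(locus.reference_ce)

    def test_depends_only_on_length(self, catalog):
        """Isometric DYS635 alleles share the length-based name but have
        distinct designations."""
        locus = catalog["DYS635"]
        a = decompose_array(locus.render_array((10, 2, 2, 2, 2, 2, 3)), locus)
        b = decompose_array(locus.render_array((13, 2, 2, 2, 4, 0, 0)), locus)
        assert a.array_length == b.array_length
        assert length_based_name(a, locus) == length_based_name(b, locus) == "23"
        assert mps_name(a, locus) != mps_name(b, locus)

    def test_flanking_indels_shift_length_name_only(self, catalog):
        """A flanking indel changes what CE measures but not the structural
        name (the published .1-style discordance mechanism)."""
        d, locus = from_designation(
            catalog, "DYS576", "CE17.1_AAAG[18]_+3AAA>-")
        assert ce_name(d, locus) == "18"
        assert length_based_name(d, locus) == "17.1"
        d2, locus2 = from_designation(
            catalog, "DYS533", "CE14.1_TATC[11]_-48.1->CTCTTCTAACTAT")
        assert ce_name(d2, locus2) == "11"
        assert length_based_name(d2, locus2) == "14.1"

    def test_ce_equals_length_based_without_flank_indels(self, catalog, rng):
        """Compatibility requirement: for every catalogue-legal allele the
        structural CE name equals the length a CE instrument would report."""
        for locus in catalog:
            for _ in range(40):
                vec = random_legal_vector(locus, rng)
                d = decompose_array(locus.render_array(vec), locus)
                assert ce_name(d, locus) == length_based_name(d, locus), \
                    (locus.name, vec)


class TestDesignationRoundTrip:
    def test_mps_name_parses_back(self, catalog, rng):
        for locus in catalog:
            for _ in range(15):
                vec = random_legal_vector(locus, rng)
                d = decompose_array(locus.render_array(vec), locus)
                name = mps_name(d, locus)
                d2 = parse_mps_name(name, locus)
                assert d2.units == d.units
                assert mps_name(d2, locus) == name

    def test_flank_descriptor_parsing(self):
        v = parse_flank_descriptor("+50C>A")
        assert (v.offset, v.kind, v.ref, v.alt) == (50, "snp", "C", "A")
        v = parse_flank_descriptor("-7A>G")
        assert (v.offset, v.kind) == (-7, "snp")
        v = parse_flank_descriptor("+3AAA>-")
        assert (v.offset, v.kind, v.ref) == (3, "del", "AAA")
        v = parse_flank_descriptor("-48.1->CTCTTCTAACTAT")
        assert (v.offset, v.kind, v.alt) == (-48, "ins", "CTCTTCTAACTAT")
        # unicode minus accepted
        v = parse_flank_descriptor("−7A>G")
        assert v.offset == -7

    def test_name_allele_bundle(self, catalog):
        locus = catalog["DYS643"]
        d = parse_mps_name("CE11_CTTTT[11]_-7A>G", locus)
        nm = name_allele(d, locus)
        assert (nm.ce, nm.length_based) == ("11", "11")
        assert nm.mps == "CE11_CTTTT[11]_-7A>G"
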