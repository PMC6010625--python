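"""Repeat-array decomposition: parsing, localisation, flank variant calling."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from ystrmps.catalog import load_catalog
from ystrmps.decompose import (
    DecompositionError,
    FlankVariant,
    LocateError,
    decompose,
    decompose_array,
    locate_array,
    render_allele,
)
from ystrmps.simulate import random_legal_vector


def units_of(d):
    return [(u.seq, u.count, u.role) for u in d.units]


class TestLocateArray:
    def test_reference_allele_interval(self, catalog):
        locus = catalog["DYS391"]
        seq = render_allele(locus, "TCTA" * 9)
        loc = locate_array(seq, locus)
        assert loc.array_end - loc.array_start == 36
        assert seq[loc.array_start:loc.array_end] == "TCTA" * 9

    def test_missing_downstream_anchor_names_side(self, catalog):
        locus = catalog["DYS391"]
        seq = locus.upstream_flank + "TCTA" * 9 + "GGGGCCCCGGGGCCCCGGGGCCCC"
        with pytest.raises(LocateError, match="downstream"):
            locate_array(seq, locus)

    def test_located_despite_13bp_flank_insertion(self, catalog):
        locus = catalog["DYS533"]
        seq = render_allele(locus, "TATC" * 11,
                            [FlankVariant(offset=-48, kind="ins", ref="-",
                                          alt="CTCTTCTAACTAT")])
        loc = locate_array(seq, locus)
        assert seq[loc.array_start:loc.array_end] == "TATC" * 11

    def test_duplicated_anchor_rejected(self, catalog):
        locus = catalog["DYS391"]
        anchor = locus.upstream_flank[-10:]
        seq = anchor + render_allele(locus, "TCTA" * 9)
        with pytest.raises(LocateError, match="upstream"):
            locate_array(seq, locus)


class TestDecomposeArray:
    def test_internal_snp_as_variant_unit(self, catalog):
        d = decompose_array("GAAA" * 13 + "GGAA", catalog["DYS458"])
        assert units_of(d) == [("GAAA", 13, "repeat"), ("GGAA", 1, "variant")]

    def test_partial_unit_intermediate_allele(self, catalog):
        d = decompose_array("GAAA" * 15 + "AA" + "GAAA" * 2, catalog["DYS458"])
        assert units_of(d) == [("GAAA", 15, "repeat"), ("AA", 1, "partial"),
                               ("GAAA", 2, "repeat")]
        assert d.partial_length == 2

    def test_uncounted_leading_block_absent(self, catalog):
        locus = catalog["DYS481"]
        d = decompose_array("CTT" * 28, locus)
        assert d.effective_block_counts(locus) == (0, 28)

    def test_backtracking_on_recurrent_motif(self, catalog):
        """A trailing TCTG[2] after the TCTG block requires backtracking."""
        arr = "TCTA" * 6 + "TCTG" + "TCTA" * 3 + "TCTG" * 2 + "TCTA" * 4
        d = decompose_array(arr, catalog["DYS437"])
        assert d.render() == arr

    def test_spacer_parsed_as_single_unit(self, catalog):
        locus = catalog["DYS448"]
        spacer = next(b.motif for b in locus.blocks if b.fixed_spacer)
        d = decompose_array("AGAGAT" * 12 + spacer + "AGAGAT" * 7, locus)
        assert [(u.role, u.count) for u in d.units] == [
            ("repeat", 12), ("spacer", 1), ("repeat", 7)]

    def test_unparseable_residue_reports_position(self, catalog):
        with pytest.raises(DecompositionError, match="position"):
            decompose_array("TCTA" * 5 + "GGCGGCGG", catalog["DYS391"])

    def test_deterministic(self, catalog):
        arr = "TAGA" * 9 + "CAGA" + "TAGA" + "TACA" * 2 + "TAGA" * 2 + "TACA" * 2 + "TAGA" * 4
        a = decompose_array(arr, catalog["DYS635"])
        b = decompose_array(arr, catalog["DYS635"])
        assert a == b

    def test_variant_units_are_one_substitution_from_motifs(self, catalog, rng):
        """Parser invariant: every variant unit differs from a catalogue motif
        by exactly one substitution; every partial unit is sub-period."""
        for locus in catalog:
            for _ in range(20):
                vec = random_legal_vector(locus, rng)
                d = decompose_array(locus.render_array(vec), locus)
                for u in d.units:
                    if u.role == "variant":
                        assert any(
                            len(u.seq) == len(m)
                            and sum(a != b for a, b in zip(u.seq, m)) == 1
                            for m in locus.motifs)
                    elif u.role == "partial":
                        assert len(u.seq) < locus.period


class TestRoundTrip:
    def test_render_decompose_identity_random_alleles(self, catalog, rng):
        """render(decompose(s)) == s and block counts survive for random
        catalogue-legal alleles of every locus."""
        for locus in catalog:
            for _ in range(50):
                vec = random_legal_vector(locus, rng)
                arr = locus.render_array(vec)
                d = decompose_array(arr, locus)
                assert d.render() == arr
                got = tuple(
                    n for b, n in zip(locus.blocks, d.block_counts(locus))
                    if not b.fixed_spacer)
                want = tuple(
                    n for b, n in zip(locus.blocks, vec) if not b.fixed_spacer)
                assert got == want, (locus.name, vec)


_HYPO_CATALOG = None


def _hypo_catalog():
    global _HYPO_CATALOG
    if _HYPO_CATALOG is None:
        _HYPO_CATALOG = load_catalog()
    return _HYPO_CATALOG


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_round_trip_property_over_block_count_space(data):
    """Any in-range combination of block copy numbers (with unambiguous
    zero-block placement) renders to a sequence the parser inverts exactly."""
    from ystrmps.simulate import _legal_vector

    cat = _hypo_catalog()
    locus = cat[data.draw(st.sampled_from(cat.names))]
    vec = tuple(
        1 if b.fixed_spacer
        else data.draw(st.integers(b.min_repeats, b.max_repeats))
        for b in locus.blocks)
    assume(_legal_vector(locus, vec))
    arr = locus.render_array(vec)
    d = decompose_array(arr, locus)
    assert d.render() == arr
    got = tuple(n for b, n in zip(locus.blocks, d.block_counts(locus))
                if not b.fixed_spacer)
    want = tuple(n for b, n in zip(locus.blocks, vec) if not b.fixed_spacer)
    assert got == want


class TestFlankVariants:
    @pytest.mark.parametrize("locus_name, array, variant", [
        ("DYS391", "TCTA" * 8, FlankVariant(offset=50, kind="snp", ref="C", alt="A")),
        ("DYS576", "AAAG" * 18, FlankVariant(offset=3, kind="del", ref="AAA", alt="-")),
        ("DYS533", "TATC" * 11,
         FlankVariant(offset=-48, kind="ins", ref="-", alt="CTCTTCTAACTAT")),
        ("DYS438", "TTTTC" * 11, FlankVariant(offset=7, kind="snp", ref="A", alt="C")),
        ("DYS643", "CTTTT" * 11, FlankVariant(offset=-7, kind="snp", ref="A", alt="G")),
    ])
    def test_apply_then_call_recovers_descriptor(self, catalog, locus_name,
                                                 array, variant):
        locus = catalog[locus_name]
        d = decompose(render_allele(locus, array, [variant]), locus)
        assert [v.descriptor for v in d.flank_variants] == [variant.descriptor]
        assert d.render() == array

    def test_reference_flanks_give_no_variants(self, catalog):
        locus = catalog["DYS391"]
        d = decompose(render_allele(locus, "TCTA" * 11), locus)
        assert d.flank_variants == ()

    def test_known_variant_annotation(self, catalog):
        locus = catalog["DYS391"]
        seq = render_allele(locus, "TCTA" * 8,
                            [FlankVariant(offset=50, kind="snp", ref="C", alt="A")])
        v = decompose(seq, locus).flank_variants[0]
        assert v.rs_id == "rs112815242"
        assert v.genomic_position == 11_982_182

    def test_mobility_shift_flag_from_catalogue(self, catalog):
        locus = catalog["DYS481"]
        seq = render_allele(locus, "CTG" + "CTT" * 22,
                            [FlankVariant(offset=-20, kind="snp", ref="C", alt="T")])
        v = decompose(seq, locus).flank_variants[0]
        assert v.rs_id == "rs368663163" and v.mobility_shift

    def test_two_snps_same_flank(self, catalog):
        locus = catalog["DYS438"]
        vs = [FlankVariant(offset=7, kind="snp", ref="A", alt="C"),
              FlankVariant(offset=21, kind="snp", ref="T", alt="C")]
        d = decompose(render_allele(locus, "TTTTC" * 10, vs), locus)
        assert [v.descriptor for v in d.flank_variants] == ["+7A>C", "+21T>C"]
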