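"""Worked-example fixtures: printed designations, a 100-leaf reference-style
phylogeny, and a full 100-sample survey profile with known summary structure.

Everything here is generated programmatically from the locus catalogue — no
sequencing data is shipped. The fixtures serve as golden inputs for the
nomenclature, concordance, summary and phylogenetic-classification layers:

* ``table3_cases`` — 60 novel sequence-variant designations (the published
  novelty table), each rendered to full amplicon DNA and re-parseable.
* ``table4_cases`` — canonical/variant naming cases for the uncounted-block
  rules of DYS385a,b, DYS481 and DYS390.
* ``reference_tree`` — a 100-leaf haplogroup-labelled phylogeny with the
  documented carrier patterns (DYS635 RPV in the 15 superhaplogroup-P
  samples, DYS389II CAGA[6]/CAGA[4], DYS481 CTG[0]/CTG[2], DYS391 +50C>A in
  haplogroup B2, DYS393 internal SNP in R1a).
* ``survey_profile`` — a 2311-allele profile over 100 samples whose
  per-locus distinct-allele counts reproduce the published diversity table
  (169 length-based vs 267 sequence-based alleles, 60 novel variants), with
  a CE companion profile containing exactly 4 discordant alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import Catalog, LocusDefinition
from .decompose import Decomposition, decompose
from .nomenclature import designation_to_sequence, split_designation

# --------------------------------------------------------------------------- #
# printed designations (normalised unit rendering, ASCII minus)
# --------------------------------------------------------------------------- #

#: the 60 novel sequence variants: (locus, designation, expected CE name)
TABLE3: tuple[tuple[str, str, str], ...] = (
    ("DYS19", "CE12_TCTA[13]CCTA[0]", "12"),
    ("DYS385a,b", "CE9_AAGG[5]GAAA[10]", "9"),
    ("DYS385a,b", "CE13_AAGG[5]GAAA[14]", "13"),
    ("DYS385a,b", "CE15_AAGG[5]GAAA[16]", "15"),
    ("DYS385a,b", "CE15_AAGG[8]GAAA[13]", "15"),
    ("DYS385a,b", "CE16_AAGG[8]GAAA[14]", "16"),
    ("DYS385a,b", "CE17_AAGG[5]GAAA[18]", "17"),
    ("DYS385a,b", "CE18_AAGG[7]GAAA[17]", "18"),
    ("DYS389II", "CE30_TAGA[11]CAGA[2]N[48]TAGA[13]CAGA[4]", "30"),
    ("DYS389II", "CE30_TAGA[9]CAGA[3]N[48]TAGA[12]CAGA[6]", "30"),
    ("DYS389II", "CE31_TAGA[10]CAGA[3]N[48]TAGA[11]CAGA[1]TAGA[1]CAGA[5]", "31"),
    ("DYS389II", "CE34_TAGA[10]CAGA[3]N[48]TAGA[15]CAGA[6]", "34"),
    ("DYS390", "CE22_TAGA[14]CAGA[8]TAGA[2]TAGA[0]", "22"),
    ("DYS390", "CE23_TAGA[5]CAGA[1]TAGA[9]CAGA[8]TAGA[2]", "23"),
    ("DYS390", "CE24_TAGA[4]CAGA[1]TAGA[10]CAGA[10]TAGA[1]", "24"),
    ("DYS390", "CE24_TAGA[4]CAGA[1]TAGA[11]CAGA[7]TAGA[3]", "24"),
    ("DYS390", "CE24_TAGA[4]CAGA[1]TAGA[11]CAGA[8]TAGA[1]GAGA[1]", "24"),
    ("DYS390", "CE26_TAGA[4]CAGA[1]TAGA[12]CAGA[9]TAGA[2]", "26"),
    ("DYS391", "CE8_TCTA[8]_+50C>A", "8"),
    ("DYS391", "CE9_TCTA[9]_+50C>A", "9"),
    ("DYS391", "CE10_TCTA[10]_+50C>A", "10"),
    ("DYS391", "CE11_TCTA[11]_+50C>A", "11"),
    ("DYS391", "CE11_TCTG[1]TCTA[10]", "11"),
    ("DYS391", "CE12_TCTA[12]_+50C>A", "12"),
    ("DYS437", "CE15_TCTG[1]TCTA[8]TCTG[2]TCTA[4]", "15"),
    ("DYS437", "CE16_TCTA[6]TCTG[1]TCTA[3]TCTG[2]TCTA[4]", "16"),
    ("DYS438", "CE8_TTTTC[8]_+21T>C", "8"),
    ("DYS438", "CE11_TTTTC[11]_+7A>C", "11"),
    ("DYS439", "CE11_GATA[11]_+3A>T", "11"),
    ("DYS448", "CE13_AGAGAT[5]N[42]AGAGAT[8]", "13"),
    ("DYS448", "CE19_AGAGAT[13]N[42]AGAGAT[6]", "19"),
    ("DYS448", "CE20.4_AGAGAT[3]AGAT[1]AGAGAT[9]N[42]AGAGAT[8]", "20.4"),
    ("DYS448", "CE23_AGAGAT[14]N[42]AGAGAT[9]", "23"),
    ("DYS448", "CE23_AGAGAT[15]N[42]AGAGAT[8]", "23"),
    ("DYS458", "CE14_GAAA[13]GGAA[1]", "14"),
    ("DYS458", "CE15_GAAA[14]GGAA[1]", "15"),
    ("DYS458", "CE16_GAAA[15]GGAA[1]", "16"),
    ("DYS458", "CE17_GAAA[17]_+32T>C", "17"),
    ("DYS458", "CE17.2_GAAA[15]AA[1]GAAA[2]", "17.2"),
    ("DYS458", "CE19_GAAA[19]_+32T>C", "19"),
    ("DYS458", "CE19_GAAG[1]GAAA[18]", "19"),
    ("DYS458", "CE19.2_GAAA[17]AA[1]GAAA[2]", "19.2"),
    ("DYS458", "CE20_GAAA[19]GGAA[1]", "20"),
    ("DYS481", "CE26_CTG[0]CTT[27]", "26"),
    ("DYS481", "CE27_CTG[0]CTT[28]", "27"),
    ("DYS481", "CE28_CTG[1]CTT[3]CCT[1]CTT[24]", "28"),
    ("DYS533", "CE14.1_TATC[11]_-48.1->CTCTTCTAACTAT", "14.1"),
    ("DYS533", "CE15_TATC[15]", "15"),
    ("DYS570", "CE16_TTTC[16]_+4T>G", "16"),
    ("DYS570", "CE17_TTCC[1]TTTC[16]", "17"),
    ("DYS570", "CE17_TTTC[15]CTTC[1]TTTC[1]", "17"),
    ("DYS570", "CE19_TTTC[5]TCTC[1]TTTC[13]", "19"),
    ("DYS576", "CE17.1_AAAG[18]_+3AAA>-", "17.1"),
    ("DYS635", "CE18_TAGA[8]TACA[2]TAGA[2]TACA[2]TAGA[4]", "18"),
    ("DYS635", "CE20_TAGA[8]CAGA[1]TAGA[1]TACA[2]TAGA[2]TACA[2]TAGA[4]", "20"),
    ("DYS635", "CE21_TAGA[9]CAGA[1]TAGA[1]TACA[2]TAGA[2]TACA[2]TAGA[4]", "21"),
    ("DYS635", "CE25_TAGA[14]TACA[3]TAGA[2]TACA[2]TAGA[4]", "25"),
    ("DYS643", "CE11_CTTTT[11]_-7A>G", "11"),
    ("DYS643", "CE15_CTTTT[15]", "15"),
    ("Y-GATA-H4", "CE13_TCTA[13]_+36A>G", "13"),
)

#: canonical/variant uncounted-block naming cases: (locus, designation, CE)
TABLE4: tuple[tuple[str, str, str], ...] = (
    ("DYS385a,b", "CE11_AAGG[6]GAAA[11]", "11"),
    ("DYS385a,b", "CE14_AAGG[6]GAAA[14]", "14"),
    ("DYS385a,b", "CE10_AAGG[6]GAAA[10]", "10"),
    ("DYS385a,b", "CE15_AAGG[5]GAAA[16]", "15"),
    ("DYS385a,b", "CE17_AAGG[5]GAAA[18]", "17"),
    ("DYS385a,b", "CE18_AAGG[7]GAAA[17]", "18"),
    ("DYS385a,b", "CE15_AAGG[8]GAAA[13]", "15"),
    ("DYS385a,b", "CE16_AAGG[8]GAAA[14]", "16"),
    ("DYS481", "CE23_CTG[1]CTT[23]", "23"),
    ("DYS481", "CE21_CTG[2]CTT[20]", "21"),
    ("DYS481", "CE27_CTG[0]CTT[28]", "27"),
    ("DYS390", "CE24_TAGA[4]CAGA[1]TAGA[11]CAGA[8]TAGA[2]", "24"),
    ("DYS390", "CE24_TAGA[4]CAGA[1]TAGA[10]CAGA[10]TAGA[1]", "24"),
    ("DYS390", "CE24_TAGA[4]CAGA[1]TAGA[11]CAGA[7]TAGA[3]", "24"),
)


@dataclass(frozen=True)
class WorkedCase:
    """A printed designation rendered to DNA with its expected names."""

    locus: str
    designation: str
    expected_ce: str
    sequence: str
    decomposition: Decomposition

    @property
    def expected_prefix(self) -> str:
        return split_designation(self.designation)[0]


def _build_cases(rows, catalog: Catalog) -> list[WorkedCase]:
    out = []
    for locus_name, designation, expected in rows:
        locus = catalog[locus_name]
        seq = designation_to_sequence(designation, locus)
        out.append(WorkedCase(
            locus=locus.name,
            designation=designation,
            expected_ce=expected,
            sequence=seq,
            decomposition=decompose(seq, locus),
        ))
    return out


def table3_cases(catalog: Catalog) -> list[WorkedCase]:
    """The 60 published novel designations as renderable worked cases."""
    return _build_cases(TABLE3, catalog)


def table4_cases(catalog: Catalog) -> list[WorkedCase]:
    """Canonical/variant naming cases for the uncounted-block loci."""
    return _build_cases(TABLE4, catalog)


# --------------------------------------------------------------------------- #
# reference-style 100-leaf phylogeny with documented carrier patterns
# --------------------------------------------------------------------------- #
_CLADE_SIZES = (
    ("A", 6), ("B2", 5), ("B2b", 4), ("C", 7), ("D", 6), ("E", 14),
    ("G2a", 3), ("H", 5), ("I", 6), ("J", 10), ("L", 5), ("T", 5),
    ("N", 4), ("O", 5), ("Q", 4), ("Q1a", 1), ("R1a", 4), ("R1b", 5), ("R2", 1),
)


def _leaf_names(label: str) -> list[str]:
    n = dict(_CLADE_SIZES)[label]
    return [f"{label}-{i + 1:02d}" for i in range(n)]


def _balanced(leaves: list[str]) -> str:
    if len(leaves) == 1:
        return leaves[0]
    mid = len(leaves) // 2
    return f"({_balanced(leaves[:mid])},{_balanced(leaves[mid:])})"


def _clade(label: str) -> str:
    return _balanced(_leaf_names(label))


@dataclass(frozen=True)
class ReferenceTreeFixture:
    tree: "SampleTree"
    carriers: dict[str, frozenset]


def reference_tree() -> ReferenceTreeFixture:
    """A 100-leaf haplogroup-labelled phylogeny carrying the documented
    variant patterns: the DYS635 RPV private to the 15 superhaplogroup-P
    samples, DYS389II CAGA[6] private to the 14 haplogroup-E samples and
    CAGA[4] in the 14 T/O/N samples plus sporadic others, the DYS391
    flanking SNP in all 9 haplogroup-B2 samples, DYS481 CTG[0] in a B2b
    subclade and CTG[2] polyphyletic (confined to G2a when combined with
    CTT[20]), and the DYS393 internal SNP in the 4 R1a samples."""
    from .phylo import SampleTree

    b2 = f"({_clade('B2')},{_clade('B2b')})"
    p = f"(({_clade('Q')},{_clade('Q1a')}),(({_clade('R1a')},{_clade('R1b')}),{_clade('R2')}))"
    ton = f"({_clade('T')},({_clade('N')},{_clade('O')}))"
    newick = (
        f"({_clade('A')},({b2},(({_clade('C')},{_clade('D')}),({_clade('E')},"
        f"(({_clade('G2a')},({_clade('H')},({_clade('I')},{_clade('J')}))),"
        f"({_clade('L')},({ton},{p})))))));"
    )
    haplogroups = {
        leaf: label for label, _ in _CLADE_SIZES for leaf in _leaf_names(label)
    }
    tree = SampleTree.from_newick(newick, haplogroups=haplogroups)

    def leaves(*labels):
        return frozenset(l for lab in labels for l in _leaf_names(lab))

    carriers = {
        "DYS635_RPV_P": leaves("Q", "Q1a", "R1a", "R1b", "R2"),
        "DYS389II_CAGA6": leaves("E"),
        "DYS389II_CAGA4": leaves("T", "N", "O") | frozenset(["C-01", "J-01", "A-01"]),
        "DYS391_rs112815242": leaves("B2", "B2b"),
        "DYS481_CTG0": leaves("B2b"),
        "DYS481_CTG2": leaves("G2a") | frozenset(
            ["H-01", "I-01", "J-02", "D-01", "L-01", "C-02"]),
        "DYS393_internal": leaves("R1a"),
    }
    return ReferenceTreeFixture(tree=tree, carriers=carriers)


def reference_tree_profile(catalog: Catalog):
    """Per-sample decompositions for the loci of the reference-tree carrier
    patterns, suitable for extract_variants/classify_variants."""
    fx = reference_tree()
    car = fx.carriers
    samples = sorted(fx.tree.leaves)

    assignments: dict[tuple[str, str], str] = {}  # (sample, locus) -> designation
    for s in samples:
        # DYS635: 7-block P signature vs isometric ancestral 5-block (both CE23)
        if s in car["DYS635_RPV_P"]:
            assignments[(s, "DYS635")] = \
                "CE23_TAGA[10]TACA[2]TAGA[2]TACA[2]TAGA[2]TACA[2]TAGA[3]"
        else:
            assignments[(s, "DYS635")] = "CE23_TAGA[13]TACA[2]TAGA[2]TACA[2]TAGA[4]"
        # DYS389II: isometric CE29 trio
        if s in car["DYS389II_CAGA6"]:
            assignments[(s, "DYS389II")] = "CE29_TAGA[10]CAGA[3]N[48]TAGA[10]CAGA[6]"
        elif s in car["DYS389II_CAGA4"]:
            assignments[(s, "DYS389II")] = "CE29_TAGA[10]CAGA[3]N[48]TAGA[12]CAGA[4]"
        else:
            assignments[(s, "DYS389II")] = "CE29_TAGA[10]CAGA[3]N[48]TAGA[11]CAGA[5]"
        # DYS391 flanking SNP in B2
        if s in car["DYS391_rs112815242"]:
            assignments[(s, "DYS391")] = "CE11_TCTA[11]_+50C>A"
        else:
            assignments[(s, "DYS391")] = "CE11_TCTA[11]"
        # DYS481: CTG[0] monophyletic in B2b; CTG[2] polyphyletic, with
        # the CTT[20] combination confined to G2a
        if s in car["DYS481_CTG0"]:
            assignments[(s, "DYS481")] = "CE24_CTG[0]CTT[25]"
        elif s in car["DYS481_CTG2"]:
            if s.startswith("G2a"):
                assignments[(s, "DYS481")] = "CE21_CTG[2]CTT[20]"
            else:
                assignments[(s, "DYS481")] = "CE24_CTG[2]CTT[23]"
        elif s.startswith("H"):
            assignments[(s, "DYS481")] = "CE24_CTG[1]CTT[24]"
        elif s.startswith("D"):
            assignments[(s, "DYS481")] = "CE21_CTG[1]CTT[21]"
        else:
            assignments[(s, "DYS481")] = "CE22_CTG[1]CTT[22]"
        # DYS393 internal SNP (A->C at the first base of the array) in R1a
        if s in car["DYS393_internal"]:
            assignments[(s, "DYS393")] = "CE12_CGAT[1]AGAT[11]"
        else:
            assignments[(s, "DYS393")] = "CE12_AGAT[12]"

    from .nomenclature import parse_mps_name

    cache: dict[tuple[str, str], Decomposition] = {}
    profile = []
    for (s, locus_name), desig in sorted(assignments.items()):
        key = (locus_name, desig)
        if key not in cache:
            cache[key] = parse_mps_name(desig, catalog[locus_name])
        profile.append((s, locus_name, cache[key]))
    return fx, profile


# --------------------------------------------------------------------------- #
# 100-sample survey profile with the published summary structure
# --------------------------------------------------------------------------- #

#: per-locus (distinct length-based alleles, distinct sequence-based alleles)
SURVEY_COUNTS: dict[str, tuple[int, int]] = {
    "DYS389II": (7, 32), "DYS390": (8, 19), "DYS448": (9, 19),
    "DYS391": (5, 10), "DYS437": (5, 9), "DYS481": (12, 21),
    "DYS458": (10, 16), "DYS385a,b": (14, 22), "DYS635": (11, 17),
    "DYS570": (8, 12), "DYS438": (7, 10), "DYS389I": (5, 6),
    "DYS439": (5, 6), "DYS19": (6, 7), "DYS393": (6, 7),
    "Y-GATA-H4": (6, 7), "DYS533": (8, 9), "DYS643": (9, 10),
    "DYS392": (8, 8), "DYS456": (5, 5), "DYS549": (6, 6), "DYS576": (9, 9),
}

#: designations guaranteed to appear among a locus's non-novel alleles
_PRIORITY_FILLS: dict[str, tuple[str, ...]] = {
    "DYS481": ("CE21_CTG[2]CTT[20]", "CE22_CTG[1]CTT[22]_-20C>T"),
    "DYS643": ("CE11_CTTTT[11]",),
}

#: substitute motif used by the internal-variant-unit fill generator
_G3_VARIANT: dict[str, str] = {
    "DYS458": "GAGA", "DYS393": "CGAT", "DYS392": "TGT",
}


def _ce_value(name: str) -> float:
    return float(name)


def _prefix_of(designation: str) -> str:
    return split_designation(designation)[0]


def _plain_units(locus: LocusDefinition, k: int) -> str | None:
    """Canonical-pattern units string at CE value k (largest counted block
    adjusted)."""
    counts = [1 if b.fixed_spacer else b.canonical for b in locus.blocks]
    counted = [i for i, b in enumerate(locus.blocks) if b.counted]
    main = max(counted, key=lambda i: counts[i])
    counts[main] += k - locus.reference_ce
    if counts[main] < 1:
        return None
    parts = []
    for b, n in zip(locus.blocks, counts):
        if b.fixed_spacer:
            parts.append(f"N[{len(b.motif)}]")
        elif n > 0:
            parts.append(f"{b.motif}[{n}]")
        elif not b.counted:
            parts.append(f"{b.motif}[0]")
    return "".join(parts)


def _vector_designations(locus: LocusDefinition, k: int):
    """Alternative same-length block-count vectors at CE value k (single-unit
    transfers between equal-period variable repeat blocks)."""
    from .simulate import _legal_vector  # shared legality rule

    base = [1 if b.fixed_spacer else b.canonical for b in locus.blocks]
    counted = [i for i, b in enumerate(locus.blocks) if b.counted]
    main = max(counted, key=lambda i: base[i])
    base[main] += k - locus.reference_ce
    if base[main] < 1 or not _legal_vector(locus, base):
        return
    variable = [i for i, b in enumerate(locus.blocks)
                if not b.fixed_spacer and b.min_repeats != b.max_repeats]
    for i in variable:
        for j in variable:
            if i == j or len(locus.blocks[i].motif) != len(locus.blocks[j].motif):
                continue
            vec = list(base)
            vec[i] -= 1
            vec[j] += 1
            if not _legal_vector(locus, vec):
                continue
            parts = []
            for b, n in zip(locus.blocks, vec):
                if b.fixed_spacer:
                    parts.append(f"N[{len(b.motif)}]")
                elif n > 0:
                    parts.append(f"{b.motif}[{n}]")
                elif not b.counted:
                    parts.append(f"{b.motif}[0]")
            yield "".join(parts)


def _flank_fill_descriptor(locus: LocusDefinition, used_offsets: set) -> str | None:
    for kv in locus.known_flank_variants:
        if kv.kind == "snp" and kv.offset not in used_offsets:
            used_offsets.add(kv.offset)
            sign = "+" if kv.offset > 0 else "-"
            return f"{sign}{abs(kv.offset)}{kv.ref}>{kv.alt}"
    for offset in (11, 13, 17, 19, 23, 29, 31, 37, 41):
        if offset in used_offsets:
            continue
        ref = locus.downstream_flank[offset - 1]
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        used_offsets.add(offset)
        return f"+{offset}{ref}>{alt}"
    return None


def _locus_inventory(locus: LocusDefinition, n_len: int, n_seq: int,
                     novel: list[str]) -> list[str]:
    """Deterministic allele inventory with exactly n_len distinct length
    names and n_seq distinct designations, containing every novel
    designation."""
    inventory = list(novel)
    lengths = {_prefix_of(d) for d in inventory}

    # 1. plain canonical-pattern alleles at new lengths
    k = locus.reference_ce
    offsets = [0]
    for i in range(1, 40):
        offsets += [-i, i]
    for off in offsets:
        if len(lengths) >= n_len:
            break
        kk = k + off
        if kk < 1 or str(kk) in lengths:
            continue
        units = _plain_units(locus, kk)
        if units is None:
            continue
        desig = f"CE{kk}_{units}"
        if desig in inventory:
            continue
        inventory.append(desig)
        lengths.add(str(kk))

    # 2. priority fills (must not add new lengths beyond budget)
    for desig in _PRIORITY_FILLS.get(locus.name, ()):
        if len(inventory) >= n_seq or desig in inventory:
            continue
        inventory.append(desig)
        lengths.add(_prefix_of(desig))

    # 3. generic isometric fills at existing lengths
    used_offsets: set = set()
    int_lengths = sorted(
        (l for l in lengths if "." not in l), key=_ce_value)
    round_ = 0
    while len(inventory) < n_seq and round_ < 8:
        round_ += 1
        for lname in int_lengths:
            if len(inventory) >= n_seq:
                break
            kk = int(lname)
            added = False
            # g0: plain designation at an already-used length
            units = _plain_units(locus, kk)
            if units is not None:
                desig = f"CE{kk}_{units}"
                if desig not in inventory:
                    inventory.append(desig)
                    added = True
            if added or len(inventory) >= n_seq:
                continue
            # g1: alternative block-count vectors (RPV)
            for units in _vector_designations(locus, kk):
                desig = f"CE{kk}_{units}"
                if desig not in inventory:
                    inventory.append(desig)
                    added = True
                    break
            if added or len(inventory) >= n_seq:
                continue
            # g2: flanking-SNP fill on the plain allele
            base = _plain_units(locus, kk)
            if base is not None:
                desc = _flank_fill_descriptor(locus, used_offsets)
                if desc is not None:
                    desig = f"CE{kk}_{base}_{desc}"
                    if desig not in inventory:
                        inventory.append(desig)
                        added = True
            if added or len(inventory) >= n_seq:
                continue
            # g3: internal variant unit replacing the last unit of the main block
            var = _G3_VARIANT.get(locus.name)
            if var is not None:
                counted = [i for i, b in enumerate(locus.blocks) if b.counted]
                main = max(counted, key=lambda i: locus.blocks[i].canonical)
                n_main = locus.blocks[main].canonical + kk - locus.reference_ce
                if n_main >= 2:
                    motif = locus.blocks[main].motif
                    desig = f"CE{kk}_{motif}[{n_main - 1}]{var}[1]"
                    if desig not in inventory:
                        inventory.append(desig)

    if len(inventory) != n_seq or len({_prefix_of(d) for d in inventory}) != n_len:
        raise RuntimeError(
            f"{locus.name}: inventory has {len(inventory)} designations over "
            f"{len({_prefix_of(d) for d in inventory})} lengths "
            f"(wanted {n_seq}/{n_len})")
    return inventory


@dataclass(frozen=True)
class SurveyFixture:
    """The 100-sample survey: profile + CE companion + known catalogue."""

    profile: "pd.DataFrame"
    ce_profile: "pd.DataFrame"
    known: "pd.DataFrame"


#: extra-allele cells: (sample, locus, verdict)
_SURVEY_EXTRAS = (
    ("S091", "DYS391", "duplication"), ("S092", "DYS439", "duplication"),
    ("S093", "DYS456", "duplication"), ("S094", "DYS549", "duplication"),
    ("S095", "DYS392", "duplication"),
    ("S096", "DYS570", "somatic"), ("S097", "DYS393", "somatic"),
    ("S098", "Y-GATA-H4", "somatic"), ("S099", "DYS533", "somatic"),
    ("S100", "DYS19", "somatic"), ("S090", "DYS643", "somatic"),
)


def survey_profile(catalog: Catalog, n_samples: int = 100) -> SurveyFixture:
    """Build the 100-sample, 2311-allele survey fixture.

    The per-locus distinct-allele structure follows SURVEY_COUNTS; every
    published novel designation appears; eleven extra alleles (5
    duplications, 6 somatic mutants, one of them an isometric DYS643 pair
    split by a flanking SNP) raise the total to 23x100 + 11; the CE
    companion profile is concordant except for four planted discordances
    (one flanking-indel, one mobility-shift SNP, two primer differences).
    """
    import pandas as pd

    novel_by_locus: dict[str, list[str]] = {}
    for locus_name, desig, _ in TABLE3:
        novel_by_locus.setdefault(locus_name, []).append(desig)

    inventories: dict[str, list[str]] = {}
    for locus_name, (n_len, n_seq) in SURVEY_COUNTS.items():
        inventories[locus_name] = _locus_inventory(
            catalog[locus_name], n_len, n_seq,
            novel_by_locus.get(locus_name, []))

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    extras_by_cell = {(s, l): v for s, l, v in _SURVEY_EXTRAS}

    # designation metadata (flank-variant structure) computed once
    meta: dict[tuple[str, str], dict] = {}

    def meta_of(locus_name: str, desig: str) -> dict:
        key = (locus_name, desig)
        if key not in meta:
            from .nomenclature import parse_flank_descriptor

            locus = catalog[locus_name]
            _, _, descs = split_designation(desig)
            variants = [parse_flank_descriptor(t).annotated(locus) for t in descs]
            meta[key] = {
                "n_flank_snps": sum(1 for v in variants if v.kind == "snp"),
                "n_flank_indels": sum(1 for v in variants if v.kind != "snp"),
                "mobility_shift": any(v.mobility_shift for v in variants),
            }
        return meta[key]

    rows = []

    def add_row(sample, locus_name, desig, status):
        m = meta_of(locus_name, desig)
        rows.append({
            "sample": sample, "locus": locus_name,
            "ce_name": _prefix_of(desig), "length_name": _prefix_of(desig),
            "mps_name": desig, "depth": 1000, "adjusted_depth": 1100,
            "status": status, "homoallelic": False, **m,
        })

    for locus_name in sorted(SURVEY_COUNTS):
        inv = inventories[locus_name]
        n = len(inv)
        if locus_name == "DYS385a,b":
            for i, sample in enumerate(samples):
                add_row(sample, locus_name, inv[(2 * i) % n], "primary")
                add_row(sample, locus_name, inv[(2 * i + 1) % n], "primary")
        else:
            for i, sample in enumerate(samples):
                add_row(sample, locus_name, inv[i % n], "primary")

    # extra alleles: a different designation, never at the -1 position
    for (sample, locus_name), verdict in sorted(extras_by_cell.items()):
        inv = inventories[locus_name]
        primary = inv[samples.index(sample) % len(inv)]
        if locus_name == "DYS643":
            extra = "CE11_CTTTT[11]_-7A>G"  # isometric somatic pair
            if primary == extra:
                extra = "CE11_CTTTT[11]"
        else:
            p_len = _ce_value(_prefix_of(primary))
            extra = next(
                d for d in inv
                if d != primary
                and _ce_value(_prefix_of(d)) not in (p_len, p_len - 1))
        add_row(sample, locus_name, extra, verdict)

    profile = pd.DataFrame(rows)

    # CE companion profile with 4 planted discordances
    ce_rows = profile[["sample", "locus", "length_name"]].rename(
        columns={"length_name": "allele"}).copy().reset_index(drop=True)
    planted = 0

    def plant(mask_desig, new_allele):
        nonlocal planted
        idx = profile.index[profile["mps_name"] == mask_desig][0]
        ce_rows.at[idx, "allele"] = new_allele
        planted += 1

    # flanking-indel case: CE primers exclude the 13-bp insertion
    plant("CE14.1_TATC[11]_-48.1->CTCTTCTAACTAT", "11")
    # mobility-shift case: rs368663163 shifts the CE call to a .1 allele
    plant("CE22_CTG[1]CTT[22]_-20C>T", "22.1")
    # two primer-placement differences (no flanking variant involved)
    i1 = profile.index[(profile["sample"] == "S050") & (profile["locus"] == "DYS456")][0]
    ce_rows.at[i1, "allele"] = str(int(profile.at[i1, "length_name"]) + 1)
    i2 = profile.index[(profile["sample"] == "S060") & (profile["locus"] == "DYS549")][0]
    ce_rows.at[i2, "allele"] = str(int(profile.at[i2, "length_name"]) - 1)
    planted += 2
    assert planted == 4

    # known-variant catalogue: everything except the published novelties
    novel_set = {(l, d) for l, d, _ in TABLE3}
    known_rows = [
        {"locus": l, "designation": d, "match_mode": "exact"}
        for l, d in sorted(set(
            (r["locus"], r["mps_name"]) for r in rows))
        if (l, d) not in novel_set
    ]
    known = pd.DataFrame(known_rows)
    return SurveyFixture(profile=profile, ce_profile=ce_rows, known=known)
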