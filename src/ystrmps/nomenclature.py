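"""CE-compatible and sequence-based (MPS) allele naming.

Two names are produced for every decomposed allele:

* ``ce_name`` — the CE-compatible structural name: the sum of counted-block
  unit counts (variant units occupy a full repeat position and count), plus,
  for uncounted variable blocks (DYS481's leading CTG, DYS385's AAGG,
  DYS390's trailing TAGA, DYS19's ccta), the deviation of their copy number
  from the canonical reference — so a DYS481 allele lacking the CTG is named
  n−1, one with two copies n+1, and a DYS19 allele without the ccta spacer
  is named a+b−1. Partial (sub-period) units append the ``.r`` residue.

* ``length_based_name`` — the name a CE instrument would report, computed
  purely from amplicon length: array length plus the net length of flanking
  indels, relative to the canonical reference. Isometric alleles collide on
  this name; for any allele without flanking indels it equals ``ce_name``.

The full MPS designation is ``CE<length name>_<bracketed units>`` followed
by flanking-variant descriptors, e.g. ``CE11_CTTTT[11]_-7A>G``. Designations
are parseable back to a Decomposition (round-trip), and can be rendered to
full amplicon DNA for simulation and fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .catalog import LocusDefinition
from .decompose import (
    Decomposition,
    FlankVariant,
    MINUS,
    decompose,
    render_allele,
)


class NamingError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleName:
    locus: str
    ce: str
    length_based: str
    mps: str

    def __str__(self) -> str:
        return self.mps


def _format(k: int, r: int) -> str:
    if k <= 0:
        raise NamingError(f"non-positive repeat count {k}")
    return f"{k}.{r}" if r else str(k)


def ce_name(d: Decomposition, locus: LocusDefinition) -> str:
    """CE-compatible structural allele name (see module docstring)."""
    eff = d.effective_block_counts(locus)
    k = locus.ce_offset
    for block, n in zip(locus.blocks, eff):
        if block.fixed_spacer:
            continue
        if block.counted:
            k += n
        else:
            k += n - block.canonical
    r = d.partial_length % locus.period
    return _format(k, r)


def length_based_name(d: Decomposition, locus: LocusDefinition) -> str:
    """The allele name electrophoresis would report, from fragment length
    alone (array length + net flanking-indel length vs the reference)."""
    delta = d.array_length + d.flank_indel_net_length - locus.reference_array_length
    k = locus.reference_ce + delta // locus.period
    r = delta % locus.period
    return _format(k, r)


def units_string(d: Decomposition, locus: LocusDefinition) -> str:
    """Bracketed unit rendering, 5'->3'. Fixed spacers print as N[len];
    uncounted variable blocks with zero copies print explicitly (CTG[0])."""
    parts: list[str] = []
    seen_blocks = {u.block_index for u in d.units}
    units = list(d.units)
    ui = 0
    for bi, block in enumerate(locus.blocks):
        if bi in seen_blocks:
            while ui < len(units) and units[ui].block_index == bi:
                u = units[ui]
                if u.role == "spacer":
                    parts.append(f"N[{len(u.seq)}]")
                else:
                    parts.append(f"{u.seq}[{u.count}]")
                ui += 1
        elif not block.counted and not block.fixed_spacer:
            parts.append(f"{block.motif}[0]")
    return "".join(parts)


def mps_name(d: Decomposition, locus: LocusDefinition) -> str:
    """Full sequence-based designation: CE<length name>_<units>[_<flank>...]."""
    name = f"CE{length_based_name(d, locus)}_{units_string(d, locus)}"
    for v in d.flank_variants:
        name += f"_{v.descriptor}"
    return name


def name_allele(d: Decomposition, locus: LocusDefinition) -> AlleleName:
    return AlleleName(
        locus=locus.name,
        ce=ce_name(d, locus),
        length_based=length_based_name(d, locus),
        mps=mps_name(d, locus),
    )


# --------------------------------------------------------------------------- #
# designation parsing / rendering
# --------------------------------------------------------------------------- #
_UNIT_RE = re.compile(r"([ACGT]+|N)\[(\d+)\]")
_SNP_RE = re.compile(r"^([+-])(\d+)([ACGT]+)>([ACGT]+)$")
_DEL_RE = re.compile(r"^([+-])(\d+)([ACGT]+)>-$")
_INS_RE = re.compile(r"^([+-])(\d+)\.1->([ACGT]+)$")


def _normalise(designation: str) -> str:
    return designation.replace(MINUS, "-").strip()


def parse_flank_descriptor(desc: str) -> FlankVariant:
    desc = _normalise(desc)
    m = _DEL_RE.match(desc)
    if m:
        sign, k, ref = m.groups()
        return FlankVariant(offset=int(k) * (1 if sign == "+" else -1),
                            kind="del", ref=ref, alt="-")
    m = _INS_RE.match(desc)
    if m:
        sign, k, alt = m.groups()
        return FlankVariant(offset=int(k) * (1 if sign == "+" else -1),
                            kind="ins", ref="-", alt=alt)
    m = _SNP_RE.match(desc)
    if m:
        sign, k, ref, alt = m.groups()
        if len(ref) != 1 or len(alt) != 1:
            raise NamingError(f"multi-base substitution not supported: {desc!r}")
        return FlankVariant(offset=int(k) * (1 if sign == "+" else -1),
                            kind="snp", ref=ref, alt=alt)
    raise NamingError(f"unparseable flank descriptor {desc!r}")


def split_designation(designation: str) -> tuple[str, str, tuple[str, ...]]:
    """Split 'CE18_TAGA[8]..._+50C>A' into (ce part, units part, descriptors)."""
    fields = _normalise(designation).split("_")
    if len(fields) < 2 or not fields[0].startswith("CE"):
        raise NamingError(f"designation {designation!r} lacks CE prefix or units")
    return fields[0][2:], fields[1], tuple(fields[2:])


def designation_to_array(units_part: str, locus: LocusDefinition) -> str:
    """Render the array DNA of a bracketed units string."""
    units_part = _normalise(units_part)
    pos = 0
    out = []
    spacers = [b for b in locus.blocks if b.fixed_spacer]
    si = 0
    for m in _UNIT_RE.finditer(units_part):
        if m.start() != pos:
            raise NamingError(f"unparseable units at {units_part[pos:]!r}")
        pos = m.end()
        seq, count = m.group(1), int(m.group(2))
        if seq == "N":
            if si >= len(spacers):
                raise NamingError(f"{locus.name}: designation has extra N-spacer")
            spacer = spacers[si].motif
            si += 1
            if len(spacer) != count:
                raise NamingError(
                    f"{locus.name}: N[{count}] but catalogue spacer is {len(spacer)} nt")
            out.append(spacer)
        else:
            out.append(seq * count)
    if pos != len(units_part):
        raise NamingError(f"unparseable units at {units_part[pos:]!r}")
    return "".join(out)


def designation_to_sequence(designation: str, locus: LocusDefinition) -> str:
    """Full amplicon DNA for a designation (reference flanks with the
    designation's flank variants applied)."""
    _, units_part, descs = split_designation(designation)
    array = designation_to_array(units_part, locus)
    variants = [parse_flank_descriptor(t) for t in descs]
    return render_allele(locus, array, variants)


def parse_mps_name(designation: str, locus: LocusDefinition) -> Decomposition:
    """Parse a designation back to a Decomposition via the real pipeline:
    render to DNA, then decompose. Guarantees parse(mps_name(d)) == d."""
    return decompose(designation_to_sequence(designation, locus), locus)
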