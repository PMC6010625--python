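"""Locus catalogue: repeat-structure grammars for the 23 PowerPlex Y23 Y-STRs.

Each locus is described declaratively (in ``data/ppy23.json``) as an ordered
list of repeat blocks on the reporting strand, plus reference flanking
sequence, a genomic anchor (GRCh38 chrY, 1-based, first array base) and a
table of known flanking variants used for annotation.  Blocks are either
repeat blocks (a 3-6 nt motif with a legal copy-number range and a canonical
reference copy number) or fixed spacers (literal intervening sequence such as
the 42 nt insert of DYS448, written N[42] in designations).

Counted blocks contribute to the CE-compatible allele name; uncounted
variable blocks (the leading CTG of DYS481, the AAGG block of DYS385, the
trailing TAGA of DYS390, the ccta of DYS19) do not, but their deviation from
the canonical copy number shifts the CE name so that length compatibility
with capillary electrophoresis is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

DNA = set("ACGT")

#: the 23 PPY23 marker names (DYS385a and DYS385b listed separately)
PPY23_MARKERS = (
    "DYS19", "DYS385a", "DYS385b", "DYS389I", "DYS389II", "DYS390",
    "DYS391", "DYS392", "DYS393", "DYS437", "DYS438", "DYS439", "DYS448",
    "DYS456", "DYS458", "DYS481", "DYS533", "DYS549", "DYS570", "DYS576",
    "DYS635", "DYS643", "Y-GATA-H4",
)


class CatalogError(ValueError):
    """Raised for malformed or inconsistent locus definitions."""


@dataclass(frozen=True)
class BlockSpec:
    """One repeat block (or fixed spacer) of a Y-STR array.

    For repeat blocks ``motif`` is the repeat unit; for spacers it is the
    full literal spacer sequence and ``min_repeats == max_repeats == 1``.
    """

    motif: str
    min_repeats: int
    max_repeats: int
    canonical: int
    counted: bool = True
    fixed_spacer: bool = False

    def validate(self, locus: str, period: int) -> None:
        if not self.motif or set(self.motif) - DNA:
            raise CatalogError(f"{locus}: block motif {self.motif!r} is not uppercase DNA")
        if self.fixed_spacer:
            if self.counted:
                raise CatalogError(f"{locus}: fixed spacer cannot be counted")
            if not (self.min_repeats == self.max_repeats == 1):
                raise CatalogError(f"{locus}: fixed spacer must have exactly one copy")
        else:
            if not 3 <= len(self.motif) <= 6:
                raise CatalogError(f"{locus}: motif {self.motif!r} length outside 3-6")
            if self.counted and len(self.motif) != period:
                raise CatalogError(
                    f"{locus}: counted motif {self.motif!r} does not match period {period}"
                )
        if self.min_repeats < 0 or self.max_repeats < self.min_repeats:
            raise CatalogError(f"{locus}: bad repeat range [{self.min_repeats},{self.max_repeats}]")
        if not self.min_repeats <= self.canonical <= self.max_repeats:
            raise CatalogError(f"{locus}: canonical count {self.canonical} outside range")


@dataclass(frozen=True)
class KnownFlankVariant:
    """A literature-known flanking variant used to annotate calls."""

    offset: int                  # signed; + downstream of array end, - upstream of array start
    kind: str                    # "snp" | "ins" | "del"
    ref: str                     # "-" for insertions
    alt: str                     # "-" for deletions
    rs_id: Optional[str] = None
    label: Optional[str] = None  # e.g. Y-SNP name such as M8738/CTS1866
    genomic_position: Optional[int] = None
    mobility_shift: bool = False  # known to shift CE mobility (e.g. rs368663163)


@dataclass(frozen=True)
class LocusDefinition:
    name: str
    period: int
    blocks: tuple[BlockSpec, ...]
    upstream_flank: str
    downstream_flank: str
    anchor_position: int
    anchor_strand: str = "+"
    ce_offset: int = 0
    n_copies: int = 1
    flank_window: int = 50
    known_flank_variants: tuple[KnownFlankVariant, ...] = ()
    reporting_strand_note: str = ""
    aliases: tuple[str, ...] = ()

    # ------------------------------------------------------------------ #
    @property
    def repeat_blocks(self) -> tuple[BlockSpec, ...]:
        return tuple(b for b in self.blocks if not b.fixed_spacer)

    @property
    def counted_blocks(self) -> tuple[BlockSpec, ...]:
        return tuple(b for b in self.blocks if b.counted)

    @property
    def reference_ce(self) -> int:
        """CE name of the canonical (GRCh38-style) reference allele."""
        return sum(b.canonical for b in self.counted_blocks) + self.ce_offset

    @property
    def reference_array_length(self) -> int:
        return sum(
            len(b.motif) if b.fixed_spacer else b.canonical * len(b.motif)
            for b in self.blocks
        )

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(b.motif for b in self.repeat_blocks))

    def render_array(self, counts) -> str:
        """Render an array sequence from per-block copy numbers (spacers take
        their literal sequence regardless of the supplied count)."""
        counts = list(counts)
        if len(counts) != len(self.blocks):
            raise ValueError(f"{self.name}: expected {len(self.blocks)} counts")
        out = []
        for b, c in zip(self.blocks, counts):
            out.append(b.motif if b.fixed_spacer else b.motif * c)
        return "".join(out)

    def reference_allele(self):
        """Canonical decomposition (rendered from canonical counts and
        re-parsed, guaranteeing grammar consistency)."""
        from .decompose import decompose_array

        return decompose_array(self.render_array(b.canonical for b in self.blocks), self)

    def genomic_position(self, offset: int) -> int:
        """GRCh38 chrY coordinate of a flank offset (± convention)."""
        if offset < 0:
            return self.anchor_position + offset  # -k -> k bases before first array base
        return self.anchor_position + self.reference_array_length - 1 + offset

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        if self.period not in (3, 4, 5, 6):
            raise CatalogError(f"{self.name}: period {self.period} outside 3-6")
        if not self.blocks:
            raise CatalogError(f"{self.name}: no blocks")
        for b in self.blocks:
            b.validate(self.name, self.period)
        if not any(b.counted for b in self.blocks):
            raise CatalogError(f"{self.name}: no counted block")
        for flank, side in ((self.upstream_flank, "upstream"), (self.downstream_flank, "downstream")):
            if len(flank) < 30:
                raise CatalogError(f"{self.name}: {side} flank shorter than 30 nt")
            if set(flank) - DNA:
                raise CatalogError(f"{self.name}: {side} flank is not uppercase DNA")
        self._check_boundaries()

    def _first_possible_motifs(self) -> list[str]:
        out = []
        for b in self.blocks:
            if b.fixed_spacer:
                break
            out.append(b.motif)
            if b.min_repeats > 0:
                break
        return out

    def _last_possible_motifs(self) -> list[str]:
        out = []
        for b in reversed(self.blocks):
            if b.fixed_spacer:
                break
            out.append(b.motif)
            if b.min_repeats > 0:
                break
        return out

    def _check_boundaries(self) -> None:
        # Maximal-extension rule requires that the flanks cannot extend an
        # adjacent repeat run: the upstream flank must not end with a motif
        # that can start the array, and the downstream flank must not begin
        # with a motif that can end it.
        for m in self._first_possible_motifs():
            if self.upstream_flank.endswith(m):
                raise CatalogError(
                    f"{self.name}: upstream flank ends with array motif {m!r} "
                    "(ambiguous array boundary)"
                )
        for m in self._last_possible_motifs():
            if self.downstream_flank.startswith(m):
                raise CatalogError(
                    f"{self.name}: downstream flank starts with array motif {m!r} "
                    "(ambiguous array boundary)"
                )


@dataclass(frozen=True)
class Catalog:
    """The validated set of PPY23 locus definitions."""

    loci: tuple[LocusDefinition, ...]
    flank_window: int = 50
    source: str = ""
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        for locus in self.loci:
            self._by_name[locus.name] = locus
            for alias in locus.aliases:
                self._by_name[alias] = locus

    def __iter__(self) -> Iterator[LocusDefinition]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, name: str) -> LocusDefinition:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown locus {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    @property
    def n_markers(self) -> int:
        """Number of PPY23 markers covered (DYS385a,b counts twice)."""
        return sum(l.n_copies for l in self.loci)

    def alleles_per_sample(self) -> int:
        return self.n_markers


def _parse_block(raw: dict, locus: str) -> BlockSpec:
    try:
        if raw.get("fixed_spacer"):
            return BlockSpec(
                motif=raw["sequence"],
                min_repeats=1, max_repeats=1, canonical=1,
                counted=False, fixed_spacer=True,
            )
        return BlockSpec(
            motif=raw["motif"],
            min_repeats=int(raw["min"]),
            max_repeats=int(raw["max"]),
            canonical=int(raw["canonical"]),
            counted=bool(raw.get("counted", True)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CatalogError(f"{locus}: malformed block spec {raw!r} ({exc})") from exc


def _parse_locus(raw: dict) -> LocusDefinition:
    name = raw.get("name", "<unnamed>")
    blocks = tuple(_parse_block(b, name) for b in raw.get("blocks", ()))
    variants = tuple(
        KnownFlankVariant(
            offset=int(v["offset"]),
            kind=v["kind"],
            ref=v.get("ref", "-"),
            alt=v.get("alt", "-"),
            rs_id=v.get("rs_id"),
            label=v.get("label"),
            genomic_position=v.get("genomic_position"),
            mobility_shift=bool(v.get("mobility_shift", False)),
        )
        for v in raw.get("known_flank_variants", ())
    )
    locus = LocusDefinition(
        name=name,
        period=int(raw["period"]),
        blocks=blocks,
        upstream_flank=raw["upstream_flank"],
        downstream_flank=raw["downstream_flank"],
        anchor_position=int(raw["anchor_position"]),
        anchor_strand=raw.get("anchor_strand", "+"),
        ce_offset=int(raw.get("ce_offset", 0)),
        n_copies=int(raw.get("n_copies", 1)),
        flank_window=int(raw.get("flank_window", 50)),
        known_flank_variants=variants,
        reporting_strand_note=raw.get("note", ""),
        aliases=tuple(raw.get("aliases", ())),
    )
    locus.validate()
    return locus


def load_catalog(path: Optional[str | Path] = None) -> Catalog:
    """Load and validate a locus catalogue (the packaged PPY23 one by default)."""
    if path is None:
        text = resources.files("ystrmps.data").joinpath("ppy23.json").read_text()
        source = "packaged:ppy23.json"
    else:
        text = Path(path).read_text()
        source = str(path)
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CatalogError(f"catalogue {source} is not valid JSON: {exc}") from exc

    loci = []
    seen = set()
    for entry in raw["loci"]:
        locus = _parse_locus(entry)
        if locus.name in seen:
            raise CatalogError(f"duplicate locus {locus.name}")
        seen.add(locus.name)
        loci.append(locus)
    cat = Catalog(
        loci=tuple(loci),
        flank_window=int(raw.get("flank_window", 50)),
        source=source,
    )
    missing = [m for m in PPY23_MARKERS if m not in cat]
    if path is None and missing:
        raise CatalogError(f"packaged catalogue misses PPY23 markers: {missing}")
    return cat
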