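"""Repeat-array decomposition of full-length Y-STR allele sequences.

Given a read or consensus sequence containing a complete STR amplicon
(upstream flank + repeat array + downstream flank), this module

1. locates the repeat array between the reference flanks (edit-tolerant, so
   flanking SNPs/indels do not break localisation),
2. parses the array into an ordered list of repeat units according to the
   locus grammar — repeat blocks, fixed spacers, single-substitution
   *variant units* (internal SNPs, e.g. GGAA inside a GAAA run) and at most
   one sub-period *partial unit* (internal indels, yielding intermediate
   ".x" alleles), and
3. calls flanking SNPs/indels by ungapped outward comparison against the
   reference flanks with banded indel rescue.

The parse is greedy maximal-extension with the fixed preference order
(extend current block > advance to next block > variant unit > partial
unit), implemented as a depth-first search with memoised failure states so
that structures like TCTA[6]TCTG[1]TCTA[3]TCTG[2]TCTA[4] (a repeat-block
motif recurring out of order) still parse deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import edlib

from .catalog import Catalog, LocusDefinition

MINUS = "−"  # unicode minus used in printed designations


class DecompositionError(ValueError):
    pass


class LocateError(DecompositionError):
    pass


class FlankError(DecompositionError):
    pass


# --------------------------------------------------------------------------- #
# data types
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class Unit:
    """A run of identical units within a decomposition.

    role: "repeat" (catalogue motif run), "spacer" (fixed intervening
    sequence), "variant" (period-length unit one substitution from the block
    motif) or "partial" (sub-period unit, internal indel).
    """

    seq: str
    count: int
    role: str
    block_index: int

    @property
    def length(self) -> int:
        return len(self.seq) * self.count


@dataclass(frozen=True)
class FlankVariant:
    """A SNP or indel in the flanking sequence, in the ±offset convention
    (+1 = first base after the array, −1 = last base before it)."""

    offset: int
    kind: str  # "snp" | "ins" | "del"
    ref: str
    alt: str
    rs_id: Optional[str] = None
    label: Optional[str] = None
    genomic_position: Optional[int] = None
    mobility_shift: bool = False

    @property
    def descriptor(self) -> str:
        sign = "+" if self.offset > 0 else "-"
        k = abs(self.offset)
        if self.kind == "snp":
            return f"{sign}{k}{self.ref}>{self.alt}"
        if self.kind == "del":
            return f"{sign}{k}{self.ref}>-"
        return f"{sign}{k}.1->{self.alt}"  # insertion between |k| and the next base out

    @property
    def net_length(self) -> int:
        """Signed length this variant adds to the amplicon."""
        if self.kind == "ins":
            return len(self.alt)
        if self.kind == "del":
            return -len(self.ref)
        return 0

    def annotated(self, locus: LocusDefinition) -> "FlankVariant":
        """Attach rs id / label / genomic position from the locus catalogue."""
        for kv in locus.known_flank_variants:
            if (kv.offset, kv.kind, kv.ref, kv.alt) == (self.offset, self.kind, self.ref, self.alt):
                return replace(
                    self, rs_id=kv.rs_id, label=kv.label,
                    genomic_position=kv.genomic_position, mobility_shift=kv.mobility_shift,
                )
        return replace(self, genomic_position=locus.genomic_position(self.offset))


@dataclass(frozen=True)
class Decomposition:
    """An allele sequence parsed into repeat units plus flanking variants."""

    locus: str
    units: tuple[Unit, ...]
    array_length: int
    flank_variants: tuple[FlankVariant, ...] = ()

    def render(self) -> str:
        """Re-concatenate the array sequence (round-trip identity)."""
        return "".join(u.seq * u.count for u in self.units)

    @property
    def partial_length(self) -> int:
        return sum(u.length for u in self.units if u.role == "partial")

    @property
    def n_internal_snps(self) -> int:
        return sum(u.count for u in self.units if u.role == "variant")

    @property
    def n_internal_indels(self) -> int:
        return sum(u.count for u in self.units if u.role == "partial")

    @property
    def flank_indel_net_length(self) -> int:
        return sum(v.net_length for v in self.flank_variants)

    def block_counts(self, locus: LocusDefinition) -> tuple[int, ...]:
        """Per-block motif-run copy numbers (variant/partial units excluded);
        the RPV signature of the allele."""
        counts = [0] * len(locus.blocks)
        for u in self.units:
            if u.role == "repeat":
                counts[u.block_index] += u.count
        return tuple(counts)

    def effective_block_counts(self, locus: LocusDefinition) -> tuple[int, ...]:
        """Per-block unit counts including variant units (these occupy a full
        repeat position and contribute to CE-compatible naming)."""
        counts = [0] * len(locus.blocks)
        for u in self.units:
            if u.role in ("repeat", "variant"):
                counts[u.block_index] += u.count
        return tuple(counts)


# --------------------------------------------------------------------------- #
# array localisation
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class LocatedArray:
    array_start: int
    array_end: int  # half-open
    observed_upstream: str
    observed_downstream: str


def _edlib_locate(query: str, target: str, max_edits: int):
    res = edlib.align(query, target, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    return res


def locate_array(sequence: str, locus: LocusDefinition,
                 anchor_length: int = 10, max_edits: int = 18) -> LocatedArray:
    """Find the repeat array between the reference flanks.

    Fast path: exact, unique occurrence of the two ``anchor_length``-nt
    flank anchors adjacent to the array. Fallback: edit-tolerant infix
    alignment of the whole reference flank (covers flanking SNPs/indels,
    including ones inside the anchor region), followed by boundary
    refinement — alignment alone cannot resolve co-optimal placements that
    trade array bases for flank edits, so candidate boundaries are scored by
    whether the array parses and how many flank variants the scan needs.
    """
    sequence = sequence.upper()
    up_anchor = locus.upstream_flank[-anchor_length:]
    down_anchor = locus.downstream_flank[:anchor_length]

    n_up = sequence.count(up_anchor)
    n_down = sequence.count(down_anchor)
    if n_up > 1:
        raise LocateError(f"{locus.name}: upstream flank anchor occurs {n_up} times")
    if n_down > 1:
        raise LocateError(f"{locus.name}: downstream flank anchor occurs {n_down} times")

    if n_up == 1:
        start_cands = [sequence.index(up_anchor) + anchor_length]
    else:
        res = _edlib_locate(locus.upstream_flank, sequence, max_edits)
        if res is None:
            raise LocateError(f"{locus.name}: upstream flank not found")
        s0 = max(loc[1] for loc in res["locations"]) + 1
        start_cands = [s for s in range(s0 - 12, s0 + 13) if s >= 0]
    if n_down == 1:
        end_cands = [sequence.index(down_anchor)]
    else:
        res = _edlib_locate(locus.downstream_flank, sequence, max_edits)
        if res is None:
            raise LocateError(f"{locus.name}: downstream flank not found")
        e0 = min(loc[0] for loc in res["locations"])
        end_cands = [e for e in range(e0 - 12, e0 + 13) if e <= len(sequence)]

    if len(start_cands) == 1 and len(end_cands) == 1:
        start, end = start_cands[0], end_cands[0]
        if not 0 <= start <= end:
            raise LocateError(
                f"{locus.name}: inverted array interval (start {start}, end {end})")
        return LocatedArray(start, end, sequence[:start], sequence[end:])

    best = None
    for start in start_cands:
        for end in end_cands:
            if end < start:
                continue
            try:
                decompose_array(sequence[start:end], locus)
                n_var = 0
                for obs, ref in ((sequence[end:], locus.downstream_flank),
                                 (sequence[:start][::-1], locus.upstream_flank[::-1])):
                    n_var += len(_scan_flank(obs, ref, locus.flank_window, band=15))
            except DecompositionError:
                continue
            score = (n_var, abs(start - start_cands[len(start_cands) // 2])
                     + abs(end - end_cands[len(end_cands) // 2]))
            if best is None or score < best[0]:
                best = (score, start, end)
    if best is None:
        raise LocateError(f"{locus.name}: no consistent array boundary found")
    _, start, end = best
    return LocatedArray(start, end, sequence[:start], sequence[end:])


# --------------------------------------------------------------------------- #
# array parsing
# --------------------------------------------------------------------------- #
def _hamming1(a: str, b: str) -> bool:
    return len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1


def decompose_array(array: str, locus: LocusDefinition) -> Decomposition:
    """Parse an array sequence (no flanks) into units. Raises
    DecompositionError with position and context on unparseable residue."""
    blocks = locus.blocks
    n_blocks = len(blocks)
    end = len(array)
    period = locus.period
    failed: set[tuple[int, int, bool]] = set()
    # track the deepest failure point for the error message
    deepest = [0]

    def search(pos: int, bi: int, partial_used: bool):
        if pos == end:
            return []
        deepest[0] = max(deepest[0], pos)
        if bi >= n_blocks:
            return None
        key = (pos, bi, partial_used)
        if key in failed:
            return None
        block = blocks[bi]
        if block.fixed_spacer:
            if array.startswith(block.motif, pos):
                rest = search(pos + len(block.motif), bi + 1, partial_used)
                if rest is not None:
                    return [(block.motif, "spacer", bi)] + rest
            rest = search(pos, bi + 1, partial_used)  # spacer absent
            if rest is not None:
                return rest
            failed.add(key)
            return None
        motif = block.motif
        # 1. extend the current block
        if array.startswith(motif, pos):
            rest = search(pos + len(motif), bi, partial_used)
            if rest is not None:
                return [(motif, "repeat", bi)] + rest
        # 2. advance to the next block
        rest = search(pos, bi + 1, partial_used)
        if rest is not None:
            return rest
        # 3. variant unit: one substitution away from the current block motif
        if pos + period <= end:
            u = array[pos:pos + period]
            if _hamming1(u, motif):
                rest = search(pos + period, bi, partial_used)
                if rest is not None:
                    return [(u, "variant", bi)] + rest
        # 4. partial unit (at most one per decomposition)
        if not partial_used:
            for plen in range(1, period):
                if pos + plen > end:
                    break
                rest = search(pos + plen, bi, True)
                if rest is not None:
                    return [(array[pos:pos + plen], "partial", bi)] + rest
        failed.add(key)
        return None

    if end == 0:
        raise DecompositionError(f"{locus.name}: empty array")
    result = search(0, 0, False)
    if result is None:
        p = deepest[0]
        ctx = array[max(0, p - 5):p + 5]
        raise DecompositionError(
            f"{locus.name}: unparseable array residue at position {p} (context {ctx!r})")

    # merge consecutive identical (seq, role, block) into counted runs
    units: list[Unit] = []
    for seq, role, bi in result:
        if units and units[-1].seq == seq and units[-1].role == role \
                and units[-1].block_index == bi:
            units[-1] = replace(units[-1], count=units[-1].count + 1)
        else:
            units.append(Unit(seq=seq, count=1, role=role, block_index=bi))
    return Decomposition(locus=locus.name, units=tuple(units), array_length=end)


# --------------------------------------------------------------------------- #
# flank variant calling
# --------------------------------------------------------------------------- #
def _scan_flank(obs: str, ref: str, window: int, band: int, confirm: int = 8):
    """Scan obs vs ref from index 0 outward; return list of
    (pos0, kind, ref_seg, alt_seg) with pos0 the 0-based offset-1 position.
    Strings are oriented so index 0 is the array-adjacent base."""
    out = []
    i = 0
    oi = 0  # extra shift of obs relative to ref (ins positive)
    limit = min(len(ref), window)
    while i < limit:
        if i + oi >= len(obs):
            break  # observed flank truncated; stop silently
        if obs[i + oi] == ref[i]:
            i += 1
            continue
        rem_obs = obs[i + oi:]
        rem_ref = ref[i:]

        def matches(a: str, b: str, n: int) -> bool:
            n = min(n, len(a), len(b))
            if n == 0:
                # no confirming bases left: only coherent if both are exhausted
                return len(a) == len(b)
            return a[:n] == b[:n]

        if matches(rem_obs[1:], rem_ref[1:], confirm):
            out.append((i, "snp", ref[i], obs[i + oi]))
            i += 1
            continue
        hit = None
        for d in range(1, band + 1):
            if i + d <= len(ref) and matches(rem_obs, ref[i + d:], confirm):
                hit = ("del", d)
                break
            if matches(rem_obs[d:], rem_ref, confirm):
                hit = ("ins", d)
                break
        if hit is None:
            raise FlankError(
                f"flank divergence at offset {i + 1} not resolvable within band {band}")
        kind, d = hit
        if kind == "del":
            out.append((i, "del", ref[i:i + d], "-"))
            oi -= d
            i += d
        else:
            out.append((i, "ins", "-", obs[i + oi:i + oi + d]))
            oi += d
            i += 1  # the ref base at i is matched by obs[i+oi]
            continue
    return out


def call_flank_variants(sequence: str, locus: LocusDefinition,
                        located: Optional[LocatedArray] = None,
                        band: int = 15) -> tuple[FlankVariant, ...]:
    """Compare observed flanks against the reference flanks outward from each
    array edge; returns annotated SNP/indel calls in the ± offset convention."""
    if located is None:
        located = locate_array(sequence, locus)
    window = locus.flank_window
    variants: list[FlankVariant] = []
    # downstream: left-to-right from the array end
    for pos0, kind, ref_seg, alt_seg in _scan_flank(
            located.observed_downstream, locus.downstream_flank, window, band):
        variants.append(FlankVariant(offset=pos0 + 1, kind=kind, ref=ref_seg, alt=alt_seg))
    # upstream: right-to-left from the array start (scan on reversed strings,
    # then un-reverse the segments)
    for pos0, kind, ref_seg, alt_seg in _scan_flank(
            located.observed_upstream[::-1], locus.upstream_flank[::-1], window, band):
        variants.append(FlankVariant(
            offset=-(pos0 + 1), kind=kind,
            ref=ref_seg[::-1] if ref_seg != "-" else "-",
            alt=alt_seg[::-1] if alt_seg != "-" else "-",
        ))
    variants.sort(key=lambda v: v.offset)
    return tuple(v.annotated(locus) for v in variants)


# --------------------------------------------------------------------------- #
# top-level
# --------------------------------------------------------------------------- #
def decompose(sequence: str, locus: LocusDefinition) -> Decomposition:
    """Full decomposition of an amplicon sequence: locate, parse, call flanks."""
    located = locate_array(sequence, locus)
    d = decompose_array(sequence[located.array_start:located.array_end], locus)
    flanks = call_flank_variants(sequence, locus, located=located)
    return replace(d, flank_variants=flanks)


def apply_flank_variants(locus: LocusDefinition,
                         variants=()) -> tuple[str, str]:
    """Return (upstream, downstream) flanks with the given variants applied —
    the inverse of call_flank_variants, used to render allele sequences."""
    up = list(locus.upstream_flank)
    down = list(locus.downstream_flank)
    # apply outermost-first so inner offsets stay valid
    for v in sorted(variants, key=lambda v: -abs(v.offset)):
        k = abs(v.offset)
        if v.offset > 0:
            i = k - 1
            if v.kind == "snp":
                if down[i] != v.ref:
                    raise FlankError(f"{locus.name}: ref mismatch at +{k}")
                down[i] = v.alt
            elif v.kind == "del":
                if "".join(down[i:i + len(v.ref)]) != v.ref:
                    raise FlankError(f"{locus.name}: ref mismatch at +{k}")
                del down[i:i + len(v.ref)]
            else:  # ins between +(k-1) and +k: the first inserted base sits at +k
                down[i:i] = list(v.alt)
        else:
            i = len(up) - k
            if v.kind == "snp":
                if up[i] != v.ref:
                    raise FlankError(f"{locus.name}: ref mismatch at -{k}")
                up[i] = v.alt
            elif v.kind == "del":
                seg = "".join(up[i - len(v.ref) + 1:i + 1])
                if seg != v.ref:
                    raise FlankError(f"{locus.name}: ref mismatch at -{k}")
                del up[i - len(v.ref) + 1:i + 1]
            else:  # ins between -(k-1) and -k: the innermost inserted base sits at -k
                up[i + 1:i + 1] = list(v.alt)
    return "".join(up), "".join(down)


def render_allele(locus: LocusDefinition, array: str, flank_variants=()) -> str:
    """Full amplicon sequence: flanks (with variants applied) around an array."""
    up, down = apply_flank_variants(locus, flank_variants)
    return up + array + down


def decompose_profile(sequences, catalog: Catalog):
    """Decompose an iterable of (sample, locus_name, sequence) records.

    Returns a list of (sample, locus_name, Decomposition); decomposition of
    repeated identical sequences is cached.
    """
    cache: dict[tuple[str, str], Decomposition] = {}
    out = []
    for sample, locus_name, seq in sequences:
        locus = catalog[locus_name]
        key = (locus.name, seq)
        if key not in cache:
            cache[key] = decompose(seq, locus)
        out.append((sample, locus.name, cache[key]))
    return out
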