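"""Per-sample allele calling from per-read decompositions, and CE/MPS
concordance checking.

Reads for one (sample, locus) are grouped by identical decomposition; groups
below the analytical threshold (default 20x) are dropped. A surviving group
whose CE length sits exactly one repeat unit below a deeper co-occurring
group is masked as -1 stutter (its depth is folded into the parent's
stutter-adjusted depth); extra alleles are therefore only ever reported
outside the -1 stutter position. DYS385a,b reports two alleles per sample
(the same allele twice when homoallelic); all other loci report one primary
allele plus any surviving additional alleles.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .catalog import Catalog, LocusDefinition
from .decompose import Decomposition, decompose
from .nomenclature import AlleleName, name_allele

ANALYTICAL_THRESHOLD = 20  # reads


class CallingError(ValueError):
    pass


@dataclass(frozen=True)
class AlleleCall:
    sample: str
    locus: str
    name: AlleleName
    depth: int
    status: str  # "primary" | "additional"
    decomposition: Decomposition
    stutter_depth: int = 0  # depth of the masked -1 stutter group, if any
    homoallelic: bool = False  # second DYS385 call for a single observed allele

    @property
    def adjusted_depth(self) -> int:
        """Stutter-adjusted depth: called reads plus the -1 stutter reads
        that originate from the same template."""
        return self.depth + self.stutter_depth


def _group_reads(reads, locus: LocusDefinition):
    """Group reads by identical decomposition; returns [(decomp, depth)]."""
    by_seq: dict[str, int] = defaultdict(int)
    for item in reads:
        if isinstance(item, str):
            by_seq[item.upper()] += 1
        else:
            seq, count = item
            by_seq[seq.upper()] += int(count)
    groups: dict[Decomposition, int] = defaultdict(int)
    for seq, count in by_seq.items():
        groups[decompose(seq, locus)] += count
    return sorted(groups.items(), key=lambda kv: (-kv[1], kv[0].render()))


def call_alleles(
    reads: Iterable,
    locus: LocusDefinition,
    sample: str = "",
    threshold: int = ANALYTICAL_THRESHOLD,
    stutter_mask: bool = True,
    stutter_adjust: bool = True,
) -> list[AlleleCall]:
    """Collapse reads for one (sample, locus) into allele calls.

    ``reads``: sequences, or (sequence, count) pairs. Returns [] when no
    group reaches the analytical threshold (no-call).
    """
    groups = _group_reads(reads, locus)
    if not groups:
        raise CallingError(f"{locus.name}: empty read set")
    period = locus.period

    masked: set[int] = set()
    stutter_extra = [0] * len(groups)
    if stutter_mask:
        for i, (d, depth) in enumerate(groups):
            # candidate parents are deeper groups exactly one repeat longer
            for j, (pd_, pdepth) in enumerate(groups):
                if pdepth > depth and \
                        pd_.array_length + pd_.flank_indel_net_length == \
                        d.array_length + d.flank_indel_net_length + period:
                    masked.add(i)
                    if stutter_adjust:
                        stutter_extra[j] += depth
                    break

    survivors = [
        (i, d, depth) for i, (d, depth) in enumerate(groups)
        if i not in masked and depth >= threshold
    ]
    if not survivors:
        return []

    def make(i, d, depth, status, homo=False):
        return AlleleCall(
            sample=sample, locus=locus.name, name=name_allele(d, locus),
            depth=depth, status=status, decomposition=d,
            stutter_depth=stutter_extra[i] if stutter_adjust else 0,
            homoallelic=homo,
        )

    calls: list[AlleleCall] = []
    if locus.n_copies == 2:
        top = survivors[:2]
        if len(top) == 1:
            # homoallelic a,b combination: report the allele twice
            i, d, depth = top[0]
            calls.append(make(i, d, depth, "primary"))
            calls.append(make(i, d, depth, "primary", homo=True))
        else:
            for i, d, depth in top:
                calls.append(make(i, d, depth, "primary"))
        for i, d, depth in survivors[2:]:
            calls.append(make(i, d, depth, "additional"))
    else:
        i, d, depth = survivors[0]
        calls.append(make(i, d, depth, "primary"))
        for i, d, depth in survivors[1:]:
            calls.append(make(i, d, depth, "additional"))
    return calls


def call_read_table(
    read_table: pd.DataFrame,
    catalog: Catalog,
    threshold: int = ANALYTICAL_THRESHOLD,
    stutter_mask: bool = True,
    stutter_adjust: bool = True,
) -> list[AlleleCall]:
    """Call alleles for a whole read table (columns: sample, locus,
    sequence, count)."""
    calls: list[AlleleCall] = []
    for (sample, locus_name), sub in read_table.groupby(["sample", "locus"], sort=True):
        locus = catalog[locus_name]
        reads = list(zip(sub["sequence"], sub["count"]))
        calls.extend(call_alleles(
            reads, locus, sample=str(sample), threshold=threshold,
            stutter_mask=stutter_mask, stutter_adjust=stutter_adjust,
        ))
    return calls


def calls_to_profile(calls: Sequence[AlleleCall]) -> pd.DataFrame:
    """Tabulate calls as the standard profile DataFrame."""
    rows = []
    for c in calls:
        d = c.decomposition
        rows.append({
            "sample": c.sample,
            "locus": c.locus,
            "ce_name": c.name.ce,
            "length_name": c.name.length_based,
            "mps_name": c.name.mps,
            "depth": c.depth,
            "adjusted_depth": c.adjusted_depth,
            "status": c.status,
            "homoallelic": c.homoallelic,
            "n_flank_snps": sum(1 for v in d.flank_variants if v.kind == "snp"),
            "n_flank_indels": sum(1 for v in d.flank_variants if v.kind != "snp"),
            "n_internal_snps": d.n_internal_snps,
            "n_internal_indels": d.n_internal_indels,
            "mobility_shift": any(v.mobility_shift for v in d.flank_variants),
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# CE/MPS concordance
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class Discordance:
    sample: str
    locus: str
    mps_allele: str   # length-based name from sequencing
    ce_allele: str    # name reported by electrophoresis
    category: str     # flanking-indel | mobility-shift-SNP | primer-difference | unknown


@dataclass(frozen=True)
class ConcordanceReport:
    n_compared: int
    n_discordant: int
    records: tuple[Discordance, ...] = ()

    @property
    def pct_discordant(self) -> float:
        return round(100.0 * self.n_discordant / self.n_compared, 2) if self.n_compared else 0.0


def _allele_sort_key(name: str):
    try:
        return (0, float(name))
    except ValueError:
        return (1, name)


def concordance(mps_profile: pd.DataFrame, ce_profile: pd.DataFrame) -> ConcordanceReport:
    """Compare sequencing-derived length-based names with a CE profile.

    ``mps_profile`` needs columns sample, locus, length_name (plus, for
    category resolution, n_flank_indels and mobility_shift); ``ce_profile``
    needs sample, locus, allele. Alleles within a (sample, locus) cell are
    paired after numeric sorting; the key sets must agree.
    """
    mkeys = set(map(tuple, mps_profile[["sample", "locus"]].drop_duplicates().values))
    ckeys = set(map(tuple, ce_profile[["sample", "locus"]].drop_duplicates().values))
    if mkeys != ckeys:
        diff = mkeys.symmetric_difference(ckeys)
        raise CallingError(f"profile key sets differ on {len(diff)} (sample, locus) cells")

    has_meta = {"n_flank_indels", "mobility_shift"} <= set(mps_profile.columns)
    n = 0
    records: list[Discordance] = []
    ce_by_key = {k: g for k, g in ce_profile.groupby(["sample", "locus"], sort=False)}
    for key, mg in mps_profile.groupby(["sample", "locus"], sort=True):
        cg = ce_by_key[key]
        order = sorted(range(len(mg)), key=lambda i: _allele_sort_key(str(mg["length_name"].iloc[i])))
        mrows = mg.iloc[order]
        calleles = sorted((str(a) for a in cg["allele"]), key=_allele_sort_key)
        if len(mrows) != len(calleles):
            raise CallingError(
                f"allele count mismatch at {key}: {len(mrows)} MPS vs {len(calleles)} CE")
        for (_, mrow), ce_allele in zip(mrows.iterrows(), calleles):
            n += 1
            mps_allele = str(mrow["length_name"])
            if mps_allele == ce_allele:
                continue
            if has_meta and mrow["n_flank_indels"] > 0:
                cat = "flanking-indel"
            elif has_meta and bool(mrow["mobility_shift"]):
                cat = "mobility-shift-SNP"
            elif _allele_sort_key(mps_allele)[0] == 0 and _allele_sort_key(ce_allele)[0] == 0:
                cat = "primer-difference"
            else:
                cat = "unknown"
            records.append(Discordance(
                sample=str(mrow["sample"]), locus=str(mrow["locus"]),
                mps_allele=mps_allele, ce_allele=ce_allele, category=cat,
            ))
    return ConcordanceReport(n_compared=n, n_discordant=len(records), records=tuple(records))
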