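"""Phylogenetic classification of Y-STR sequence variants.

Variants extracted from a profile of decompositions (flanking SNPs/indels,
internal variant units and partial units, and repeat-pattern-variation (RPV)
block-count signatures) are mapped as binary presence/absence characters
onto a rooted sample phylogeny. The minimum number of state changes under
parsimony (gains and losses allowed, root state free) gives the variant's
origin count; a variant is monophyletic when its carriers are exactly the
leaf set of one node. Slow-mutating SNPs/indels are expected to be
monophyletic; rapidly slipping RPVs recurrent (polyphyletic).

Parsimony is computed by unit-cost dynamic programming over the two states,
which is exact on multifurcating trees (the Fitch union/intersection pass
generalised to k-ary nodes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import dendropy
import pandas as pd

from .catalog import Catalog
from .decompose import Decomposition

INF = float("inf")


class PhyloError(ValueError):
    pass


#: default shorthand haplogroup hierarchy (child -> parent); used to resolve
#: superhaplogroup groupings such as P containing Q and R
DEFAULT_HIERARCHY: dict[str, str] = {
    "B2b": "B2", "B2a": "B2", "B2": "B",
    "Q1a": "Q", "Q": "P", "R": "P",
    "R1a": "R1", "R1b": "R1", "R1": "R", "R2": "R",
    "G2a": "G2", "G2": "G",
    "E1b": "E", "J1": "J", "J2": "J",
    "C1a": "C", "O1": "O", "O2": "O", "N1": "N",
}


class SampleTree:
    """A rooted phylogeny over samples with per-leaf haplogroup labels."""

    def __init__(self, tree: dendropy.Tree,
                 haplogroups: Optional[Mapping[str, str]] = None,
                 hierarchy: Optional[Mapping[str, str]] = None):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise PhyloError("duplicate leaf ids in tree")
        self.leaves: frozenset[str] = frozenset(labels)
        self.haplogroups: dict[str, str] = dict(haplogroups or {})
        self.hierarchy: dict[str, str] = dict(
            hierarchy if hierarchy is not None else DEFAULT_HIERARCHY)
        # cache per-node leaf sets (bottom-up)
        self._leafsets: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._leafsets[node] = frozenset([node.taxon.label])
            else:
                s = frozenset().union(*(self._leafsets[c] for c in node.child_nodes()))
                self._leafsets[node] = s
        self._all_leafsets = frozenset(self._leafsets.values())

    # -------------------------------------------------------------- #
    @classmethod
    def from_newick(cls, source: str | Path,
                    haplogroups: Optional[Mapping[str, str]] = None,
                    hierarchy: Optional[Mapping[str, str]] = None) -> "SampleTree":
        text = Path(source).read_text() if isinstance(source, Path) else str(source)
        if isinstance(source, str) and "(" not in source:
            text = Path(source).read_text()
        tree = dendropy.Tree.get(data=text, schema="newick", rooting="default-rooted")
        return cls(tree, haplogroups=haplogroups, hierarchy=hierarchy)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def _check_carriers(self, carriers) -> frozenset[str]:
        carriers = frozenset(carriers)
        unknown = carriers - self.leaves
        if unknown:
            raise PhyloError(f"unknown sample ids: {sorted(unknown)[:5]}")
        if not carriers:
            raise PhyloError("empty carrier set")
        return carriers

    # -------------------------------------------------------------- #
    def count_origins(self, carriers: Iterable[str]) -> int:
        """Minimum number of presence/absence state changes on the tree
        (gains and losses both allowed, root state free). A non-empty
        carrier set implies at least one origin, so the floor is 1."""
        carriers = self._check_carriers(carriers)
        cost: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                state = 1 if node.taxon.label in carriers else 0
                cost[node] = (INF, 0.0) if state else (0.0, INF)
            else:
                c0 = c1 = 0.0
                for child in node.child_nodes():
                    k0, k1 = cost[child]
                    c0 += min(k0, k1 + 1)
                    c1 += min(k1, k0 + 1)
                cost[node] = (c0, c1)
        changes = min(cost[self.tree.seed_node])
        return max(1, int(changes))

    def is_monophyletic(self, carriers: Iterable[str]) -> bool:
        """True iff the carriers are exactly the leaf set of one node."""
        return self._check_carriers(carriers) in self._all_leafsets

    # -------------------------------------------------------------- #
    def label_of(self, leaf: str) -> Optional[str]:
        return self.haplogroups.get(leaf)

    def _ancestor_chain(self, label: str) -> list[str]:
        chain = [label]
        while label in self.hierarchy:
            label = self.hierarchy[label]
            chain.append(label)
        return chain

    def associate_haplogroups(self, carriers: Iterable[str]):
        """Haplogroup labels among carriers, a common (super)haplogroup if
        the hierarchy provides one, and exclusivity flags."""
        carriers = self._check_carriers(carriers)
        labels = {self.haplogroups[s] for s in carriers if s in self.haplogroups}
        exclusive = not any(
            self.haplogroups.get(s) in labels
            for s in self.leaves - carriers
        ) if labels else False
        common: Optional[str] = None
        if labels:
            chains = [self._ancestor_chain(l) for l in labels]
            for cand in chains[0]:
                if all(cand in c for c in chains):
                    common = cand
                    break
        common_exclusive = False
        if common is not None:
            common_exclusive = not any(
                common in self._ancestor_chain(self.haplogroups.get(s, ""))
                for s in self.leaves - carriers
            )
        return HaplogroupAssociation(
            labels=frozenset(labels), exclusive=exclusive,
            common=common, common_exclusive=common_exclusive,
        )


@dataclass(frozen=True)
class HaplogroupAssociation:
    labels: frozenset[str]
    exclusive: bool
    common: Optional[str]
    common_exclusive: bool


@dataclass(frozen=True)
class VariantRecord:
    """One sequence variant (SNP/indel/RPV) with its carriers and, once
    classified against a tree, its phylogenetic status."""

    variant_id: str
    locus: str
    kind: str       # "SNP" | "indel" | "RPV"
    location: str   # "internal" | "flanking"
    detail: str     # descriptor / unit / block-count signature
    carriers: frozenset[str]
    origins: int = 0
    monophyletic: bool = False
    singleton: bool = False
    associated_haplogroups: frozenset[str] = frozenset()
    exclusive: bool = False


# --------------------------------------------------------------------------- #
# variant extraction from profiles of decompositions
# --------------------------------------------------------------------------- #
def extract_variants(
    profile: Iterable[tuple[str, str, Decomposition]],
    catalog: Catalog,
) -> list[VariantRecord]:
    """One record per distinct flanking variant, internal variant/partial
    unit, and RPV block-count signature (signatures that share their array
    length with a different signature at the same locus)."""
    profile = list(profile)
    flank: dict[tuple[str, str, str], set[str]] = {}
    internal: dict[tuple[str, str, str], set[str]] = {}
    # (locus, signature) -> carriers ; (locus, length) -> signatures
    rpv_carriers: dict[tuple[str, tuple[int, ...]], set[str]] = {}
    rpv_lengths: dict[tuple[str, int], set[tuple[int, ...]]] = {}

    for sample, locus_name, d in profile:
        locus = catalog[locus_name]
        for v in d.flank_variants:
            kind = "SNP" if v.kind == "snp" else "indel"
            flank.setdefault((locus.name, v.descriptor, kind), set()).add(sample)
        for u in d.units:
            if u.role == "variant":
                internal.setdefault((locus.name, u.seq, "SNP"), set()).add(sample)
            elif u.role == "partial":
                internal.setdefault((locus.name, u.seq, "indel"), set()).add(sample)
        if len([b for b in locus.repeat_blocks]) > 1:
            sig = d.block_counts(locus)
            rpv_carriers.setdefault((locus.name, sig), set()).add(sample)
            rpv_lengths.setdefault((locus.name, d.array_length), set()).add(sig)

    records: list[VariantRecord] = []
    for (locus_name, desc, kind), carriers in sorted(flank.items()):
        records.append(VariantRecord(
            variant_id=f"{locus_name}:flank:{desc}", locus=locus_name, kind=kind,
            location="flanking", detail=desc, carriers=frozenset(carriers)))
    for (locus_name, unit, kind), carriers in sorted(internal.items()):
        records.append(VariantRecord(
            variant_id=f"{locus_name}:internal:{unit}", locus=locus_name, kind=kind,
            location="internal", detail=unit, carriers=frozenset(carriers)))
    for (locus_name, sig), carriers in sorted(rpv_carriers.items()):
        locus = catalog[locus_name]
        length = sum(
            len(b.motif) if b.fixed_spacer else n * len(b.motif)
            for b, n in zip(locus.blocks, sig))
        # RPV only where >= 2 distinct signatures share an array length
        shared = {
            s for lname, l in rpv_lengths
            if lname == locus_name
            for s in rpv_lengths[(lname, l)]
            if l == length
        }
        if len(shared) < 2:
            continue
        detail = "/".join(str(n) for n in sig)
        records.append(VariantRecord(
            variant_id=f"{locus_name}:RPV:{detail}", locus=locus_name, kind="RPV",
            location="internal", detail=detail, carriers=frozenset(carriers)))
    return records


def classify_variants(records: Iterable[VariantRecord],
                      tree: SampleTree) -> list[VariantRecord]:
    """Fill origins, monophyly, singleton and haplogroup-association fields."""
    out = []
    for rec in records:
        carriers = rec.carriers & tree.leaves
        if not carriers:
            out.append(rec)
            continue
        assoc = tree.associate_haplogroups(carriers)
        out.append(replace(
            rec,
            carriers=carriers,
            origins=tree.count_origins(carriers),
            monophyletic=tree.is_monophyletic(carriers),
            singleton=len(carriers) == 1,
            associated_haplogroups=assoc.labels,
            exclusive=assoc.common_exclusive or assoc.exclusive,
        ))
    return out


def variants_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "variant_id": r.variant_id, "locus": r.locus, "kind": r.kind,
        "location": r.location, "detail": r.detail,
        "n_carriers": len(r.carriers),
        "carriers": ";".join(sorted(r.carriers)),
        "origins": r.origins, "monophyletic": r.monophyletic,
        "singleton": r.singleton,
        "haplogroups": ";".join(sorted(r.associated_haplogroups)),
        "exclusive": r.exclusive,
    } for r in records])


def presence_matrix(records: Iterable[VariantRecord],
                    samples: Iterable[str]) -> pd.DataFrame:
    """0/1 variants x samples matrix for figure-style summaries."""
    samples = list(samples)
    records = list(records)
    data = {
        r.variant_id: [1 if s in r.carriers else 0 for s in samples]
        for r in records
    }
    return pd.DataFrame(data, index=samples).T
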