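"""Phylogenetically structured synthetic Y-STR datasets.

The generator emulates the study design every pipeline stage expects: a
rooted 100-sample phylogeny with haplogroup-labelled clades; rare SNP/indel
events placed once on single branches (mimicking their ~1e-8 per-generation
mutation rate, so each event is monophyletic by construction); block-wise
stepwise slippage applied independently on every branch at a much higher
rate (mimicking the ~1e-3 repeat-array rate and allowing recurrence);
per-allele read depths drawn from a truncated lognormal spanning the
251-11,600x range observed with the analytical threshold of 20x; a fraction
of reads rendered at the -1 stutter position; and, among the 100 samples,
5 constitutive duplications (two alleles at full dose each) and 6 somatic
mutants (one dose split between two alleles, the extra allele never at the
-1 stutter position).

All randomness flows through one seeded generator: identical configurations
give byte-identical outputs, and every read traces to exactly one truth
allele recorded in the ledger.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import Catalog, LocusDefinition, load_catalog
from .decompose import FlankVariant, decompose, render_allele
from .nomenclature import mps_name
from .phylo import SampleTree


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 100
    seed: int = 0
    snp_indel_events: int = 15
    slippage_rate: float = 0.01     # per counted block per branch
    depth_median: float = 1500.0    # reads per single-dose allele
    depth_cv: float = 0.15
    min_depth: int = 251
    max_depth: int = 11600
    stutter_rate: float = 0.10      # fraction of reads at -1 repeat
    n_duplications: int = 5
    n_somatic: int = 6
    somatic_fraction: tuple[float, float] = (0.30, 0.45)
    haplogroup_min_clades: int = 8
    tree_newick: Optional[str] = None

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for rate in (self.slippage_rate, self.stutter_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")


# --------------------------------------------------------------------------- #
# tree simulation
# --------------------------------------------------------------------------- #
class _Node:
    __slots__ = ("name", "children", "parent")

    def __init__(self, name=None):
        self.name = name
        self.children: list["_Node"] = []
        self.parent: Optional["_Node"] = None

    def add(self, child: "_Node"):
        child.parent = self
        self.children.append(child)

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        def rec(n):
            if not n.children:
                return f"{n.name}:1"
            return "(" + ",".join(rec(c) for c in n.children) + "):1"
        return rec(self)[:-2] + ";"


def _random_tree(n: int, rng: np.random.Generator) -> _Node:
    """Rooted binary tree by sequential random edge attachment."""
    names = [f"S{i + 1:03d}" for i in range(n)]
    root = _Node()
    a, b_ = _Node(names[0]), _Node(names[1])
    root.add(a)
    root.add(b_)
    edges = [a, b_]  # each edge identified by its child node
    for name in names[2:]:
        child = edges[rng.integers(len(edges))]
        parent = child.parent
        mid = _Node()
        parent.children[parent.children.index(child)] = mid
        mid.parent = parent
        mid.add(child)
        leaf = _Node(name)
        mid.add(leaf)
        edges.append(mid)
        edges.append(leaf)
    return root


def _label_haplogroups(root: _Node, min_clades: int) -> dict[str, str]:
    """Cut the tree below the root into >= min_clades subtrees and label
    each subtree's leaves with a shorthand haplogroup name."""
    frontier: list[_Node] = [root]
    while len(frontier) < min_clades:
        expandable = [n for n in frontier if n.children]
        if not expandable:
            break
        biggest = max(expandable, key=lambda n: len(n.leaves()))
        frontier.remove(biggest)
        frontier.extend(biggest.children)
    labels: dict[str, str] = {}
    for i, node in enumerate(frontier):
        for leaf in node.leaves():
            labels[leaf.name] = f"HG{i + 1:02d}"
    return labels


def simulate_tree(config: SimulationConfig):
    """Build (or load) the sample tree; returns (root node, SampleTree)."""
    rng = np.random.default_rng(config.seed)
    if config.tree_newick is not None:
        stree = SampleTree.from_newick(config.tree_newick)
        return None, stree
    root = _random_tree(config.n_samples, rng)
    labels = _label_haplogroups(root, config.haplogroup_min_clades)
    stree = SampleTree.from_newick(root.newick(), haplogroups=labels)
    return root, stree


# --------------------------------------------------------------------------- #
# mutation placement
# --------------------------------------------------------------------------- #
def _edges_preorder(root: _Node):
    out = []
    stack = [root]
    while stack:
        node = stack.pop()
        for child in reversed(node.children):
            out.append((node, child))
            stack.append(child)
    return out


def _legal_vector(locus: LocusDefinition, vec) -> bool:
    """Bounds plus canonical-parse safety: after dropping zero blocks no two
    adjacent repeat blocks may share a motif (the parse would merge them),
    and a zero block may not precede a later same-motif block with copies
    (greedy parsing would re-attribute that run to the earlier block)."""
    prev_motif = None
    for bi, (block, n) in enumerate(zip(locus.blocks, vec)):
        if block.fixed_spacer:
            prev_motif = None  # spacer separates runs
            continue
        if not block.min_repeats <= n <= block.max_repeats:
            return False
        if n > 0:
            if block.motif == prev_motif:
                return False
            prev_motif = block.motif
        else:
            for later, m in zip(vec[bi + 1:], locus.blocks[bi + 1:]):
                if not m.fixed_spacer and m.motif == block.motif and later > 0:
                    return False
    return True


def _canonical_vector(locus: LocusDefinition) -> tuple[int, ...]:
    return tuple(1 if b.fixed_spacer else b.canonical for b in locus.blocks)


def random_legal_vector(locus: LocusDefinition, rng: np.random.Generator) -> tuple[int, ...]:
    """Uniformly sample per-block copy numbers within the catalogue ranges,
    rejecting vectors whose rendering would not re-parse to the same counts
    (zero blocks between same-motif runs)."""
    for _ in range(200):
        vec = tuple(
            1 if b.fixed_spacer else int(rng.integers(b.min_repeats, b.max_repeats + 1))
            for b in locus.blocks)
        if _legal_vector(locus, vec):
            return vec
    raise RuntimeError(f"{locus.name}: could not sample a legal vector")


def _step_block(locus, vec, bi, delta):
    new = list(vec)
    new[bi] += delta
    return tuple(new) if _legal_vector(locus, new) else None


@dataclass(frozen=True)
class _Event:
    """A SNP/indel event placed on one branch."""

    event_id: str
    locus: str
    copy: int
    kind: str  # flank_snp | flank_del | flank_ins | internal_snp | internal_partial
    detail: tuple
    branch: str          # child-node identifier (leaf name or internal index)
    carriers: frozenset


def _mutate_motif(motif: str, rng, forbidden: set[str]) -> Optional[str]:
    order = rng.permutation(len(motif))
    for i in order:
        for base in "ACGT":
            if base != motif[i]:
                cand = motif[:i] + base + motif[i + 1:]
                if cand not in forbidden:
                    return cand
    return None


def _render_array(locus: LocusDefinition, vec, internal_events) -> str:
    """Array DNA from a block-count vector plus internal events
    (block_index -> ('snp', variant_motif) or ('partial', seq))."""
    parts = []
    for bi, (block, n) in enumerate(zip(locus.blocks, vec)):
        if block.fixed_spacer:
            parts.append(block.motif)
            continue
        ev = internal_events.get(bi)
        if ev is None:
            parts.append(block.motif * n)
        elif ev[0] == "snp":
            parts.append(block.motif * (n - 1) + ev[1])
        else:  # partial inserted before the last two units
            parts.append(block.motif * (n - 2) + ev[1] + block.motif * 2)
    return "".join(parts)


def _truth_designation(locus: LocusDefinition, vec, internal_events,
                       flank_variants) -> str:
    """Designation constructed by generator bookkeeping (independent of the
    decomposition parser): units from the vector and events, CE name from
    counted sums, uncounted-block shifts and partial residues."""
    k = locus.ce_offset
    r = 0
    length = 0
    parts = []
    for bi, (block, n) in enumerate(zip(locus.blocks, vec)):
        if block.fixed_spacer:
            parts.append(f"N[{len(block.motif)}]")
            length += len(block.motif)
            continue
        ev = internal_events.get(bi)
        n_units = n
        if ev is None:
            if n > 0:
                parts.append(f"{block.motif}[{n}]")
            elif not block.counted:
                parts.append(f"{block.motif}[0]")
        elif ev[0] == "snp":
            if n - 1 > 0:
                parts.append(f"{block.motif}[{n - 1}]")
            parts.append(f"{ev[1]}[1]")
        else:
            if n - 2 > 0:
                parts.append(f"{block.motif}[{n - 2}]")
            parts.append(f"{ev[1]}[1]")
            parts.append(f"{block.motif}[2]")
            r += len(ev[1])
            length += len(ev[1])
        length += n * len(block.motif)
        if block.counted:
            k += n_units
        else:
            k += n_units - block.canonical
    net = sum(v.net_length for v in flank_variants)
    delta = length + net - locus.reference_array_length
    lb_k = locus.reference_ce + delta // locus.period
    lb_r = delta % locus.period
    prefix = f"{lb_k}.{lb_r}" if lb_r else str(lb_k)
    name = f"CE{prefix}_" + "".join(parts)
    for v in sorted(flank_variants, key=lambda v: v.offset):
        name += f"_{v.descriptor}"
    return name


def _locus_keys(catalog: Catalog):
    keys = []
    for locus in catalog:
        for copy in range(locus.n_copies):
            keys.append((locus.name, copy))
    return keys


def place_mutations(root: _Node, stree: SampleTree, catalog: Catalog,
                    config: SimulationConfig, rng: np.random.Generator):
    """Evolve block-count vectors by branchwise slippage and place SNP/indel
    events on single branches. Returns (alleles table, events table)."""
    edges = _edges_preorder(root)
    node_ids = {}
    for i, (_, child) in enumerate(edges):
        node_ids[id(child)] = child.name or f"node{i}"
    keys = _locus_keys(catalog)

    # root states
    root_vec = {}
    for name, copy in keys:
        locus = catalog[name]
        vec = list(_canonical_vector(locus))
        if locus.n_copies == 2 and copy == 1:
            # second copy starts at a shorter allele so the pair is heteroallelic
            main = max(
                (i for i, b in enumerate(locus.blocks) if b.counted),
                key=lambda i: vec[i])
            vec[main] = max(locus.blocks[main].min_repeats, vec[main] - 3)
        root_vec[(name, copy)] = tuple(vec)

    # --- slippage along edges ------------------------------------------------
    vectors = {id(root): root_vec}
    slippage_rows = []
    for parent, child in edges:
        state = dict(vectors[id(parent)])
        for key in keys:
            locus = catalog[key[0]]
            vec = state[key]
            for bi, block in enumerate(locus.blocks):
                if block.fixed_spacer or block.min_repeats == block.max_repeats:
                    continue
                if rng.random() >= config.slippage_rate:
                    continue
                delta = 1 if rng.random() < 0.5 else -1
                new = _step_block(locus, vec, bi, delta)
                if new is None:
                    new = _step_block(locus, vec, bi, -delta)
                    delta = -delta
                if new is None:
                    continue
                vec = new
                slippage_rows.append({
                    "event_id": f"slip{len(slippage_rows) + 1}",
                    "kind": "slippage", "locus": key[0], "copy": key[1],
                    "branch": node_ids[id(child)], "detail": f"block{bi}{delta:+d}",
                    "carriers": ";".join(sorted(l.name for l in child.leaves())),
                })
            state[key] = vec
        vectors[id(child)] = state

    # --- SNP/indel events ----------------------------------------------------
    events: list[_Event] = []
    used_flank: set = set()
    used_internal: set = set()
    attempt = 0
    while len(events) < config.snp_indel_events and attempt < 2000:
        attempt += 1
        parent, child = edges[rng.integers(len(edges))]
        key = keys[rng.integers(len(keys))]
        locus = catalog[key[0]]
        kind = ["flank_snp", "flank_del", "flank_ins",
                "internal_snp", "internal_partial"][rng.integers(5)]
        carriers = frozenset(l.name for l in child.leaves())
        detail = None
        if kind.startswith("flank"):
            side = 1 if rng.random() < 0.5 else -1
            offset = side * int(rng.integers(3, locus.flank_window - 6))
            if (key[0], offset) in used_flank:
                continue
            flank = locus.downstream_flank if side > 0 else locus.upstream_flank
            if kind == "flank_snp":
                ref = flank[offset - 1] if side > 0 else flank[len(flank) + offset]
                alt = "ACGT"[rng.integers(4)]
                if alt == ref:
                    continue
                fv = FlankVariant(offset=offset, kind="snp", ref=ref, alt=alt)
            elif kind == "flank_del":
                d = int(rng.integers(1, 4))
                if side > 0:
                    ref = flank[offset - 1:offset - 1 + d]
                else:
                    i = len(flank) + offset
                    ref = flank[i - d + 1:i + 1]
                if len(ref) < d:
                    continue
                fv = FlankVariant(offset=offset, kind="del", ref=ref, alt="-")
            else:
                d = int(rng.integers(1, 4))
                alt = "".join("ACGT"[rng.integers(4)] for _ in range(d))
                fv = FlankVariant(offset=offset, kind="ins", ref="-", alt=alt)
            # validate: applying then re-decomposing must recover the variant
            try:
                test = render_allele(
                    locus, locus.render_array(_canonical_vector(locus)), [fv])
                got = decompose(test, locus).flank_variants
            except Exception:
                continue
            if [v.descriptor for v in got] != [fv.descriptor]:
                continue
            used_flank.add((key[0], offset))
            detail = ("flank", fv)
        else:
            counted = [i for i, b in enumerate(locus.blocks)
                       if b.counted and not b.fixed_spacer]
            bi = counted[rng.integers(len(counted))]
            if (key[0], bi) in used_internal:
                continue
            block = locus.blocks[bi]
            motifs = set(locus.motifs)
            if kind == "internal_snp":
                var = _mutate_motif(block.motif, rng, motifs)
                if var is None:
                    continue
                ev = ("snp", var)
            else:
                if block.min_repeats < 3:
                    continue
                cands = [block.motif[2:], block.motif[:2], block.motif[1:3]]
                ev = None
                for partial in cands:
                    if 0 < len(partial) < locus.period:
                        ev = ("partial", partial)
                        break
                if ev is None:
                    continue
            # validate designation construction == parser output on a test allele
            vec = _canonical_vector(locus)
            try:
                seq = render_allele(locus, _render_array(locus, vec, {bi: ev}), [])
                got = mps_name(decompose(seq, locus), locus)
            except Exception:
                continue
            if got != _truth_designation(locus, vec, {bi: ev}, []):
                continue
            used_internal.add((key[0], bi))
            detail = ("internal", bi, ev)
        events.append(_Event(
            event_id=f"ev{len(events) + 1}", locus=key[0], copy=key[1],
            kind=kind, detail=detail, branch=node_ids[id(child)],
            carriers=carriers,
        ))

    # --- per-leaf alleles ----------------------------------------------------
    allele_rows = []
    for leaf in root.leaves():
        state = vectors[id(leaf)]
        for key in keys:
            locus = catalog[key[0]]
            vec = state[key]
            internal: dict[int, tuple] = {}
            flanks: list[FlankVariant] = []
            for ev in events:
                if (ev.locus, ev.copy) != key or leaf.name not in ev.carriers:
                    continue
                if ev.detail[0] == "flank":
                    flanks.append(ev.detail[1])
                else:
                    internal[ev.detail[1]] = ev.detail[2]
            # guard: internal events need enough units in the block
            for bi, ev in list(internal.items()):
                need = 1 if ev[0] == "snp" else 2
                if vec[bi] < need:
                    del internal[bi]
            array = _render_array(locus, vec, internal)
            seq = render_allele(locus, array, flanks)
            allele_rows.append({
                "sample": leaf.name, "locus": key[0], "copy": key[1],
                "vector": vec,
                "flanks": tuple(flanks),
                "designation": _truth_designation(locus, vec, internal, flanks),
                "sequence": seq,
            })
    alleles = pd.DataFrame(allele_rows)
    event_rows = [{
        "event_id": e.event_id, "kind": e.kind, "locus": e.locus, "copy": e.copy,
        "branch": e.branch,
        "detail": (e.detail[1].descriptor if e.detail[0] == "flank"
                   else f"block{e.detail[1]}:{e.detail[2][0]}:{e.detail[2][1]}"),
        "carriers": ";".join(sorted(e.carriers)),
    } for e in events]
    events_df = pd.DataFrame(event_rows + slippage_rows)
    return alleles, events_df


# --------------------------------------------------------------------------- #
# read emission
# --------------------------------------------------------------------------- #
def _draw_depth(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.depth_cv <= 0:
        return int(round(config.depth_median))
    sigma = float(np.sqrt(np.log1p(config.depth_cv ** 2)))
    mu = float(np.log(config.depth_median))
    d = int(round(float(rng.lognormal(mu, sigma))))
    return int(min(max(d, config.min_depth), config.max_depth))


def _stutter_sequence(locus: LocusDefinition, vec, sequence: str):
    """Sequence with one fewer repeat in the longest counted block, or None."""
    counted = [(i, n) for i, (b, n) in enumerate(zip(locus.blocks, vec))
               if b.counted and not b.fixed_spacer]
    if not counted:
        return None
    bi, n = max(counted, key=lambda t: t[1])
    if _step_block(locus, vec, bi, -1) is None:
        return None
    motif = locus.blocks[bi].motif
    run = motif * n
    pos = sequence.find(run)
    if pos < 0:
        return None  # block interrupted by an internal event; skip stutter
    return sequence[:pos] + motif * (n - 1) + sequence[pos + len(run):]


def _extra_allele(locus: LocusDefinition, vec, deltas):
    """A second allele obtained by stepping the largest counted block."""
    counted = [(i, n) for i, (b, n) in enumerate(zip(locus.blocks, vec))
               if b.counted and not b.fixed_spacer]
    bi, _ = max(counted, key=lambda t: t[1])
    for delta in deltas:
        new = _step_block(locus, vec, bi, delta)
        if new is not None:
            return new
    return None


def emit_reads(alleles: pd.DataFrame, catalog: Catalog,
               config: SimulationConfig, rng: np.random.Generator):
    """Draw depths, add stutter, and inject duplications/somatic mutants.

    Returns (read table, truth-dose table, extra-allele truth table).
    """
    single_copy = [l.name for l in catalog if l.n_copies == 1]
    samples = sorted(alleles["sample"].unique())
    pool = [(s, l) for l in single_copy for s in samples]
    order = rng.permutation(len(pool))
    picked = [pool[i] for i in order[:config.n_duplications + config.n_somatic]]
    dup_cells = set(picked[:config.n_duplications])
    som_cells = set(picked[config.n_duplications:])

    read_rows = []
    dose_rows = []
    extra_rows = []

    def emit(sample, locus, seq, depth, allele_id):
        n_st = 0
        if config.stutter_rate > 0 and depth > 0:
            st = None
            row = alleles[(alleles["sample"] == sample) & (alleles["locus"] == locus.name)]
            # stutter built from this allele's vector
            st = _stutter_sequence(locus, allele_vectors[allele_id], seq)
            if st is not None:
                n_st = int(rng.binomial(depth, config.stutter_rate))
                if n_st:
                    read_rows.append({"sample": sample, "locus": locus.name,
                                      "sequence": st, "count": n_st,
                                      "source_allele": allele_id, "is_stutter": True})
        if depth - n_st > 0:
            read_rows.append({"sample": sample, "locus": locus.name,
                              "sequence": seq, "count": depth - n_st,
                              "source_allele": allele_id, "is_stutter": False})

    allele_vectors = {}
    for (sample, locus_name), sub in alleles.groupby(["sample", "locus"], sort=True):
        locus = catalog[locus_name]
        cell_alleles = []
        for _, row in sub.sort_values("copy").iterrows():
            aid = f"{sample}|{locus_name}|{row['copy']}"
            allele_vectors[aid] = row["vector"]
            cell_alleles.append((aid, row["vector"], row["sequence"], row["designation"]))

        extra = None
        if (sample, locus_name) in dup_cells:
            extra_kind = "duplication"
            new_vec = _extra_allele(locus, cell_alleles[0][1], (2, -2, 3))
        elif (sample, locus_name) in som_cells:
            extra_kind = "somatic"
            new_vec = _extra_allele(locus, cell_alleles[0][1], (1, 2, -2))
        else:
            new_vec = None
        if new_vec is not None:
            # extras arise on the same chromosome background, so they carry
            # the primary allele's flanking variants
            primary_flanks = tuple(sub.sort_values("copy").iloc[0]["flanks"])
            array = _render_array(locus, new_vec, {})
            seq = render_allele(locus, array, primary_flanks)
            aid = f"{sample}|{locus_name}|extra"
            allele_vectors[aid] = new_vec
            desig = _truth_designation(locus, new_vec, {}, primary_flanks)
            extra = (aid, new_vec, seq, desig, extra_kind)
            extra_rows.append({"sample": sample, "locus": locus_name,
                               "verdict": extra_kind, "designation": desig})

        if extra is not None and extra[4] == "somatic":
            dose = _draw_depth(config, rng)
            frac = float(rng.uniform(*config.somatic_fraction))
            d_extra = int(round(dose * frac))
            d_main = dose - d_extra
            emit(sample, locus, cell_alleles[0][2], d_main, cell_alleles[0][0])
            emit(sample, locus, extra[2], d_extra, extra[0])
            dose_rows.append({"sample": sample, "locus": locus_name,
                              "allele_id": cell_alleles[0][0], "dose": d_main,
                              "designation": cell_alleles[0][3], "dose_class": "split"})
            dose_rows.append({"sample": sample, "locus": locus_name,
                              "allele_id": extra[0], "dose": d_extra,
                              "designation": extra[3], "dose_class": "split"})
        else:
            emitted = list(cell_alleles)
            if extra is not None:
                emitted.append(extra[:4])
            for aid, vec, seq, desig in [e[:4] for e in emitted]:
                dose = _draw_depth(config, rng)
                emit(sample, locus, seq, dose, aid)
                dose_rows.append({"sample": sample, "locus": locus_name,
                                  "allele_id": aid, "dose": dose,
                                  "designation": desig, "dose_class": "full"})

    reads = pd.DataFrame(read_rows)
    # merge identical sequences within a cell (e.g. stutter coinciding with a
    # co-occurring shorter allele keeps separate provenance rows; the caller
    # aggregates by sequence)
    doses = pd.DataFrame(dose_rows)
    extras = pd.DataFrame(extra_rows,
                          columns=["sample", "locus", "verdict", "designation"])
    return reads, doses, extras


# --------------------------------------------------------------------------- #
# orchestration
# --------------------------------------------------------------------------- #
@dataclass
class SimulatedDataset:
    config: SimulationConfig
    tree: SampleTree
    newick: str
    haplogroups: dict[str, str]
    alleles: pd.DataFrame      # truth alleles: sample, locus, copy, designation, sequence
    events: pd.DataFrame       # truth ledger of mutation events
    reads: pd.DataFrame        # sample, locus, sequence, count, provenance
    doses: pd.DataFrame        # drawn per-allele doses
    extras: pd.DataFrame       # injected duplication/somatic truth


def simulate_dataset(config: SimulationConfig,
                     catalog: Optional[Catalog] = None) -> SimulatedDataset:
    """Run the full generator: tree, mutations, alleles, reads, truth ledger."""
    catalog = catalog or load_catalog()
    root, stree = simulate_tree(config)
    if root is None:
        raise ValueError("simulate_dataset requires a generated tree "
                         "(tree_newick input is supported by place_mutations only)")
    rng = np.random.default_rng(config.seed + 1)
    alleles, events = place_mutations(root, stree, catalog, config, rng)
    reads, doses, extras = emit_reads(alleles, catalog, config, rng)
    return SimulatedDataset(
        config=config, tree=stree, newick=root.newick(),
        haplogroups=dict(stree.haplogroups),
        alleles=alleles, events=events, reads=reads, doses=doses, extras=extras,
    )
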