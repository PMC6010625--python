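"""Parsimony origin counts, monophyly, haplogroup association, extraction."""

import itertools

import numpy as np
import pytest

from ystrmps.phylo import (
    PhyloError,
    SampleTree,
    classify_variants,
    extract_variants,
    presence_matrix,
)
from ystrmps.simulate import _random_tree


def brute_force_min_changes(tree: SampleTree, carriers) -> int:
    """Exhaustive minimum over all ancestral 0/1 assignments (oracle)."""
    nodes = list(tree.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    best = None
    for bits in itertools.product((0, 1), repeat=len(internal)):
        state = {id(n): b for n, b in zip(internal, bits)}
        for lf in leaves:
            state[id(lf)] = 1 if lf.taxon.label in carriers else 0
        changes = 0
        for n in nodes:
            for c in n.child_nodes():
                if state[id(n)] != state[id(c)]:
                    changes += 1
        if best is None or changes < best:
            best = changes
    return max(1, best)


def random_sample_tree(n, rng):
    return SampleTree.from_newick(_random_tree(n, rng).newick())


class TestCountOrigins:
    def test_single_leaf_carrier(self, rng):
        t = random_sample_tree(8, rng)
        leaf = sorted(t.leaves)[0]
        assert t.count_origins([leaf]) == 1
        assert t.is_monophyletic([leaf])

    def test_full_clade_is_one_origin(self, rng):
        t = random_sample_tree(10, rng)
        for node in t.tree.postorder_node_iter():
            carriers = t._leafsets[node]
            assert t.count_origins(carriers) == 1
            assert t.is_monophyletic(carriers)

    def test_all_leaves_root_clade(self, rng):
        t = random_sample_tree(9, rng)
        assert t.is_monophyletic(t.leaves)
        assert t.count_origins(t.leaves) == 1

    def test_matches_exhaustive_oracle(self, rng):
        """>= 500 random carrier sets on trees of <= 12 leaves equal the
        brute-force minimum over all ancestral assignments."""
        checked = 0
        while checked < 500:
            n = int(rng.integers(4, 13))
            t = random_sample_tree(n, rng)
            leaves = sorted(t.leaves)
            for _ in range(10):
                mask = rng.random(n) < rng.uniform(0.2, 0.8)
                carriers = {l for l, m in zip(leaves, mask) if m}
                if not carriers:
                    continue
                assert t.count_origins(carriers) == \
                    brute_force_min_changes(t, carriers), (t.as_newick(), carriers)
                checked += 1

    def test_monophyly_implies_single_origin(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            t = random_sample_tree(n, rng)
            leaves = sorted(t.leaves)
            mask = rng.random(n) < 0.5
            carriers = {l for l, m in zip(leaves, mask) if m}
            if carriers and t.is_monophyletic(carriers):
                assert t.count_origins(carriers) == 1

    def test_reroot_invariance(self, rng):
        """Origin counts are invariant to re-rooting along any edge."""
        import dendropy

        for _ in range(10):
            t = random_sample_tree(8, rng)
            leaves = sorted(t.leaves)
            mask = rng.random(8) < 0.5
            carriers = {l for l, m in zip(leaves, mask) if m} or {leaves[0]}
            base = t.count_origins(carriers)
            for edge_node in list(t.tree.preorder_node_iter())[2:5]:
                clone = dendropy.Tree(t.tree)
                node = clone.find_node(
                    lambda n: t._leafsets.get(edge_node) is not None
                    and {lf.taxon.label for lf in n.leaf_iter()}
                    == set(t._leafsets[edge_node]))
                if node is None or node.edge.head_node is clone.seed_node:
                    continue
                clone.reroot_at_edge(node.edge, update_bipartitions=False)
                t2 = SampleTree(clone)
                assert t2.count_origins(carriers) == base

    def test_unknown_sample_rejected(self, rng):
        t = random_sample_tree(6, rng)
        with pytest.raises(PhyloError, match="unknown"):
            t.count_origins(["nope"])

    def test_polytomy_support(self):
        t = SampleTree.from_newick("((a,b,c),(d,e,f));")
        assert t.count_origins(["a", "b", "c"]) == 1
        assert t.count_origins(["a", "d"]) == 2
        assert t.is_monophyletic(["d", "e", "f"])


class TestHaplogroupAssociation:
    def test_exclusive_single_label(self):
        t = SampleTree.from_newick(
            "((b1,b2,b3),(x1,x2));",
            haplogroups={"b1": "B2", "b2": "B2", "b3": "B2", "x1": "E", "x2": "E"})
        assoc = t.associate_haplogroups(["b1", "b2", "b3"])
        assert assoc.labels == {"B2"} and assoc.exclusive

    def test_superhaplogroup_resolution(self):
        t = SampleTree.from_newick(
            "(((q1,q2),(r1,r2)),(e1,e2));",
            haplogroups={"q1": "Q", "q2": "Q", "r1": "R1a", "r2": "R2",
                         "e1": "E", "e2": "E"})
        assoc = t.associate_haplogroups(["q1", "q2", "r1", "r2"])
        assert assoc.common == "P" and assoc.common_exclusive

    def test_spanning_labels_not_exclusive(self):
        t = SampleTree.from_newick(
            "((a1,a2),(j1,j2));",
            haplogroups={"a1": "E", "a2": "E", "j1": "J", "j2": "J"})
        assoc = t.associate_haplogroups(["a1", "j1"])
        assert assoc.labels == {"E", "J"} and not assoc.exclusive


class TestReferenceFixture:
    def test_dys635_rpv_monophyletic_in_15_superhaplogroup_p(self, catalog,
                                                             reference_fixture):
        fx, profile = reference_fixture
        recs = classify_variants(extract_variants(profile, catalog), fx.tree)
        rec = next(r for r in recs if r.variant_id == "DYS635:RPV:10/2/2/2/2/2/3")
        assert len(rec.carriers) == 15
        assert rec.monophyletic and rec.origins == 1
        assert rec.carriers == fx.carriers["DYS635_RPV_P"]

    def test_dys389ii_caga_blocks(self, catalog, reference_fixture):
        fx, profile = reference_fixture
        recs = classify_variants(extract_variants(profile, catalog), fx.tree)
        caga6 = next(r for r in recs if r.variant_id.endswith("10/3/0/10/6"))
        assert caga6.monophyletic and len(caga6.carriers) == 14
        caga4 = next(r for r in recs if r.variant_id.endswith("10/3/0/12/4"))
        assert not caga4.monophyletic and caga4.origins > 1

    def test_dys391_flank_snp_in_b2(self, catalog, reference_fixture):
        fx, profile = reference_fixture
        recs = classify_variants(extract_variants(profile, catalog), fx.tree)
        rec = next(r for r in recs if r.variant_id == "DYS391:flank:+50C>A")
        assert len(rec.carriers) == 9
        assert rec.monophyletic and rec.exclusive

    def test_dys481_ctg2_with_ctt20_confined_to_g2a(self, catalog,
                                                    reference_fixture):
        fx, profile = reference_fixture
        recs = classify_variants(extract_variants(profile, catalog), fx.tree)
        rec = next(r for r in recs if r.variant_id == "DYS481:RPV:2/20")
        assert rec.associated_haplogroups == {"G2a"} and rec.exclusive
        poly = next(r for r in recs if r.variant_id == "DYS481:RPV:2/23")
        assert not poly.monophyletic

    def test_empty_profile_gives_no_variants(self, catalog):
        assert extract_variants([], catalog) == []

    def test_presence_matrix_shape(self, catalog, reference_fixture):
        fx, profile = reference_fixture
        recs = extract_variants(profile, catalog)
        m = presence_matrix(recs, sorted(fx.tree.leaves))
        assert m.shape == (len(recs), 100)
        assert set(np.unique(m.values)) <= {0, 1}
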