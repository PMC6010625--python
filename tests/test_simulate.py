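"""Synthetic-data generator: determinism, conservation, recovery oracles."""

import numpy as np
import pandas as pd

from ystrmps.calling import call_read_table, calls_to_profile
from ystrmps.simulate import (
    SimulationConfig,
    place_mutations,
    simulate_dataset,
    simulate_tree,
)


def small_config(**kw):
    base = dict(n_samples=12, seed=5, snp_indel_events=4, n_duplications=1,
                n_somatic=1, depth_cv=0.0, stutter_rate=0.0)
    base.update(kw)
    return SimulationConfig(**base)


class TestTree:
    def test_two_samples_is_a_cherry(self):
        root, stree = simulate_tree(SimulationConfig(n_samples=2, seed=1))
        assert stree.n_leaves == 2
        assert root.newick().count("(") == 1

    def test_binary_tree_internal_node_count(self):
        root, stree = simulate_tree(SimulationConfig(n_samples=100, seed=1))
        internal = root.newick().count("(")
        assert stree.n_leaves == 100
        assert internal == 99

    def test_same_seed_identical_newick(self):
        a = simulate_tree(SimulationConfig(n_samples=100, seed=1))[0].newick()
        b = simulate_tree(SimulationConfig(n_samples=100, seed=1))[0].newick()
        assert a == b

    def test_haplogroups_cover_all_samples(self):
        _, stree = simulate_tree(SimulationConfig(n_samples=50, seed=3))
        assert set(stree.haplogroups) == stree.leaves
        assert len(set(stree.haplogroups.values())) >= 8


class TestPlaceMutations:
    def test_zero_rates_give_reference_alleles(self, catalog):
        cfg = small_config(slippage_rate=0.0, snp_indel_events=0)
        root, stree = simulate_tree(cfg)
        rng = np.random.default_rng(0)
        alleles, events = place_mutations(root, stree, catalog, cfg, rng)
        assert events.empty
        # every single-copy allele is the canonical reference designation
        for _, row in alleles[alleles["copy"] == 0].iterrows():
            locus = catalog[row["locus"]]
            ref = locus.reference_allele()
            from ystrmps.nomenclature import mps_name

            assert row["designation"] == mps_name(ref, locus), row["locus"]

    def test_event_carriers_are_a_clade(self, catalog):
        cfg = small_config(snp_indel_events=6, slippage_rate=0.0)
        root, stree = simulate_tree(cfg)
        rng = np.random.default_rng(11)
        _, events = place_mutations(root, stree, catalog, cfg, rng)
        snp_events = events[events["kind"] != "slippage"]
        assert len(snp_events) == 6
        for _, ev in snp_events.iterrows():
            carriers = set(ev["carriers"].split(";"))
            assert stree.is_monophyletic(carriers)
            assert stree.count_origins(carriers) == 1


class TestEmitReads:
    def test_degenerate_depth_model(self, catalog):
        cfg = small_config(depth_median=500.0, n_duplications=0, n_somatic=0,
                           snp_indel_events=0, slippage_rate=0.0)
        ds = simulate_dataset(cfg, catalog)
        per_allele = ds.reads.groupby("source_allele")["count"].sum()
        assert (per_allele == 500).all()

    def test_reads_conserve_drawn_doses(self, catalog):
        cfg = small_config(stutter_rate=0.1, depth_cv=0.15)
        ds = simulate_dataset(cfg, catalog)
        per_allele = ds.reads.groupby("source_allele")["count"].sum()
        doses = ds.doses.set_index("allele_id")["dose"]
        for aid, dose in doses.items():
            assert per_allele.get(aid, 0) == dose

    def test_stutter_fraction_binomial(self, catalog):
        cfg = small_config(n_samples=6, stutter_rate=0.1,
                           depth_median=1000.0, snp_indel_events=0,
                           slippage_rate=0.0, n_duplications=0, n_somatic=0)
        ds = simulate_dataset(cfg, catalog)
        st = ds.reads[ds.reads["is_stutter"]]["count"].sum()
        total = ds.reads["count"].sum()
        assert 0.07 < st / total < 0.13

    def test_duplication_emitted_at_two_full_doses(self, catalog):
        cfg = small_config(n_duplications=1, n_somatic=0, depth_median=800.0)
        ds = simulate_dataset(cfg, catalog)
        cell = ds.extras.iloc[0]
        sub = ds.doses[(ds.doses["sample"] == cell["sample"])
                       & (ds.doses["locus"] == cell["locus"])]
        assert len(sub) == 2
        assert (sub["dose"] == 800).all()

    def test_somatic_splits_one_dose(self, catalog):
        cfg = small_config(n_duplications=0, n_somatic=1, depth_median=800.0)
        ds = simulate_dataset(cfg, catalog)
        cell = ds.extras.iloc[0]
        sub = ds.doses[(ds.doses["sample"] == cell["sample"])
                       & (ds.doses["locus"] == cell["locus"])]
        assert len(sub) == 2
        assert sub["dose"].sum() == 800


class TestDeterminismAndRecovery:
    def test_same_seed_byte_identical_outputs(self, catalog):
        cfg = small_config(depth_cv=0.15, stutter_rate=0.1)
        a = simulate_dataset(cfg, catalog)
        b = simulate_dataset(cfg, catalog)
        assert a.newick == b.newick
        pd.testing.assert_frame_equal(a.reads, b.reads)
        pd.testing.assert_frame_equal(a.events, b.events)

    def test_noise_free_truth_recovery(self, catalog):
        """On stutter-free noise-free reads the caller reproduces the truth
        designations for 100% of alleles."""
        cfg = small_config(n_samples=10, snp_indel_events=3)
        ds = simulate_dataset(cfg, catalog)
        reads = ds.reads.groupby(["sample", "locus", "sequence"],
                                 as_index=False)["count"].sum()
        profile = calls_to_profile(call_read_table(reads, catalog))
        truth = set(map(tuple, ds.doses[["sample", "locus", "designation"]].values))
        called = set(map(tuple,
                         profile[["sample", "locus", "mps_name"]].values))
        assert called == truth
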