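"""Diversity tables, isometric groups, novelty filtering, headline counts."""

import pandas as pd
import pytest

from ystrmps.summary import (
    SummaryError,
    diversity_table,
    headline_counts,
    isometric_groups,
    load_known_catalogue,
    novelty_filter,
)


def mini_profile(rows):
    return pd.DataFrame(rows, columns=["sample", "locus", "ce_name",
                                       "length_name", "mps_name", "status"])


class TestDiversity:
    def test_single_allele_per_locus_no_increase(self):
        prof = mini_profile([
            ("s1", "DYS391", "11", "11", "CE11_TCTA[11]", "primary"),
            ("s1", "DYS458", "16", "16", "CE16_GAAA[16]", "primary"),
        ])
        df = diversity_table(prof)
        assert (df[df["locus"] != "Total"]["pct_increase"] == 0.0).all()

    def test_planted_isometric_pair_counts(self):
        prof = mini_profile([
            ("s1", "DYS635", "23", "23", "CE23_TAGA[10]TACA[2]TAGA[2]TACA[2]TAGA[2]TACA[2]TAGA[3]", "primary"),
            ("s2", "DYS635", "23", "23", "CE23_TAGA[13]TACA[2]TAGA[2]TACA[2]TAGA[4]", "primary"),
        ])
        row = diversity_table(prof).iloc[0]
        assert (row["n_length_alleles"], row["n_sequence_alleles"]) == (1, 2)
        assert row["pct_increase"] == 100.0

    def test_totals_row_conserves_column_sums(self, survey):
        df = diversity_table(survey.profile)
        body = df[df["locus"] != "Total"]
        tot = df[df["locus"] == "Total"].iloc[0]
        assert tot["n_length_alleles"] == body["n_length_alleles"].sum()
        assert tot["n_sequence_alleles"] == body["n_sequence_alleles"].sum()


class TestIsometricGroups:
    def test_planted_groups_histogram(self):
        rows = []
        # two groups of size 2, one of size 3
        for i, names in enumerate([["A1", "A2"], ["B1", "B2"], ["C1", "C2", "C3"]]):
            for j, n in enumerate(names):
                rows.append((f"s{j}", f"L{i}", "10", "10", n, "primary"))
        sizes, per_locus = isometric_groups(mini_profile(rows))
        assert sizes == {2: 2, 3: 1}
        assert sum(per_locus.values()) == 3

    def test_no_variation_empty_tally(self):
        prof = mini_profile([
            ("s1", "DYS391", "11", "11", "CE11_TCTA[11]", "primary"),
            ("s2", "DYS391", "11", "11", "CE11_TCTA[11]", "primary"),
        ])
        sizes, per_locus = isometric_groups(prof)
        assert sizes == {} and per_locus == {}

    def test_group_members_partition_distinct_alleles(self, survey):
        sizes, _ = isometric_groups(survey.profile)
        n_in_groups = sum(k * v for k, v in sizes.items())
        n_distinct = survey.profile.groupby("locus")["mps_name"].nunique().sum()
        n_singleton_lengths = sum(
            1 for _, sub in survey.profile.groupby(["locus", "length_name"])
            if sub["mps_name"].nunique() == 1)
        assert n_in_groups + n_singleton_lengths == n_distinct


class TestNovelty:
    def test_empty_catalogue_returns_everything(self, survey):
        out = novelty_filter(survey.profile, None)
        assert len(out) == survey.profile.groupby("locus")["mps_name"].nunique().sum()

    def test_self_catalogue_returns_nothing(self, survey):
        known = survey.profile[["locus", "mps_name"]].drop_duplicates().rename(
            columns={"mps_name": "designation"})
        known["match_mode"] = "exact"
        assert len(novelty_filter(survey.profile, known)) == 0

    def test_new_flank_phase_retained(self):
        prof = mini_profile([
            ("s1", "DYS643", "11", "11", "CE11_CTTTT[11]_-7A>G", "primary"),
        ])
        known = pd.DataFrame([
            {"locus": "DYS643", "designation": "CE11_CTTTT[11]", "match_mode": "exact"},
        ])
        assert len(novelty_filter(prof, known)) == 1

    def test_array_mode_wildcard_matches_any_flank_phase(self):
        prof = mini_profile([
            ("s1", "DYS643", "11", "11", "CE11_CTTTT[11]_-7A>G", "primary"),
        ])
        known = pd.DataFrame([
            {"locus": "DYS643", "designation": "CE11_CTTTT[11]", "match_mode": "array"},
        ])
        assert len(novelty_filter(prof, known)) == 0

    def test_malformed_catalogue_rejected(self, tmp_path):
        p = tmp_path / "known.tsv"
        p.write_text("locus\tdesignation\tmatch_mode\nDYS643\tCE11_CTTTT[11]\tfuzzy\n")
        with pytest.raises(SummaryError, match="line 2"):
            load_known_catalogue(p)


class TestHeadline:
    def test_single_sample_no_extras(self, catalog, survey):
        one = survey.profile[(survey.profile["sample"] == "S001")]
        hc = headline_counts(one, catalog)
        assert hc.total_alleles == 23
        assert hc.n_extra_alleles == 0

    def test_planted_snp_variants_recovered(self, catalog):
        """3 distinct SNP variants carried by 5 distinct alleles."""
        prof = mini_profile([
            ("s1", "DYS391", "8", "8", "CE8_TCTA[8]_+50C>A", "primary"),
            ("s2", "DYS391", "9", "9", "CE9_TCTA[9]_+50C>A", "primary"),
            ("s3", "DYS458", "14", "14", "CE14_GAAA[13]GGAA[1]", "primary"),
            ("s4", "DYS458", "15", "15", "CE15_GAAA[14]GGAA[1]", "primary"),
            ("s5", "DYS643", "11", "11", "CE11_CTTTT[11]_-7A>G", "primary"),
        ])
        hc = headline_counts(prof, catalog)
        assert hc.n_snp_indel_variants == 3
        assert hc.n_snp_indel_alleles == 5
        assert hc.n_snp_indel_loci == 3
        assert hc.n_snp_indel_samples == 5

    def test_survey_headline_numbers(self, catalog, survey):
        hc = headline_counts(survey.profile, catalog, known=survey.known)
        assert hc.total_alleles == 2311
        assert hc.n_samples == 100
        assert (hc.n_duplications, hc.n_somatic) == (5, 6)
        assert hc.distinct_length_alleles == 169
        assert hc.distinct_sequence_alleles == 267
        assert hc.pct_increase == 58.0
        assert hc.n_novel == 60
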