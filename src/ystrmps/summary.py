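"""Diversity, isometric-group, novelty and headline summaries of a profile.

A *profile* here is the tabular output of the calling layer (one row per
reported allele): columns sample, locus, ce_name, length_name, mps_name and
optionally depth/status. Length-based allele counts emulate what CE sees;
sequence-based counts use the full MPS designation. Isometric groups are
alleles sharing (locus, length name) but differing in designation; novelty
is assessed against a known-variant catalogue keyed by designation, with the
full designation (array plus phased flanking variants) as the comparison
unit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .catalog import Catalog
from .nomenclature import split_designation

_UNIT_TOKEN = re.compile(r"([ACGT]+|N)\[(\d+)\]")


class SummaryError(ValueError):
    pass


# --------------------------------------------------------------------------- #
# diversity (length-based vs sequence-based allele counts)
# --------------------------------------------------------------------------- #
def diversity_table(profile: pd.DataFrame,
                    known: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-locus distinct length-based and sequence-based allele counts,
    percentage increase (1 dp), optional novelty counts, plus a totals row.

    Rows are ordered by descending percentage increase; the totals row
    reports the overall increase rounded to the nearest percent.
    """
    rows = []
    novel = novelty_filter(profile, known) if known is not None else None
    for locus, sub in profile.groupby("locus", sort=True):
        n_len = sub["length_name"].nunique()
        n_seq = sub["mps_name"].nunique()
        pct = round(100.0 * (n_seq - n_len) / n_len, 1) if n_len else 0.0
        row = {"locus": locus, "n_length_alleles": n_len,
               "n_sequence_alleles": n_seq, "pct_increase": pct}
        if novel is not None:
            row["n_novel"] = novel[novel["locus"] == locus]["mps_name"].nunique()
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["pct_increase", "locus"], ascending=[False, True]).reset_index(drop=True)
    tot_len = int(df["n_length_alleles"].sum())
    tot_seq = int(df["n_sequence_alleles"].sum())
    total = {"locus": "Total", "n_length_alleles": tot_len,
             "n_sequence_alleles": tot_seq,
             "pct_increase": float(round(100.0 * (tot_seq - tot_len) / tot_len))
             if tot_len else 0.0}
    if novel is not None:
        total["n_novel"] = int(df["n_novel"].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def isometric_groups(profile: pd.DataFrame):
    """Isometric allele groups: (locus, length name) cells with >= 2 distinct
    designations. Returns (histogram of group sizes, per-locus group counts)."""
    sizes: dict[int, int] = {}
    per_locus: dict[str, int] = {}
    for (locus, _), sub in profile.groupby(["locus", "length_name"], sort=True):
        n = sub["mps_name"].nunique()
        if n >= 2:
            sizes[n] = sizes.get(n, 0) + 1
            per_locus[locus] = per_locus.get(locus, 0) + 1
    return sizes, per_locus


# --------------------------------------------------------------------------- #
# novelty filtering
# --------------------------------------------------------------------------- #
def load_known_catalogue(path) -> pd.DataFrame:
    """Known-variant catalogue TSV: columns locus, designation, optional
    match_mode ('exact' or 'array'; 'array' ignores flanking descriptors,
    matching flank-agnostic prior reports)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise SummaryError(f"cannot read known-variant catalogue {path}: {exc}") from exc
    required = {"locus", "designation"}
    if not required <= set(df.columns):
        raise SummaryError(f"known-variant catalogue needs columns {sorted(required)}")
    if "match_mode" not in df.columns:
        df["match_mode"] = "exact"
    df["match_mode"] = df["match_mode"].fillna("exact")
    for i, mode in enumerate(df["match_mode"]):
        if mode not in ("exact", "array"):
            raise SummaryError(f"known-variant catalogue line {i + 2}: bad match_mode {mode!r}")
    return df


def _array_part(designation: str) -> str:
    return split_designation(designation)[1]


def novelty_filter(profile: pd.DataFrame,
                   known: pd.DataFrame | None) -> pd.DataFrame:
    """Distinct (locus, designation) pairs in the profile that are absent
    from the known catalogue. The comparison unit is the full designation —
    an allele whose array matches a known entry but carries a new phased
    flanking variant is retained — except for 'array'-mode known entries,
    which match any designation with the same array portion."""
    distinct = profile[["locus", "mps_name"]].drop_duplicates()
    if known is None or known.empty:
        return distinct.reset_index(drop=True)
    exact = {
        (r["locus"], r["designation"])
        for _, r in known[known["match_mode"] == "exact"].iterrows()
    }
    array_mode = {
        (r["locus"], _array_part(r["designation"]))
        for _, r in known[known["match_mode"] == "array"].iterrows()
    }
    keep = []
    for _, row in distinct.iterrows():
        key = (row["locus"], row["mps_name"])
        if key in exact:
            continue
        if (row["locus"], _array_part(row["mps_name"])) in array_mode:
            continue
        keep.append(row)
    return pd.DataFrame(keep, columns=["locus", "mps_name"]).reset_index(drop=True)


# --------------------------------------------------------------------------- #
# headline counts
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class HeadlineCounts:
    total_alleles: int
    n_samples: int
    n_extra_alleles: int
    n_duplications: int
    n_somatic: int
    distinct_length_alleles: int
    distinct_sequence_alleles: int
    pct_increase: float
    n_snp_indel_variants: int
    n_snp_indel_alleles: int
    n_snp_indel_loci: int
    n_snp_indel_samples: int
    n_rpv_alleles: int
    n_novel: int | None = None


def _designation_variants(locus_name: str, designation: str, catalog: Catalog):
    """Distinct SNP/indel variant identities mentioned by a designation
    (string-level: internal non-catalogue units + flank descriptors)."""
    locus = catalog[locus_name]
    motifs = set(locus.motifs)
    _, units, descs = split_designation(designation)
    found = set()
    for m in _UNIT_TOKEN.finditer(units):
        seq, count = m.group(1), int(m.group(2))
        if seq == "N" or count == 0:
            continue
        if seq not in motifs:
            kind = "SNP" if len(seq) == locus.period else "indel"
            found.add((locus_name, "internal", seq, kind))
    for desc in descs:
        kind = "SNP" if ">" in desc and not desc.endswith(">-") and ".1->" not in desc else "indel"
        found.add((locus_name, "flanking", desc, kind))
    return found


def headline_counts(profile: pd.DataFrame, catalog: Catalog,
                    known: pd.DataFrame | None = None) -> HeadlineCounts:
    """Study-level summary: total alleles analysed, extra alleles by class,
    distinct allele counts, SNP/indel variant tallies and RPV allele count."""
    status = profile["status"] if "status" in profile.columns else pd.Series(
        ["primary"] * len(profile))
    n_dup = int((status == "duplication").sum())
    n_som = int((status == "somatic").sum())
    n_extra = n_dup + n_som + int((status == "additional").sum())

    distinct = profile[["locus", "mps_name"]].drop_duplicates()
    variant_ids = set()
    allele_has_variant = []
    for _, row in distinct.iterrows():
        vs = _designation_variants(row["locus"], row["mps_name"], catalog)
        variant_ids |= vs
        if vs:
            allele_has_variant.append((row["locus"], row["mps_name"]))
    bearing = set(allele_has_variant)
    mask = [
        (l, m) in bearing
        for l, m in zip(profile["locus"], profile["mps_name"])
    ]
    snp_samples = profile[mask]["sample"].nunique() if any(mask) else 0

    sizes, _ = isometric_groups(profile)
    # distinct sequence alleles that belong to an isometric group
    n_rpv = 0
    for (_, _), sub in profile.groupby(["locus", "length_name"], sort=False):
        n = sub["mps_name"].nunique()
        if n >= 2:
            n_rpv += n

    tot_len = profile.groupby("locus")["length_name"].nunique().sum()
    tot_seq = profile.groupby("locus")["mps_name"].nunique().sum()
    novel = None
    if known is not None:
        novel = len(novelty_filter(profile, known))
    return HeadlineCounts(
        total_alleles=len(profile),
        n_samples=profile["sample"].nunique(),
        n_extra_alleles=n_extra,
        n_duplications=n_dup,
        n_somatic=n_som,
        distinct_length_alleles=int(tot_len),
        distinct_sequence_alleles=int(tot_seq),
        pct_increase=float(round(100.0 * (tot_seq - tot_len) / tot_len))
        if tot_len else 0.0,
        n_snp_indel_variants=len(variant_ids),
        n_snp_indel_alleles=len(bearing),
        n_snp_indel_loci=len({v[0] for v in variant_ids}),
        n_snp_indel_samples=int(snp_samples),
        n_rpv_alleles=n_rpv,
        n_novel=novel,
    )
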