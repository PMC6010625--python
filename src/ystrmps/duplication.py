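"""Relative read-depth ratio test: constitutive duplication vs somatic mutation.

When a normally single-copy Y-STR shows two alleles in one sample, the two
explanations predict different read doses. The test compares stutter-adjusted
depths of the query locus against a similar-amplicon-size reference locus
amplified in the same multiplex: donor samples with single alleles at both
loci define the expected depth-ratio range for a single-dose allele; in the
query sample, two alleles whose summed ratio is about double that range
indicate a constitutive duplication, while a summed ratio within the
single-dose range indicates a somatic mutant splitting one dose. The extra
allele must not sit in the -1 stutter position (enforced upstream by the
caller's stutter masking).

The expected range is operationalised as Tukey fences (Q1 - 1.5 IQR,
Q3 + 1.5 IQR) clipped to the observed donor extremes. The verdict compares
the summed ratio against two hypotheses: the single-dose range (somatic)
and its doubling (duplication). Where the two ranges overlap — unavoidable
once depth noise widens the fences — the tie is broken at the geometric
midpoint between one and two doses (donor median x sqrt 2), the
equal-relative-distance boundary for multiplicative depth noise; a sum in
neither range is ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import Catalog

MIN_DONORS = 10
#: tie-break boundary between one and two doses, in donor-median multiples
DUPLICATION_BOUNDARY = math.sqrt(2.0)
#: approximate extra amplicon length beyond the repeat array (primers+flanks)
_AMPLICON_PAD = 120


class RatioTestError(ValueError):
    pass


class InsufficientDataError(RatioTestError):
    pass


@dataclass(frozen=True)
class RatioTestResult:
    sample: str
    locus: str
    reference_locus: str
    expected_ratio_low: float
    expected_ratio_high: float
    per_allele_ratios: tuple[float, ...]
    verdict: str  # "duplication" | "somatic" | "ambiguous"
    donor_median: float | None = None

    @property
    def summed_ratio(self) -> float:
        return float(sum(self.per_allele_ratios))


def choose_reference_locus(locus_name: str, catalog: Catalog,
                           available=None) -> str:
    """Nearest-amplicon-size single-copy companion marker in the multiplex."""
    locus = catalog[locus_name]
    size = locus.reference_array_length + _AMPLICON_PAD

    def amplicon(l):
        return l.reference_array_length + _AMPLICON_PAD

    candidates = [
        l for l in catalog
        if l.name != locus.name and l.n_copies == 1
        and (available is None or l.name in available)
    ]
    if not candidates:
        raise RatioTestError(f"no reference locus available for {locus_name}")
    return min(candidates, key=lambda l: (abs(amplicon(l) - size), l.name)).name


def donor_ratio_stats(
    locus: str,
    reference_locus: str,
    depth_table: pd.DataFrame,
    exclude_sample: str | None = None,
    min_donors: int = MIN_DONORS,
) -> tuple[float, float, float]:
    """(low fence, high fence, median) of single-dose donor depth ratios.

    ``depth_table`` columns: sample, locus, depth (stutter-adjusted), one row
    per called allele. Donors are samples (excluding the query) with exactly
    one allele at both loci; donors missing either locus are skipped.
    """
    tab = depth_table[depth_table["locus"].isin([locus, reference_locus])]
    ratios = []
    for sample, sub in tab.groupby("sample", sort=True):
        if sample == exclude_sample:
            continue
        q = sub[sub["locus"] == locus]["depth"]
        r = sub[sub["locus"] == reference_locus]["depth"]
        if len(q) == 1 and len(r) == 1 and float(r.iloc[0]) > 0:
            ratios.append(float(q.iloc[0]) / float(r.iloc[0]))
    if len(ratios) < min_donors:
        raise InsufficientDataError(
            f"{locus} vs {reference_locus}: only {len(ratios)} usable donor samples "
            f"(need >= {min_donors})")
    arr = np.asarray(ratios)
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    low = max(q1 - 1.5 * iqr, float(arr.min()))
    high = min(q3 + 1.5 * iqr, float(arr.max()))
    return float(low), float(high), float(np.median(arr))


def expected_ratio_range(
    locus: str,
    reference_locus: str,
    depth_table: pd.DataFrame,
    exclude_sample: str | None = None,
    min_donors: int = MIN_DONORS,
) -> tuple[float, float]:
    """Empirical single-dose depth-ratio interval from donor samples
    (Tukey fences clipped to the observed extremes)."""
    low, high, _ = donor_ratio_stats(
        locus, reference_locus, depth_table,
        exclude_sample=exclude_sample, min_donors=min_donors)
    return low, high


def classify_extra_allele(
    sample: str,
    locus: str,
    reference_locus: str,
    allele_depths: tuple[float, float],
    reference_depth: float,
    expected_range: tuple[float, float],
    donor_median: float | None = None,
    boundary: float = DUPLICATION_BOUNDARY,
) -> RatioTestResult:
    """Classify a two-allele observation as duplication / somatic / ambiguous.

    The summed ratio is tested against the single-dose range (somatic) and
    its doubling (duplication); in the overlap the verdict follows the
    geometric-midpoint boundary ``donor_median * boundary``.
    """
    if len(allele_depths) != 2:
        raise RatioTestError(f"{sample}/{locus}: need exactly 2 allele depths")
    if reference_depth <= 0:
        raise RatioTestError(f"{sample}/{locus}: non-positive reference depth")
    low, high = expected_range
    if low > high:
        raise RatioTestError(f"invalid expected range ({low}, {high})")
    if donor_median is None:
        donor_median = (low + high) / 2.0
    ratios = tuple(float(d) / float(reference_depth) for d in allele_depths)
    summed = sum(ratios)
    in_single = low <= summed <= high
    in_double = 2.0 * low <= summed <= 2.0 * high
    if in_single and in_double:
        verdict = "duplication" if summed >= boundary * donor_median else "somatic"
    elif in_double:
        verdict = "duplication"
    elif in_single:
        verdict = "somatic"
    else:
        verdict = "ambiguous"
    return RatioTestResult(
        sample=sample, locus=locus, reference_locus=reference_locus,
        expected_ratio_low=low, expected_ratio_high=high,
        per_allele_ratios=ratios, verdict=verdict, donor_median=donor_median,
    )


def run_duplication_test(
    depth_table: pd.DataFrame,
    catalog: Catalog,
    boundary: float = DUPLICATION_BOUNDARY,
    min_donors: int = MIN_DONORS,
) -> list[RatioTestResult]:
    """Apply the ratio test to every single-copy (sample, locus) cell showing
    exactly two alleles. ``depth_table`` columns: sample, locus, depth."""
    results = []
    available = set(depth_table["locus"].unique())
    counts = depth_table.groupby(["sample", "locus"]).size()
    for (sample, locus_name), n in counts.items():
        if n != 2 or catalog[locus_name].n_copies != 1:
            continue
        ref_name = choose_reference_locus(locus_name, catalog, available=available)
        ref_rows = depth_table[(depth_table["sample"] == sample)
                               & (depth_table["locus"] == ref_name)]
        if len(ref_rows) != 1:
            continue  # reference locus itself not single-allele in this sample
        try:
            low, high, med = donor_ratio_stats(
                locus_name, ref_name, depth_table,
                exclude_sample=sample, min_donors=min_donors)
        except InsufficientDataError:
            results.append(RatioTestResult(
                sample=str(sample), locus=str(locus_name),
                reference_locus=ref_name, expected_ratio_low=float("nan"),
                expected_ratio_high=float("nan"), per_allele_ratios=(),
                verdict="insufficient-data"))
            continue
        depths = tuple(
            float(x) for x in
            depth_table[(depth_table["sample"] == sample)
                        & (depth_table["locus"] == locus_name)]["depth"]
        )
        results.append(classify_extra_allele(
            str(sample), str(locus_name), ref_name, depths,
            float(ref_rows["depth"].iloc[0]), (low, high),
            donor_median=med, boundary=boundary))
    return results


def annotate_profile(profile: pd.DataFrame,
                     results: list[RatioTestResult]) -> pd.DataFrame:
    """Rewrite 'additional' statuses in a profile to the test verdicts."""
    profile = profile.copy()
    verdicts = {(r.sample, r.locus): r.verdict for r in results}
    for idx, row in profile.iterrows():
        v = verdicts.get((row["sample"], row["locus"]))
        if v is not None and row["status"] == "additional":
            profile.at[idx, "status"] = v
    return profile
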