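# Methods

`ystrmps` analyses forensic Y-STR amplicons at the sequence level: it parses
full-length allele sequences of the 23 PowerPlex Y23 (PPY23) loci into
repeat-block structures, derives both capillary-electrophoresis-compatible
(CE) and fully sequence-based (MPS) allele names, calls alleles from reads
under an analytical depth threshold with stutter handling, distinguishes
constitutive allele duplications from somatic mutants by relative read
depth, and classifies sequence variants as monophyletic or polyphyletic on
a sample phylogeny. This note documents the models, rules, parameters and
numerical choices.

## Locus grammars

Each locus is a declarative grammar (`data/ppy23.json`): an ordered list of
repeat blocks on the reporting strand, each with a motif (3–6 nt), a legal
copy-number range, a canonical (reference) copy number and a *counted* flag,
plus optional fixed spacers (the 42 nt insert of DYS448 and 48 nt insert of
DYS389II, written `N[42]`/`N[48]` in designations). Uncounted variable
blocks — the leading `CTG[0–2]` of DYS481, the `AAGG[5–9]` of DYS385a,b,
the trailing `TAGA[1–3]` of DYS390 and the `ccta[0–1]` of DYS19 — are
reported in designations but excluded from CE names for back-compatibility
with length-based nomenclature.

DYS385a and DYS385b share one definition on the b-copy/forward-strand
convention (commercial kits do not distinguish the copies); calls carry the
a/b-unresolved interpretation by reporting two alleles per sample, doubled
when homoallelic. The catalogue therefore holds 22 definitions covering 23
markers, and a full profile has 23 alleles per sample.

**Reference flanks are synthetic stand-ins.** The packaged upstream and
downstream flanks (60 nt) and the N-spacers are deterministic synthetic
sequences, not genomic sequence. They are constrained so that (a) the
documented reference base(s) sit at every known flanking-variant offset
(e.g. C at +50 of DYS391, the AAA at +3…+5 of DYS576), (b) no flank can
extend an adjacent repeat run (unambiguous array boundaries under maximal
extension), and (c) the 10 nt boundary anchors are unique. Genomic anchor
coordinates (GRCh38 chrY, 1-based position of the first array base) are
exact for loci with documented flanking-variant positions — the coordinate
arithmetic `pos(+k) = anchor + reference_array_length − 1 + k`,
`pos(−k) = anchor − k` reproduces all ten documented positions — and
approximate elsewhere; they feed annotation only. Consequence: the package
analyses any data generated against its own catalogue (including all
simulated and fixture data) exactly, but real MiSeq reads would require
re-deriving the flank fields from genomic sequence first.

## Repeat-array decomposition

`locate_array` finds the array between the flanks: exact unique anchor
match (10 nt, configurable) as the fast path, otherwise edit-tolerant infix
alignment of the whole reference flank (edlib), which tolerates flanking
SNPs/indels anywhere including inside the anchor region. Because alignment
alone cannot resolve co-optimal placements that trade array bases for flank
edits, the fuzzy path refines candidate boundaries (±12 nt) by requiring
the enclosed array to parse and choosing the boundary needing the fewest
flank variants.

`decompose` parses the array by greedy maximal extension with a fixed
preference order at each position: (1) extend the current block's motif,
(2) advance to the next block, (3) accept a *variant unit* — a
period-length word exactly one substitution from the current block's motif
(an internal SNP, e.g. `GGAA` inside a `GAAA` run), (4) accept a single
*partial unit* shorter than the period (an internal indel, producing
intermediate `.x` alleles; at most one per allele). The preference order is
implemented as a depth-first search with memoised failure states, so
structures in which a motif recurs out of block order (e.g.
`TCTG[1]TCTA[8]TCTG[2]TCTA[4]` at DYS437) still parse, deterministically.
Block copy-number ranges are generator/validation constraints, not parsing
constraints: an allele outside the usual range still decomposes. The parse
round-trips: re-concatenating the units always reproduces the array.

Flanking variants are called by ungapped outward comparison against the
reference flank from each array edge; on mismatch a substitution is
accepted if the following bases re-align (8 nt confirmation), otherwise a
banded indel rescue (default band 15 nt, covering the largest documented
case, a 13 bp insertion) realigns the remainder. Offsets use the ±
convention (+1 first base after the array, −1 last base before it);
insertions are left-anchored and reported as `−48.1->…` style. Calls are
annotated with rs identifiers and genomic positions from the catalogue's
known-variant table. The placement of rs368663163 (the DYS481
mobility-shift SNP) at offset −20 in the synthetic flank is itself a
stand-in; only its presence/absence drives downstream logic.

## Nomenclature

For a decomposition with effective block counts `n_b` (motif runs plus
variant units, which occupy full repeat positions):

* **CE-compatible name** `k[.r]`:
  `k = Σ_counted n_b + Σ_uncounted (n_b − canonical_b)`, `r` = total partial
  length mod period. The single shift rule reproduces all documented
  special cases: DYS385 `AAGG[5]→n−1 … AAGG[8]→n+2`, DYS481 `CTG[0]→n−1`,
  `CTG[2]→n+1`, DYS390 `TAGA[1]→−1`, `TAGA[3]→+1`, and DYS19's `a+b−1`
  when the ccta spacer is absent.
* **Length-based name**: what a CE instrument reports — computed purely
  from amplicon length (array length plus the net length of flanking
  indels) relative to the canonical reference. Isometric alleles collide on
  this name; for any allele without flanking indels it equals the
  CE-compatible name (the compatibility requirement, verified as a property
  over the legal allele space).
* **MPS designation**: `CE<length name>_<bracketed units>[_<flank
  descriptors>…]`, e.g. `CE11_CTTTT[11]_-7A>G`. The length-based prefix is
  deliberate: alleles whose electrophoretic length is shifted by a flanking
  indel print as `CE17.1_AAAG[18]_+3AAA>-` — the array says 18, CE sees
  17.1. Unicode minus in printed sources is normalised to ASCII. Zero-copy
  uncounted blocks print explicitly (`CTG[0]`); zero-copy counted blocks
  are omitted. Designations parse back to the identical decomposition by
  rendering to DNA and re-running the real pipeline.

## Allele calling

Reads for one (sample, locus) are grouped by identical decomposition.
Groups below the analytical threshold (default 20×) are dropped. A group
whose amplicon length is exactly one repeat unit below a deeper group is
masked as −1 stutter — masking is keyed on length, not exact sequence,
since the stutter of `GAAA[17]` is `GAAA[16]` whatever the rest of the
array carries — and its depth is folded into the parent's stutter-adjusted
depth. Extra alleles are therefore only reported outside the −1 position.
No other PCR-error model is applied; the threshold plus stutter rule
replaces upstream noise correction. Reads are assumed pre-oriented to the
reporting strand.

CE/MPS concordance compares per-allele length-based names with a CE
profile (alleles within a cell paired after numeric sorting) and reports
the discordance count, percentage (2 dp) and a suggested resolution per
discordance: *flanking-indel* if the sequence carries a flanking indel,
*mobility-shift-SNP* if it carries a flanking SNP (e.g. rs368663163),
otherwise *primer-difference* (or *unknown* for non-numeric names).

## Duplication vs somatic mutation

For a single-copy locus with two alleles, stutter-adjusted depths of both
alleles are divided by the depth of a reference locus of nearest amplicon
size in the multiplex. Donor samples (all others with single alleles at
both loci, ≥ 10 required) give the single-dose ratio range, operationalised
as Tukey fences (Q1 − 1.5 IQR, Q3 + 1.5 IQR) clipped to the observed
extremes — fences resist depth outliers. The summed ratio of the two query
alleles is then tested against two hypotheses: the single-dose range
(somatic: one dose split between two sequences) and its doubling
(duplication: two full doses). Where depth noise makes the two ranges
overlap, the verdict follows the geometric midpoint between one and two
doses (donor median × √2), the equal-relative-distance boundary under
multiplicative depth noise; a sum in neither range is ambiguous, and cells
with too few donors are reported as such rather than guessed. The √2
multiple is exposed as a parameter. A simple exceed-the-fence rule was
rejected because, at realistic depth dispersion (CV 15%), roughly one in
ten true duplications lands just inside the upper single-dose fence and
would be miscalled somatic; the two-range rule classifies those correctly
while leaving genuinely intermediate sums ambiguous.

## Phylogenetic classification

Variants extracted from a profile — flanking SNPs/indels, internal
variant/partial units, and repeat-pattern-variation (RPV) signatures (a
block copy-number vector that shares its array length with a different
vector at the same locus) — are binary presence/absence characters on a
rooted sample tree. Origin counts are minimum state changes under
parsimony with gains and losses allowed and the root state free, computed
by unit-cost dynamic programming over the two states (exact on
multifurcating trees); a non-empty carrier set implies at least one origin,
so the floor is 1 — this also covers the degenerate all-carriers case,
where zero changes are needed on the tree but the variant still arose once
above the root. A variant is monophyletic iff its carriers are exactly the
leaf set of one node; single-carrier variants are additionally flagged as
singletons, since one observation cannot distinguish a private mutation
from an unsampled clade. Haplogroup association reports the carrier label
set, a common superhaplogroup resolved through a packaged shorthand
hierarchy (P ⊇ Q, R; R ⊇ R1a, R1b, R2; …), and exclusivity (no non-carrier
shares the labels).

## Synthetic data

The generator emulates the study design end to end; its defaults are the
study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 100 | leaves of a random rooted binary tree (sequential random edge attachment), haplogroup labels from cutting the tree into ≥ 8 clades |
| `snp_indel_events` | 15 | rare events (flank SNP/ins/del, internal variant unit, internal partial), each placed once on one random branch — monophyletic by construction, mimicking the ~1e−8 per-generation SNP scale |
| `slippage_rate` | 0.01 per counted block per branch | ±1-unit stepwise slippage applied independently on every branch, allowing recurrence — the ~1e−3 repeat-array scale, five orders faster |
| `depth_median`, `depth_cv` | 1500, 0.15 | per-allele dose ~ lognormal, truncated to [251, 11600] (the observed per-allele coverage range) |
| `stutter_rate` | 0.10 | fraction of an allele's reads rendered with one fewer repeat in its longest counted block |
| `n_duplications`, `n_somatic` | 5, 6 | extra-allele cells among the samples: duplications emit two full doses (+2-repeat second allele), somatic mutants split one dose (fraction U(0.30, 0.45)) with a +1-repeat mutant — never at the −1 stutter position |

Every event is validated at placement time: the generator's independently
constructed truth designation must equal what the parser produces on a test
render, so the truth ledger is exact. All randomness flows through one
seeded generator; identical configurations are byte-identical. What the
simulator does **not** model: sequencing substitution errors and quality
profiles, PCR chimeras, multi-step slippage, coalescent-realistic branch
lengths, and locus-specific stutter ratios. Passing recovery tests on this
data therefore demonstrates the correctness of the decomposition, naming,
calling, dose and phylogenetic logic — not robustness to raw-instrument
noise, which upstream read QC is assumed to have handled.

Worked-example fixtures are generated programmatically: the 60 published
novel designations and the uncounted-block naming table as renderable
cases; a 100-leaf labelled phylogeny carrying the documented
variant-pattern examples (the 15-sample superhaplogroup-P DYS635 RPV, the
DYS389II CAGA[6]/CAGA[4] contrast, DYS481 CTG[0]/CTG[2], the DYS391
flanking SNP private to haplogroup B2, the DYS393 internal SNP private to
R1a); and a 100-sample, 2311-allele survey profile whose per-locus
distinct-allele counts reproduce the published diversity table exactly
(169 length-based vs 267 sequence-based alleles, 60 novel designations),
with a CE companion profile containing exactly four discordances (one
flanking-indel, one mobility-shift, two primer differences).

## Numerical and design choices

* Parsimony ties and greedy ambiguities are broken toward the catalogue's
  canonical block order; the parser is a pure function.
* The flank scanner confirms each hypothesis with up to 8 matching bases
  and requires at least one; at a flank's end an indel is only accepted if
  both sequences are exhausted together.
* Allele names sort numerically when pairing MPS against CE alleles within
  a multi-allele cell.
* Diversity percentages are per-locus 1 dp; the overall increase is
  rounded to the nearest percent. DYS385a,b is one accounting row
  contributing two alleles per sample.
* Novelty matching is exact on normalised designations (array plus phased
  flanking variants); `array`-mode catalogue entries match flank-agnostic
  prior reports. Fuzzy literature matching is out of scope.
* DYS389I and DYS389II are independent definitions with their own flanks;
  the combined-amplicon subtraction mode (one primer pair amplifying both)
  is not implemented because all supported inputs are per-locus amplicons.
* Problem sizes in the test suite (tree-oracle cases at ≤ 12 leaves,
  ≥ 1000-allele round-trip samples, 40–100-sample simulations) were chosen
  to exercise every code path at desk scale.

## Known limitations

* Synthetic flanks (above): real reads need a catalogue rebuilt from
  genomic sequence.
* One partial unit per allele; a second makes the allele unparseable (none
  is documented).
* The duplication test assumes exactly two alleles at a normally
  single-copy locus; higher copy numbers and mapping-coverage CNV
  detection are out of scope.
* Population-genetic summary statistics are deliberately absent: the
  sampling design the package mirrors maximises haplogroup diversity and
  is not a population sample.
* Haplogroup prediction from STR haplotypes is out of scope; the tree is
  an input, never inferred.
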