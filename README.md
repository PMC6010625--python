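# ystrmps

Sequence-level analysis of forensic Y-chromosomal STRs (the 23 PowerPlex
Y23 loci) from massively parallel sequencing data.

Capillary electrophoresis (CE) types an STR by fragment length alone;
sequencing reveals that alleles of identical length can differ in repeat
structure (isometric alleles / repeat pattern variation, RPV), carry SNPs
or indels inside the repeat array, or carry variants in the flanking DNA
that shift the electrophoretic length. Because Y-STRs are linked on the
non-recombining Y, every variant can also be read in the framework of a
SNP-based haplogroup phylogeny: slow-mutating SNPs/indels arise once
(monophyletic), fast-slipping repeat arrays recur (polyphyletic). This
package implements that analysis end to end for forensic geneticists and
Y-chromosome researchers:

* **Locus catalogue** — declarative repeat grammars for the 23 PPY23 loci
  (blocks, counted/uncounted status, fixed spacers, reference flanks,
  GRCh38 anchors, known flanking variants).
* **Repeat decomposition** — parse a full amplicon into bracketed repeat
  units plus internal variant/partial units and flanking SNP/indel calls.
* **Nomenclature** — CE-compatible names with the uncounted-block rules
  (`AAGG[5-9]GAAA[n]` at DYS385a,b, `CTG[0-2]CTT[n]` at DYS481,
  `TAGA[n]CAGA[o]TAGA[p]CAGA[q]TAGA[1-3]` at DYS390, `a+b−1` at DYS19),
  length-based names (what CE sees), and full MPS designations that parse
  back losslessly.
* **Allele calling** — 20× analytical threshold, −1 stutter masking with
  stutter-adjusted depths, two alleles for DYS385a,b, CE/MPS concordance
  reporting with discordance-resolution categories.
* **Duplication vs somatic test** — relative read-depth ratios against a
  similar-sized reference locus: two full doses mean a constitutive
  duplication, a split single dose means a somatic mutant.
* **Phylogenetic classification** — variants as presence/absence
  characters on a rooted sample tree: parsimony origin counts, monophyly,
  haplogroup associations (with superhaplogroup resolution).
* **Summary statistics** — length-based vs sequence-based allele
  diversity, isometric-group tallies, novelty filtering against a
  known-variant catalogue, headline counts.
* **Synthetic data** — a seeded generator producing a haplogroup-labelled
  tree, branch-placed rare SNP/indel events, recurrent block-wise
  slippage, depth/stutter read tables and injected duplication/somatic
  cells, with an exact truth ledger.

## Naming model

For an allele decomposed into blocks with effective counts *n<sub>b</sub>*
(motif runs plus internal variant units):

* CE-compatible name  *k* = Σ<sub>counted</sub> *n<sub>b</sub>* +
  Σ<sub>uncounted</sub> (*n<sub>b</sub>* − canonical<sub>b</sub>), with a
  `.r` suffix for sub-period partial units;
* length-based name = reference CE + (amplicon length − reference length)
  / period, where amplicon length includes flanking indels;
* MPS designation = `CE<length name>_<units>[_<flank descriptors>]`.

The two names coincide for every allele without flanking indels — the
back-compatibility requirement that motivates the uncounted-block rules.

## Worked example

```python
from ystrmps import load_catalog
from ystrmps.decompose import decompose, render_allele, FlankVariant
from ystrmps.nomenclature import name_allele

catalog = load_catalog()
locus = catalog["DYS458"]
seq = render_allele(locus, "GAAA" * 15 + "AA" + "GAAA" * 2)
d = decompose(seq, locus)
nm = name_allele(d, locus)
print("units: ", " ".join(f"{u.seq}[{u.count}]" for u in d.units))
print("CE name:", nm.ce, "| length-based:", nm.length_based)
print("MPS designation:", nm.mps)
```

prints

```
units:  GAAA[15] AA[1] GAAA[2]
CE name: 17.2 | length-based: 17.2
MPS designation: CE17.2_GAAA[15]AA[1]GAAA[2]
```

— a 2 nt deletion inside the array makes an intermediate ".2" allele: 17
full repeats plus a 2 nt residue. Flanking indels instead shift only what
CE sees:

```python
locus = catalog["DYS576"]
seq = render_allele(locus, "AAAG" * 18,
                    [FlankVariant(offset=3, kind="del", ref="AAA", alt="-")])
nm = name_allele(decompose(seq, locus), locus)
print("DYS576:", nm.mps, "| CE sees:", nm.length_based, "| array says:", nm.ce)
```

```
DYS576: CE17.1_AAAG[18]_+3AAA>- | CE sees: 17.1 | array says: 18
```

The 18-repeat array with a 3 bp flanking deletion migrates as a 17.1
allele — the kind of case that produces CE/MPS discordance when flanks are
ignored.

## Command line

```sh
ystrmps simulate --out run/sim --seed 1 --n-samples 100
ystrmps call      --reads run/sim/reads.tsv --out run/profile.tsv
ystrmps duptest   --profile run/profile.tsv --out run/duptest.tsv \
                  --annotated-profile run/profile_annotated.tsv
ystrmps classify  --profile run/profile.tsv --tree run/sim/tree.nwk \
                  --haplogroups run/sim/haplogroups.tsv --out run/variants.tsv
ystrmps summarize --profile run/profile_annotated.tsv --out run/summary
```

(`ystrmps all --out run` chains the stages; `ystrmps validate` schema-checks
inputs.) All intermediates are TSV; re-running with the same seed gives
byte-identical outputs.

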