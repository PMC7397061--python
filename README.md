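# privar

Case-private rare-variant discovery for small Mendelian case/control
cohorts, with a synthetic-cohort generator for fully reproducible,
desk-scale testing.

## The problem

When a handful of animals (or people) in a breed share a rare, fully
penetrant Mendelian phenotype, the standard discovery analysis is
simple set algebra over whole-genome variant calls: find the variants
that every sequenced case carries under an inheritance model and that
no control carries, annotate the survivors for protein consequence,
and weigh the remaining candidates with conservation, pedigree
segregation and a genotyped validation cohort.  `privar` implements
that analysis as a tested, reusable library for the canonical setting
of **two sequenced cases against a control panel**, as used for
dominant disorders in dog breeds — e.g. a paroxysmal
exercise-induced dyskinesia segregating in Shetland Sheepdogs, where
this strategy isolates a `PCK2` missense variant, c.1658G>A /
p.(Arg553Gln), at a strictly conserved arginine.

## The method

For a genotype matrix $G \in \{0,1,2,\cdot\}^{V \times S}$ of
alt-allele counts over variants $V$ and samples $S$ split into cases
$C$ and controls $K$, the case-exclusive set under model $m$ is

$$E_m = \{ v : \forall c \in C,\ G_{vc} = r_m \ \wedge\ \forall k \in K,\ G_{vk} = 0 \}$$

with required call $r_\text{dominant} = 1$ (all cases het) and
$r_\text{recessive} = 2$ (all cases hom-alt).  A missing case call
fails the sharing requirement; a missing control call is, by default,
not treated as evidence of carriage (policy `missing_control=ref`, a
strict `drop` mode discards such variants).  Survivors are annotated
against CDS transcript models: the affected codon is assembled across
exon boundaries (minus-strand alleles complemented), translated, and
classified (synonymous / missense / nonsense / stop-loss / start-loss
/ intronic / intergenic) with HGVS `c.`/`p.` names.  Protein-changing
survivors are ranked by an explicit linear score
(severity + conservation + optional gene-list prior), residue
conservation is the identity fraction of the alignment column over
non-gap rows, and the final evidence is a pedigree dominant-model
check plus a genotype x phenotype table with a perfect-association
predicate (every case a carrier, no control carrying).

## Worked example

`examples/` contains one short script per capability.  The core
discovery run (`examples/02_filter_case_exclusive.py`) simulates a
cohort of 2 cases and 20 controls with planted case-exclusive
variants, then recovers them by filtering alone:

```
variants scanned:            1410
case-exclusive heterozygous: 1030
case-exclusive homozygous:   36
total case-exclusive:        1066
protein-changing het:        10
protein-changing hom:        0
```

Every variant carried by a control or by only one case has been
removed; the counts equal the generator's ground truth exactly.  The
worked consequence call (`examples/03_annotate_causal_snv.py`) prints

```
codon change:     CGA -> CAA
effect class:     missense
HGVS (cDNA):      c.1658G>A
HGVS (protein):   p.(Arg553Gln)  /  p.Arg553Gln
```

i.e. the arginine at residue 553 becomes glutamine.  The full pipeline
is one call (`examples/06_full_discovery.py`) or one shell command:

```sh
privar discover --out-dir run1 --seed 7
```

which writes the filter summary, ranked candidate table, association
table, segregation verdict and a policy log as TSVs.

## Layout

- `src/privar/variants.py` — VCF 4.x I/O, multi-allelic splitting, normalization (trim + left-align)
- `src/privar/cohort.py` — case-exclusive filtering and the filter-count summary
- `src/privar/consequence.py` — CDS coordinate mapping, SNV consequence classes, HGVS naming, GFF3/BED gene models
- `src/privar/conservation.py` — residue-to-column mapping and identity conservation
- `src/privar/segregation.py` — pedigree dominant-model checks, association tables
- `src/privar/simulate.py` — synthetic cohort fixtures with ground truth
- `src/privar/prioritize.py`, `src/privar/pipeline.py`, `src/privar/cli.py` — ranking, orchestration, CLI
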