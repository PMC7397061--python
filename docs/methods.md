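# Methods

## Model and assumptions

`privar` targets the discovery setting of a rare, fully penetrant
Mendelian trait with a very small number of sequenced cases and a
panel of sequenced controls.  The filter is pure presence/absence set
algebra on diploid genotypes — no allele-frequency thresholds, call
qualities, kinship correction or population model.  That is a
deliberate mirror of how such analyses are actually run at this cohort
size: with two cases, any statistical burden machinery is meaningless,
and the discriminating power comes entirely from the control panel.
The consequences of the assumptions are explicit:

- **Shared causality.** The filter only finds variants shared by *all*
  cases.  If the cases are phenocopies with distinct causes, the true
  variant is removed by the intersection.
- **Full penetrance (dominant model).** A carrier control removes the
  variant.  The segregation checker has an `allow_nonpenetrant` escape
  hatch that downgrades unaffected-carrier violations to warnings, but
  the cohort filter itself has no such mode.
- **Autosomal diploid genotypes.** Haploid or polyploid GT fields are
  rejected on read.  Sex-chromosome records are processed under the
  same diploid rules with a logged warning that hemizygosity is not
  modeled.
- **Small variants only.** Records are normalized biallelic SNVs and
  short indels; structural variants are out of scope, and the
  consequence annotator classifies substitutions only.

## Genotype handling

Genotypes are stored as alt-allele counts (0/1/2) with a single
MISSING state (−1).  Half-called genotypes (`0/.`) are treated as
MISSING: an unobserved allele is evidence in neither direction.
Phased separators are ignored.  Two policies govern MISSING calls in
the filter:

- In a **case**, MISSING always fails the sharing requirement —
  "shared by all cases" demands an observed genotype.
- In a **control**, the default policy (`missing_control="ref"`)
  treats MISSING as non-carriage, because absence of a call is not
  evidence of carriage; the strict policy (`"drop"`) removes any
  variant with an uncalled control.  Whether a published "absent from
  controls" filter meant allele-level or call-level absence is usually
  unstated, so both policies are first-class and the active one is
  logged in every pipeline run.

Variant identity for all set operations is the normalized
`(contig, pos, ref, alt)` tuple, with coordinates 1-based inclusive
throughout.  Normalization trims shared allele bases (keeping at least
one per allele) and left-aligns indels through repeats by extending
with the reference base; it is idempotent, and the test suite checks
it against an independent whole-sequence-diff oracle.

## Consequence annotation

Transcript models are CDS interval lists in transcription order; total
CDS length must be a multiple of 3.  CDS coordinates count forward
from the CDS start on the plus strand and backward from the genomic
end on the minus strand.  For an SNV the containing codon is assembled
base-by-base across exon boundaries, minus-strand alleles are
complemented into CDS orientation, and both codons are translated with
the standard codon table (NCBI table 1, the only table currently
wired).  Classification: equal amino acids → synonymous; alt stop →
nonsense; ref stop → stop-loss; residue 1 Met lost → start-loss;
otherwise missense.  Positions inside the transcript's CDS footprint
but not in a CDS interval report `intronic`; splice-region effects are
not modeled, and indel/frameshift consequences are recognized in the
class vocabulary but not annotated (documented limitation — the
intended use case is SNV candidates).  With multiple overlapping
transcripts, each is annotated and the most severe class is reported,
ties broken by transcript id.

HGVS: `c.<pos><REF>><ALT>` with alleles in CDS orientation, and the
predicted protein form `p.(Arg553Gln)` by default, with flags for the
unparenthesized spelling and `*` vs `Ter` for stop gains (both
spellings circulate; synonymous changes render as `p.(Arg553=)`).

## Conservation

Scoring is binary identity over the alignment column holding the
reference residue: the fraction of non-gap rows matching the reference
character, with the reference row included in the denominator and gap
rows excluded.  `strictly_conserved` means fraction 1.0.  No
substitution-matrix similarity and no phylogenetic weighting: the
claim the score supports is strict conservation, and an identity
fraction stays directly interpretable.  The cost is that conservative
substitutions (Arg→Lys) count as mismatches.

## Segregation and association

The dominant-model checker collects three violation kinds: affected
non-carriers, unaffected carriers (full penetrance), and Mendelian
impossibilities given genotyped parents (gamete-set reasoning, with
untyped parents treated as unconstrained).  Unknown-phenotype
individuals never trigger phenotype violations.  The association table
tabulates genotype class by case/control status; perfect association
means no hom-ref case and no carrier control with at least one case
present.  A two-sided Fisher exact test on the carrier × phenotype 2×2
table is computed for reporting only — at these cohort shapes the
perfect-association pattern is the evidence, and no p-value is part of
any acceptance condition.

## Candidate ranking

Published prioritization among a handful of protein-changing
candidates is expert judgment about the genes.  The ranking here is
therefore an explicit linear score, not a claimed reconstruction of
that judgment:

    score = w_severity * rank + w_conservation * fraction + w_prior * [gene in list]

with severity ranks nonsense/start-loss/stop-loss = 3, missense = 2,
all else 0, default weights (1.0, 0.5, 0.0), and the knowledge prior
OFF by default.  A metabolic-gene missense candidate outranks a
stop-gain in an unrelated gene only when the user supplies a gene list
and turns the prior on — the documentation states this rather than
hiding judgment inside a formula.  Sorting is stable with a
lexicographic `(gene, contig, pos)` tie-break, so rankings are
input-order independent.

## Synthetic cohort generator

The generator emulates the *structure* of the two-case discovery
setting, not its genomics.  Defaults: 2 contigs × 500 kb of i.i.d.
uniform ACGT sequence; 10 multi-exon genes per contig in disjoint
slots (alternating strand, ATG start and TAA stop codons written in);
one designated 600-codon gene carrying a CGA arginine codon at residue
553 whose second-base G>A substitution (CDS position 1658) yields
glutamine; 2 cases and 20 controls; planted category counts 1030
het-shared / 36 hom-shared case-exclusive variants with 10 / 0
protein-changing; 300 background variants forced to have at least one
control carrier; and 2 private singletons per sample.  The planted
counts are the study-shaped discovery conditions; the 20-control panel
stands in for a much larger published panel because the filter's
output is control-count independent once every planted variant is
absent from all controls.  The 0-count protein-changing homozygous
category is realized by planting hom-shared variants only at
intergenic, intronic or synonymous sites.  Non-protein-changing plants
mix intergenic (~80%), intronic (~15%) and synonymous (~5%) sites so
the annotator is exercised on every benign class.  All loci are
collision-free by construction and every output byte is a
deterministic function of the seed.

What the generator does **not** emulate: read-level error, linkage
disequilibrium, demography, mutation-rate heterogeneity, genotype
quality, or breed structure.  Passing tests on these fixtures
demonstrate the correctness of the set algebra, coordinate arithmetic
and bookkeeping — not robustness to real-data artifacts such as
systematically miscalled regions, which enter a real analysis before
this pipeline's inputs.

The genotyping-cohort files model the validation stage: 4
heterozygous cases (three related family members and one unrelated
case) against 117 breed-matched plus 515 other-breed homozygous-
reference controls, with a PED-format family whose affected dam and
two affected offspring are het and whose unaffected members are
hom-ref.

The protein-alignment simulator writes a gapless reference row with
arginine at the target residue; other species rows diverge by random
substitution (25% of columns) and gaps (3%), with the target column
either strictly conserved or mutated in a stated number of rows.

## Numerical and policy choices

- Coordinates 1-based inclusive everywhere; any half-open arithmetic
  is private to implementations.
- VCF FILTER column ignored by default (`pass_only=True` restricts to
  PASS), since site-level filters are upstream policy.
- Records are written sorted by `(contig, pos, ref, alt)`; unsorted
  input is sorted on write with a logged notice.
- All randomness flows through `numpy.random.default_rng(seed)`;
  fixture generation and pipeline reports are byte-reproducible.
- Test problem sizes: most suites run on a reduced fixture (2 × 60 kb
  contigs, 30/6 planted counts) chosen as the smallest shape that
  still exercises multi-exon genes on both strands and every planted
  category; the acceptance suite runs the full study-shaped fixture
  once.

## Known limitations

- SNV-only consequence annotation; no splice, UTR, promoter or
  frameshift effects; no canonical-transcript selection.
- No genotype likelihoods, imputation or quality-aware filtering.
- Hemizygosity (X in males) is unmodeled; the dominant checker and
  filter treat all contigs as autosomal.
- The conservation score is column identity only and depends on the
  supplied alignment being correct; alignment construction is out of
  scope.
- With a single sequenced case, private singletons would be
  indistinguishable from shared case-exclusive variants; the generator
  therefore requires at least two cases.
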