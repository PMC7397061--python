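"""Consequence annotation of the worked causal substitution.

Builds a 560-codon forward-strand transcript whose codon 553 is CGA
(arginine) and annotates the G>A substitution at CDS position 1658:
the second base of that codon, turning CGA into CAA (glutamine).
"""

import numpy as np

from privar import TranscriptModel, VariantRecord, annotate_snv, cds_to_genomic

rng = np.random.default_rng(0)
n_codons = 560
seq = list(rng.choice(list("ACGT"), size=3 * n_codons + 500))

# one intron to show codon assembly across exon boundaries
tm = TranscriptModel(
    "tx-demo", "PCK2", "chr1", "+",
    cds_intervals=((101, 1000), (1201, 1201 + 3 * n_codons - 900 - 1)),
)
for k, base in enumerate("CGA"):             # write Arg codon 553
    seq[cds_to_genomic(tm, 552 * 3 + 1 + k) - 1] = base
reference = {"chr1": "".join(seq)}

g = cds_to_genomic(tm, 1658)
effect = annotate_snv(tm, reference, VariantRecord("chr1", g, "G", "A"))

print(f"genomic position: chr1:{g}")
print(f"CDS position:     {effect.cds_pos}")
print(f"codon change:     {effect.ref_codon} -> {effect.alt_codon}")
print(f"effect class:     {effect.effect_class.value}")
print(f"HGVS (cDNA):      {effect.c_hgvs}")
print(f"HGVS (protein):   {effect.p_hgvs()}  /  {effect.p_hgvs(parenthesized=False)}")

# Expected: missense, c.1658G>A, p.(Arg553Gln) at residue 553 — the
# arginine-to-glutamine substitution the pipeline is built to find.
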