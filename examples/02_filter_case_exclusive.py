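"""Case-exclusive filtering: the core discovery step.

Keeps variants where every case is heterozygous (dominant model) or
homozygous-alternate (recessive model) and no control carries the
alternate allele, then tabulates protein-changing survivors.
"""

import tempfile
from pathlib import Path

from privar import (
    CohortSimSpec,
    InheritanceModel,
    SampleSheet,
    TranscriptIndex,
    case_exclusive_variants,
    load_reference,
    read_gene_models,
    read_vcf,
    simulate_fixture,
    summarize_filter,
)

spec = CohortSimSpec(seed=42)  # full study-shaped counts: 1030 het / 36 hom
with tempfile.TemporaryDirectory() as tmp:
    bundle = simulate_fixture(spec, Path(tmp) / "fixture")

    sheet = SampleSheet.read_tsv(bundle.sample_sheet_tsv)
    matrix, sheet = read_vcf(bundle.cohort_vcf, sheet)
    reference = load_reference(bundle.reference_fasta)
    index = TranscriptIndex(read_gene_models(bundle.gene_models_gff3))

    survivors = {
        model: case_exclusive_variants(matrix, sheet, model)
        for model in InheritanceModel
    }
    by_key = {v.key: v for v in matrix.variants}
    effects = {
        k: index.annotate(reference, by_key[k])
        for keys in survivors.values() for k in keys
    }
    summary = summarize_filter(matrix, sheet, effects)

print(f"variants scanned:            {matrix.n_variants}")
print(f"case-exclusive heterozygous: {summary.n_het_shared}")
print(f"case-exclusive homozygous:   {summary.n_hom_shared}")
print(f"total case-exclusive:        {summary.n_case_exclusive_total}")
print(f"protein-changing het:        {summary.n_protein_changing_het}")
print(f"protein-changing hom:        {summary.n_protein_changing_hom}")

# Expected output: 1030 / 36 / 1066 and 10 / 0 — the filter recovers the
# planted counts exactly; everything carried by a control or by only one
# case has been removed.
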