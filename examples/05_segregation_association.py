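"""Pedigree segregation and cohort genotype-phenotype association.

A family with an affected dam and two affected offspring (all het) plus
unaffected hom-ref relatives is checked against a fully penetrant
autosomal dominant model; a genotyping cohort of 4 het cases vs 632
hom-ref controls is tabulated and tested for perfect association.
"""

from privar import (
    Individual,
    Pedigree,
    Sample,
    SampleSheet,
    association_table,
    carrier_exact_test,
    check_dominant_segregation,
    is_perfectly_associated,
)

pedigree = Pedigree({
    "sire": Individual("sire", sex="male", phenotype="unaffected"),
    "dam": Individual("dam", sex="female", phenotype="affected"),
    "kid1": Individual("kid1", "sire", "dam", "female", "affected"),
    "kid2": Individual("kid2", "sire", "dam", "female", "affected"),
    "kid3": Individual("kid3", "sire", "dam", "female", "unknown"),
})
genotypes = {"sire": 0, "dam": 1, "kid1": 1, "kid2": 1}
consistent, violations = check_dominant_segregation(pedigree, genotypes)
print(f"dominant-model consistent: {consistent}  (violations: {len(violations)})")

# genotyping cohort: 4 het cases, 117 breed-matched + 515 other controls
samples = [Sample(f"case{i}", "case", "Shetland Sheepdog") for i in range(4)]
samples += [Sample(f"shet{i}", "control", "Shetland Sheepdog") for i in range(117)]
samples += [Sample(f"other{i}", "control", "various") for i in range(515)]
sheet = SampleSheet(samples)
cohort_gts = {s.id: (1 if s.status == "case" else 0) for s in sheet}

table = association_table(cohort_gts, sheet)
print("\ngenotype x phenotype counts:")
print(table.to_frame().to_string())
print(f"\nperfect association: {is_perfectly_associated(table)}")
print(f"Fisher exact p (carrier x phenotype): {carrier_exact_test(table):.2e}")

# Perfect association means every case carries the allele and no control
# does; with 4 vs 632 samples the exact test is already decisive.
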