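"""Case-exclusive (private) variant filtering.

The discovery strategy for a fully penetrant Mendelian trait in a small
case cohort: keep variants at which *every* case has the genotype
required by the inheritance model (heterozygous under a dominant model,
homozygous-alternate under a recessive model) and *no* control carries
the alternate allele.  The filter is pure presence/absence — no allele
frequencies, quality thresholds or population models — and its results
shrink monotonically as cases or controls are added.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .variants import MISSING, GenotypeMatrix, SampleSheet, VariantKey

logger = logging.getLogger(__name__)


class CohortFilterError(ValueError):
    pass


class InheritanceModel(enum.Enum):
    """Zygosity required of every case sample."""

    DOMINANT_HET = "dominant_het"
    RECESSIVE_HOM = "recessive_hom"


_REQUIRED_CALL = {InheritanceModel.DOMINANT_HET: 1, InheritanceModel.RECESSIVE_HOM: 2}


@dataclass(frozen=True)
class FilterSummary:
    """Count ledger of surviving variants per filtering step and zygosity.

    ``n_case_exclusive_total`` is the union of both zygosity models; the
    two sets are disjoint by construction (a case cannot be both het and
    hom-alt at one site).
    """

    n_het_shared: int
    n_hom_shared: int
    n_protein_changing_het: int
    n_protein_changing_hom: int

    @property
    def n_case_exclusive_total(self) -> int:
        return self.n_het_shared + self.n_hom_shared

    def __post_init__(self) -> None:
        if min(self.n_het_shared, self.n_hom_shared,
               self.n_protein_changing_het, self.n_protein_changing_hom) < 0:
            raise CohortFilterError("negative count in FilterSummary")
        if self.n_protein_changing_het > self.n_het_shared:
            raise CohortFilterError("protein-changing het count exceeds het total")
        if self.n_protein_changing_hom > self.n_hom_shared:
            raise CohortFilterError("protein-changing hom count exceeds hom total")

    def to_tsv(self, path: str | Path) -> None:
        """Two-row, two-column table: filtering step x zygosity."""
        with open(path, "w") as fh:
            fh.write("filtering_step\theterozygous_variants\thomozygous_variants\n")
            fh.write(f"case_exclusive\t{self.n_het_shared}\t{self.n_hom_shared}\n")
            fh.write(
                "case_exclusive_protein_changing\t"
                f"{self.n_protein_changing_het}\t{self.n_protein_changing_hom}\n"
            )


def _cohort_columns(
    matrix: GenotypeMatrix, sheet: SampleSheet
) -> tuple[np.ndarray, np.ndarray]:
    cases = [s.id for s in sheet.cases]
    controls = [s.id for s in sheet.controls]
    unknown = [s.id for s in sheet if s.status == "unknown"]
    if not cases:
        raise CohortFilterError("sample sheet contains no case samples")
    if unknown:
        logger.info("ignoring %d unknown-status samples: %s", len(unknown), unknown)
    return matrix.sample_index(cases), matrix.sample_index(controls)


def case_exclusive_mask(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    model: InheritanceModel,
    missing_control: str = "ref",
) -> np.ndarray:
    """Boolean mask over matrix rows of case-exclusive variants.

    A variant survives when every case has exactly the model's required
    call (a missing case call always fails the sharing requirement) and
    no control carries the alternate allele.

    ``missing_control`` sets the policy for missing control genotypes:
    ``"ref"`` (default) treats a missing control call as non-carriage —
    absence of a call is not evidence of carriage; ``"drop"`` discards
    any variant with a missing control call.
    """
    if missing_control not in ("ref", "drop"):
        raise CohortFilterError(
            f"missing_control must be 'ref' or 'drop', got {missing_control!r}"
        )
    sex_contigs = {"X", "Y", "chrX", "chrY"} & {v.contig for v in matrix.variants}
    if sex_contigs:
        logger.warning(
            "sex-chromosome records (%s) are filtered under the autosomal "
            "diploid model; hemizygosity is not modeled", sorted(sex_contigs)
        )
    case_idx, control_idx = _cohort_columns(matrix, sheet)
    case_calls = matrix.calls[:, case_idx]
    control_calls = matrix.calls[:, control_idx]

    required = _REQUIRED_CALL[model]
    mask = (case_calls == required).all(axis=1)
    if missing_control == "ref":
        mask &= ((control_calls == 0) | (control_calls == MISSING)).all(axis=1)
    else:
        mask &= (control_calls == 0).all(axis=1)
    return mask


def case_exclusive_variants(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    model: InheritanceModel,
    missing_control: str = "ref",
) -> list[VariantKey]:
    """Identities of case-exclusive variants, in matrix input order."""
    mask = case_exclusive_mask(matrix, sheet, model, missing_control)
    return [matrix.variants[i].key for i in np.flatnonzero(mask)]


def summarize_filter(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    effects: Mapping[VariantKey, object],
    missing_control: str = "ref",
    protein_changing=None,
) -> FilterSummary:
    """Tabulate case-exclusive counts and their protein-changing subsets.

    ``effects`` maps every surviving variant's key to its effect class
    (anything accepted by ``protein_changing``, by default
    :func:`privar.consequence.is_protein_changing`).  A survivor without
    an effect is an error — the summary must not silently undercount.
    """
    if protein_changing is None:
        from .consequence import is_protein_changing as protein_changing

    counts = {}
    for model in InheritanceModel:
        keys = case_exclusive_variants(matrix, sheet, model, missing_control)
        n_pc = 0
        for key in keys:
            if key not in effects:
                raise CohortFilterError(
                    f"no effect annotation for surviving variant {key}"
                )
            if protein_changing(effects[key]):
                n_pc += 1
        counts[model] = (len(keys), n_pc)

    (n_het, pc_het), (n_hom, pc_hom) = (
        counts[InheritanceModel.DOMINANT_HET],
        counts[InheritanceModel.RECESSIVE_HOM],
    )
    return FilterSummary(n_het, n_hom, pc_het, pc_hom)


def write_survivors_tsv(
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    path: str | Path,
    missing_control: str = "ref",
) -> None:
    """One row per surviving variant with model label and per-sample calls."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\tmodel\t" + "\t".join(matrix.samples) + "\n")
        for model in InheritanceModel:
            mask = case_exclusive_mask(matrix, sheet, model, missing_control)
            for i in np.flatnonzero(mask):
                v = matrix.variants[i]
                calls = "\t".join(
                    "." if c == MISSING else str(int(c)) for c in matrix.calls[i]
                )
                fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{model.value}\t{calls}\n")
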