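"""Pedigree segregation checks and cohort genotype-phenotype association.

Two complementary pieces of genetic evidence for a dominant candidate
variant: (1) within the family, genotypes must be compatible with an
autosomal dominant, fully penetrant model and with Mendelian
transmission; (2) across a genotyped case/control cohort, the variant
should show a perfect association — every case a carrier, no control
carrying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .variants import MISSING, SampleSheet

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")
_CALL_TO_CLASS = {0: "hom_ref", 1: "het", 2: "hom_alt"}


class PedigreeError(ValueError):
    pass


@dataclass(frozen=True)
class Individual:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "unknown"  # male | female | unknown
    phenotype: str = "unknown"  # affected | unaffected | unknown

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise PedigreeError(f"{self.id}: bad sex {self.sex!r}")
        if self.phenotype not in ("affected", "unaffected", "unknown"):
            raise PedigreeError(f"{self.id}: bad phenotype {self.phenotype!r}")


@dataclass
class Pedigree:
    """Family structure with per-individual phenotype labels."""

    individuals: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind in self.individuals.values():
            for parent, required_sex in ((ind.sire, "male"), (ind.dam, "female")):
                if parent is None:
                    continue
                if parent not in self.individuals:
                    raise PedigreeError(
                        f"{ind.id}: parent {parent!r} not in pedigree"
                    )
                psex = self.individuals[parent].sex
                if psex not in ("unknown", required_sex):
                    raise PedigreeError(
                        f"{ind.id}: parent {parent!r} has sex {psex}, "
                        f"expected {required_sex}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: tuple[str, ...]) -> None:
            if iid in stack:
                raise PedigreeError(f"individual {iid!r} is its own ancestor")
            if state.get(iid) == 1:
                return
            ind = self.individuals[iid]
            for parent in (ind.sire, ind.dam):
                if parent is not None:
                    visit(parent, stack + (iid,))
            state[iid] = 1

        for iid in self.individuals:
            visit(iid, ())

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __len__(self) -> int:
        return len(self.individuals)

    @classmethod
    def read_ped(cls, path: str | Path) -> "Pedigree":
        """Read a PED-like TSV: family, id, sire, dam, sex, phenotype.

        ``0`` means missing parent; sex codes 1/2/0 = male/female/unknown
        (words also accepted); phenotype codes 2/1/0 = affected/
        unaffected/unknown (words also accepted).
        """
        sex_map = {"1": "male", "2": "female", "0": "unknown",
                   "male": "male", "female": "female", "unknown": "unknown"}
        phe_map = {"2": "affected", "1": "unaffected", "0": "unknown",
                   "affected": "affected", "unaffected": "unaffected",
                   "unknown": "unknown"}
        inds: dict[str, Individual] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                _fam, iid, sire, dam, sex, phe = line.rstrip("\n").split("\t")[:6]
                inds[iid] = Individual(
                    iid,
                    sire if sire != "0" else None,
                    dam if dam != "0" else None,
                    sex_map[sex.lower()],
                    phe_map[phe.lower()],
                )
        return cls(inds)

    def write_ped(self, path: str | Path, family: str = "F1") -> None:
        sex_code = {"male": "1", "female": "2", "unknown": "0"}
        phe_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
        with open(path, "w") as fh:
            for ind in self.individuals.values():
                fh.write(
                    f"{family}\t{ind.id}\t{ind.sire or 0}\t{ind.dam or 0}\t"
                    f"{sex_code[ind.sex]}\t{phe_code[ind.phenotype]}\n"
                )


@dataclass(frozen=True)
class Violation:
    individual: str
    kind: str  # affected_noncarrier | unaffected_carrier | mendelian
    detail: str


_GAMETES = {0: {0}, 1: {0, 1}, 2: {1}}


def _possible_child_counts(g_sire: int | None, g_dam: int | None) -> set[int]:
    """Alt-allele counts a child can inherit given parental genotypes.

    ``None`` stands for an ungenotyped parent (either gamete possible).
    """
    sire_g = _GAMETES[g_sire] if g_sire is not None else {0, 1}
    dam_g = _GAMETES[g_dam] if g_dam is not None else {0, 1}
    return {a + b for a in sire_g for b in dam_g}


def check_dominant_segregation(
    pedigree: Pedigree,
    genotypes: Mapping[str, int],
    allow_nonpenetrant: bool = False,
) -> tuple[bool, list[Violation]]:
    """Check genotypes against a fully penetrant autosomal dominant model.

    Violations are collected for: an affected individual carrying no
    alternate allele; an unaffected individual carrying one (downgraded
    to a logged warning with ``allow_nonpenetrant``); and any Mendelian
    impossibility given the genotyped parents (e.g. a het offspring of
    two hom-ref parents).  Unknown-phenotype individuals are never
    phenotype violations.  Ungenotyped individuals are skipped.

    Returns ``(consistent, violations)`` with ``consistent`` true iff no
    violations remain.
    """
    for iid in genotypes:
        if iid not in pedigree:
            raise PedigreeError(f"genotype given for unknown individual {iid!r}")
    clean = {i: g for i, g in genotypes.items() if g in (0, 1, 2)}

    violations: list[Violation] = []
    for iid, ind in pedigree.individuals.items():
        g = clean.get(iid)
        if g is None:
            continue
        if ind.phenotype == "affected" and g == 0:
            violations.append(
                Violation(iid, "affected_noncarrier",
                          "affected individual carries no alternate allele")
            )
        elif ind.phenotype == "unaffected" and g >= 1:
            if allow_nonpenetrant:
                logger.warning(
                    "unaffected carrier %s tolerated (non-penetrance allowed)", iid
                )
            else:
                violations.append(
                    Violation(iid, "unaffected_carrier",
                              f"unaffected individual carries {g} alternate allele(s)")
                )
        possible = _possible_child_counts(
            clean.get(ind.sire) if ind.sire else None,
            clean.get(ind.dam) if ind.dam else None,
        )
        if g not in possible:
            violations.append(
                Violation(
                    iid, "mendelian",
                    f"genotype {g} impossible for parents "
                    f"(sire={clean.get(ind.sire) if ind.sire else '?'}, "
                    f"dam={clean.get(ind.dam) if ind.dam else '?'})",
                )
            )
    return (not violations, violations)


@dataclass(frozen=True)
class AssociationTable:
    """Genotype-class x phenotype counts for one variant."""

    counts: tuple[tuple[int, int], ...]  # rows hom_ref/het/hom_alt; cols case/control

    def __post_init__(self) -> None:
        if len(self.counts) != 3 or any(len(r) != 2 for r in self.counts):
            raise PedigreeError("AssociationTable needs 3x2 counts")
        if any(c < 0 for row in self.counts for c in row):
            raise PedigreeError("negative count in AssociationTable")

    def count(self, genotype_class: str, status: str) -> int:
        i = GENOTYPE_CLASSES.index(genotype_class)
        j = ("case", "control").index(status)
        return self.counts[i][j]

    @property
    def n_cases(self) -> int:
        return sum(row[0] for row in self.counts)

    @property
    def n_controls(self) -> int:
        return sum(row[1] for row in self.counts)

    def carriers(self, status: str) -> int:
        j = ("case", "control").index(status)
        return self.counts[1][j] + self.counts[2][j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.counts), index=list(GENOTYPE_CLASSES),
            columns=["case", "control"],
        )


def association_table(
    genotypes: Mapping[str, int], sheet: SampleSheet
) -> AssociationTable:
    """Tabulate genotype classes by case/control status.

    ``genotypes`` maps sample id -> alt-allele count; every genotyped
    sample must appear in the sheet.  Unknown-status samples are
    excluded with a logged count; missing genotypes are skipped.
    """
    status_of = {s.id: s.status for s in sheet}
    counts = np.zeros((3, 2), dtype=int)
    n_unknown = 0
    for sid, g in genotypes.items():
        if sid not in status_of:
            raise PedigreeError(f"genotyped sample {sid!r} not in sample sheet")
        if g == MISSING or g is None:
            continue
        status = status_of[sid]
        if status == "unknown":
            n_unknown += 1
            continue
        counts[GENOTYPE_CLASSES.index(_CALL_TO_CLASS[g]),
               ("case", "control").index(status)] += 1
    if n_unknown:
        logger.info("association_table: excluded %d unknown-status samples", n_unknown)
    return AssociationTable(tuple(tuple(int(c) for c in row) for row in counts))


def is_perfectly_associated(table: AssociationTable) -> bool:
    """True iff every case carries >= 1 alternate allele and no control does."""
    return (
        table.n_cases > 0
        and table.count("hom_ref", "case") == 0
        and table.carriers("control") == 0
    )


def carrier_exact_test(table: AssociationTable) -> float:
    """Two-sided Fisher exact p-value on the carrier x phenotype 2x2 table.

    Provided for reporting only; the headline evidence for a private
    fully penetrant variant is the perfect-association pattern itself.
    """
    case_car, ctrl_car = table.carriers("case"), table.carriers("control")
    contingency = [
        [case_car, table.n_cases - case_car],
        [ctrl_car, table.n_controls - ctrl_car],
    ]
    return float(fisher_exact(contingency, alternative="two-sided")[1])
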