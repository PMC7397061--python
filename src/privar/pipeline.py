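"""End-to-end discovery run: filter -> annotate -> rank -> associate.

Orchestrates the individual modules behind one function,
:func:`run_discovery`, that consumes a :class:`RunConfig` and writes a
set of TSV reports: the filter-count summary, the ranked candidate
table, the genotype-phenotype association table, the pedigree
segregation verdict, and a log of every decision policy in force.
Outputs are deterministic: two runs of the same config (and seed, in
fixture mode) produce byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import cohort as _cohort
from .cohort import FilterSummary, InheritanceModel
from .consequence import (
    CodingEffect,
    TranscriptIndex,
    effect_class_of,
    is_protein_changing,
    read_gene_models,
)
from .conservation import MultipleAlignment, column_conservation
from .prioritize import CandidateRow, DEFAULT_WEIGHTS, rank_candidates, write_candidates_tsv
from .segregation import (
    Pedigree,
    association_table,
    carrier_exact_test,
    check_dominant_segregation,
    is_perfectly_associated,
)
from .simulate import CohortSimSpec, read_genotypes_tsv, simulate_fixture
from .variants import SampleSheet, load_reference, normalize_matrix, read_vcf

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


@dataclass
class RunConfig:
    """Inputs and policies of one discovery run.

    Either give the five input paths, or set ``simulate`` to have a
    fixture generated (with ``seed``) under ``out_dir/fixture`` and used
    as input.
    """

    out_dir: Path
    vcf: Path | None = None
    sample_sheet: Path | None = None
    reference: Path | None = None
    gene_models: Path | None = None
    pedigree: Path | None = None
    alignment: Path | None = None
    alignment_gene: str | None = "PCK2"
    alignment_ref_id: str = "dog"
    genotyping_sheet: Path | None = None
    genotypes: Path | None = None
    missing_control: str = "ref"
    weights: dict[str, float] = field(default_factory=dict)
    gene_list: tuple[str, ...] = ()
    allow_nonpenetrant: bool = False
    normalize: bool = True
    simulate: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML (or JSON — YAML superset) config.

        Relative paths are resolved against the config file's directory.
        """
        path = Path(path)
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        base = path.parent
        path_keys = (
            "out_dir", "vcf", "sample_sheet", "reference", "gene_models",
            "pedigree", "alignment", "genotyping_sheet", "genotypes",
        )
        for key in path_keys:
            if raw.get(key) is not None:
                raw[key] = (base / raw[key]).resolve()
        if "gene_list" in raw and raw["gene_list"] is not None:
            raw["gene_list"] = tuple(raw["gene_list"])
        return cls(**raw)

    def validate(self) -> None:
        if self.out_dir is None:
            raise PipelineError("config: out_dir is required")
        if not self.simulate:
            required = ("vcf", "sample_sheet", "reference", "gene_models")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise PipelineError(f"config: missing inputs {missing}")
            for key in ("vcf", "sample_sheet", "reference", "gene_models",
                        "pedigree", "alignment", "genotyping_sheet", "genotypes"):
                p = getattr(self, key)
                if p is not None and not Path(p).exists():
                    raise PipelineError(f"config: {key} path does not exist: {p}")


@dataclass
class RunResult:
    summary: FilterSummary
    candidates: list[CandidateRow]
    association: object | None
    perfectly_associated: bool | None
    segregation_consistent: bool | None
    outputs: dict[str, Path]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_discovery(config: RunConfig) -> RunResult:
    """Run the full discovery pipeline and write the report files."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    if config.simulate:
        bundle = simulate_fixture(
            CohortSimSpec(seed=config.seed), out / "fixture"
        )
        config.vcf = bundle.cohort_vcf
        config.sample_sheet = bundle.sample_sheet_tsv
        config.reference = bundle.reference_fasta
        config.gene_models = bundle.gene_models_gff3
        config.pedigree = config.pedigree or bundle.pedigree_ped
        config.alignment = config.alignment or bundle.alignment_fasta
        config.genotyping_sheet = config.genotyping_sheet or bundle.genotyping_sheet_tsv
        config.genotypes = config.genotypes or bundle.genotypes_tsv
        log_lines.append(f"fixture: simulated under {bundle.directory} (seed={config.seed})")

    # ---- load inputs ----
    @_stage("load")
    def load():
        sheet = SampleSheet.read_tsv(config.sample_sheet)
        matrix, sheet = read_vcf(config.vcf, sheet)
        reference = load_reference(config.reference)
        transcripts = read_gene_models(config.gene_models)
        if config.normalize:
            matrix = normalize_matrix(matrix, reference)
        return matrix, sheet, reference, transcripts

    matrix, sheet, reference, transcripts = load()
    if not sheet.cases:
        raise PipelineError("stage 'load' failed: sample sheet has no cases")
    log_lines += [
        f"input: {matrix.n_variants} variants x {matrix.n_samples} samples",
        f"cohort: {len(sheet.cases)} cases, {len(sheet.controls)} controls",
        f"policy missing_control={config.missing_control}",
        f"policy normalize={config.normalize}",
        f"policy allow_nonpenetrant={config.allow_nonpenetrant}",
    ]

    # ---- filter ----
    @_stage("filter")
    def run_filter():
        survivors = {
            model: _cohort.case_exclusive_variants(
                matrix, sheet, model, config.missing_control
            )
            for model in InheritanceModel
        }
        return survivors

    survivors = run_filter()
    for model, keys in survivors.items():
        log_lines.append(f"filter: {model.value} survivors = {len(keys)}")

    # ---- annotate ----
    @_stage("annotate")
    def annotate():
        index = TranscriptIndex(transcripts)
        by_key = {v.key: v for v in matrix.variants}
        effects = {}
        for keys in survivors.values():
            for key in keys:
                effects[key] = index.annotate(reference, by_key[key])
        return effects

    effects = annotate()
    summary = _cohort.summarize_filter(matrix, sheet, effects, config.missing_control)
    summary_path = out / "filter_summary.tsv"
    summary.to_tsv(summary_path)
    survivors_path = out / "survivors.tsv"
    _cohort.write_survivors_tsv(matrix, sheet, survivors_path, config.missing_control)
    log_lines.append(
        f"summary: total={summary.n_case_exclusive_total} "
        f"het={summary.n_het_shared} hom={summary.n_hom_shared} "
        f"pc_het={summary.n_protein_changing_het} pc_hom={summary.n_protein_changing_hom}"
    )

    # ---- conservation (optional) ----
    msa = None
    if config.alignment is not None:
        msa = MultipleAlignment.read_fasta(config.alignment)

    # ---- candidates + ranking ----
    @_stage("rank")
    def rank():
        rows = []
        for keys in survivors.values():
            for key in keys:
                eff = effects[key]
                if not isinstance(eff, CodingEffect) or not is_protein_changing(eff):
                    continue
                cons = None
                if msa is not None and eff.gene == config.alignment_gene:
                    try:
                        cons = column_conservation(
                            msa, config.alignment_ref_id, eff.residue_index
                        ).fraction_identical
                    except Exception:
                        cons = None
                rows.append(
                    CandidateRow(
                        gene=eff.gene, contig=key[0], pos=key[1],
                        ref=key[2], alt=key[3],
                        effect_class=effect_class_of(eff),
                        c_hgvs=eff.c_hgvs, p_hgvs=eff.p_hgvs(),
                        conservation=cons,
                    )
                )
        if not rows:
            return []
        return rank_candidates(rows, config.weights or None, config.gene_list)

    candidates = rank()
    candidates_path = out / "candidates.tsv"
    write_candidates_tsv(candidates, candidates_path)
    weights = dict(DEFAULT_WEIGHTS) | dict(config.weights)
    log_lines.append(
        f"rank: {len(candidates)} protein-changing candidates, weights={weights}, "
        f"gene_list={'on' if config.gene_list else 'off'}"
    )

    # ---- association (optional) ----
    assoc = None
    perfect = None
    if config.genotyping_sheet is not None and config.genotypes is not None:
        @_stage("associate")
        def associate():
            gsheet = SampleSheet.read_tsv(config.genotyping_sheet)
            gts = read_genotypes_tsv(config.genotypes)
            cohort_gts = {k: v for k, v in gts.items() if k in set(gsheet.ids)}
            table = association_table(cohort_gts, gsheet)
            return table

        assoc = associate()
        perfect = is_perfectly_associated(assoc)
        assoc_path = out / "association.tsv"
        frame = assoc.to_frame()
        frame.index.name = "genotype"
        frame.to_csv(assoc_path, sep="\t")
        log_lines.append(
            f"association: cases={assoc.n_cases} controls={assoc.n_controls} "
            f"perfect={perfect} fisher_p={carrier_exact_test(assoc):.3g}"
        )

    # ---- segregation (optional) ----
    consistent = None
    if config.pedigree is not None and config.genotypes is not None:
        @_stage("segregate")
        def segregate():
            ped = Pedigree.read_ped(config.pedigree)
            gts = read_genotypes_tsv(config.genotypes)
            ped_gts = {k: v for k, v in gts.items() if k in ped}
            return ped, check_dominant_segregation(
                ped, ped_gts, config.allow_nonpenetrant
            )

        ped, (consistent, violations) = segregate()
        seg_path = out / "segregation.tsv"
        with open(seg_path, "w") as fh:
            fh.write(f"consistent_with_autosomal_dominant\t{consistent}\n")
            for v in violations:
                fh.write(f"violation\t{v.individual}\t{v.kind}\t{v.detail}\n")
        log_lines.append(f"segregation: consistent={consistent} "
                         f"violations={len(violations)}")

    log_path = out / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")

    outputs = {
        "filter_summary": summary_path,
        "survivors": survivors_path,
        "candidates": candidates_path,
        "run_log": log_path,
    }
    if assoc is not None:
        outputs["association"] = out / "association.tsv"
    if consistent is not None:
        outputs["segregation"] = out / "segregation.tsv"

    return RunResult(
        summary=summary,
        candidates=candidates,
        association=assoc,
        perfectly_associated=perfect,
        segregation_consistent=consistent,
        outputs=outputs,
    )
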