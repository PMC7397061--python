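"""Synthetic desk-scale cohort fixtures with known ground truth.

Generates every input the discovery pipeline consumes — reference FASTA,
gene models (GFF3), multi-sample cohort VCF, sample sheet, pedigree,
genotyping-cohort files and a protein multiple alignment — together with
a truth table labelling every planted variant.  The generator emulates
the structure of a two-case whole-genome comparison against a control
panel in which a known number of case-exclusive heterozygous and
homozygous variants (a stated subset protein-changing) is planted on a
random background of control-shared variants and per-sample singletons,
with one designated causal missense variant: an arginine codon (CGA)
whose second base G>A substitution yields glutamine at a chosen residue
of a long multi-exon gene.

Everything is deterministic given the seed: the same spec produces
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consequence import (
    TranscriptModel,
    cds_to_genomic,
    write_gene_models_gff3,
    _revcomp,
    _translate_codon,
)
from .conservation import MultipleAlignment
from .variants import GenotypeMatrix, Sample, SampleSheet, VariantRecord, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_SPECIES = (
    "dog", "human", "mouse", "cattle", "chicken",
    "xenopus", "zebrafish", "drosophila", "celegans",
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class CausalVariantSpec:
    """The planted causal missense substitution.

    The generator writes a CGA (Arg) codon at ``residue_index`` of the
    designated gene and plants a G>A substitution at its second base,
    producing CAA (Gln) — hence ``cds_pos`` must sit at the second base
    of its codon.
    """

    gene: str = "PCK2"
    residue_index: int = 553
    cds_pos: int = 1658
    ref_aa: str = "Arg"
    alt_aa: str = "Gln"
    strand: str = "+"

    def __post_init__(self) -> None:
        if (self.cds_pos + 2) // 3 != self.residue_index:
            raise SimulationError(
                f"cds_pos {self.cds_pos} is not inside codon {self.residue_index}"
            )
        if (self.cds_pos - 1) % 3 != 1:
            raise SimulationError(
                "causal cds_pos must be the second base of its codon "
                "(CGA -> CAA construction)"
            )
        if (self.ref_aa, self.alt_aa) != ("Arg", "Gln"):
            raise SimulationError("causal construction realizes Arg->Gln only")
        if self.strand not in ("+", "-"):
            raise SimulationError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class CohortSimSpec:
    """Generator parameters for one fixture bundle.

    The planted category counts are the quantities the cohort filter
    must recover exactly; the background and singleton variants exist to
    be filtered away.
    """

    seed: int = 0
    contig_lengths: tuple[int, ...] = (500_000, 500_000)
    n_cases: int = 2
    n_controls: int = 20
    het_shared: int = 1030
    hom_shared: int = 36
    protein_changing_het: int = 10
    protein_changing_hom: int = 0
    background_shared: int = 300
    singletons_per_sample: int = 2
    genes_per_contig: int = 10
    causal: CausalVariantSpec = field(default_factory=CausalVariantSpec)
    # genotyping (validation) cohort
    n_genotyped_cases: int = 4
    n_breed_matched_controls: int = 117
    n_other_controls: int = 515
    msa_species: tuple[str, ...] = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise SimulationError(
                "need >= 2 cases: the sharing filter is defined on a case pair "
                "and singletons must not masquerade as shared variants"
            )
        if self.protein_changing_het > self.het_shared:
            raise SimulationError("protein_changing_het exceeds het_shared")
        if self.protein_changing_hom > self.hom_shared:
            raise SimulationError("protein_changing_hom exceeds hom_shared")
        if self.protein_changing_het < 1:
            raise SimulationError("causal variant requires protein_changing_het >= 1")
        if self.genes_per_contig < 1 or not self.contig_lengths:
            raise SimulationError("need >= 1 contig and >= 1 gene per contig")


@dataclass
class FixtureBundle:
    """Paths of one generated fixture plus its in-memory truth table."""

    directory: Path
    reference_fasta: Path
    gene_models_gff3: Path
    cohort_vcf: Path
    sample_sheet_tsv: Path
    pedigree_ped: Path
    alignment_fasta: Path
    truth_tsv: Path
    genotyping_sheet_tsv: Path
    genotypes_tsv: Path
    truth: pd.DataFrame
    transcripts: list[TranscriptModel]
    spec: CohortSimSpec


# ---------------------------------------------------------------------------
# gene placement


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Random composition of `total` into `parts` parts each >= minimum."""
    if total < parts * minimum:
        raise SimulationError(f"cannot split {total} into {parts} parts of >= {minimum}")
    extra = rng.multinomial(total - parts * minimum, [1.0 / parts] * parts)
    return [minimum + int(e) for e in extra]


def _place_genes(
    spec: CohortSimSpec, rng: np.random.Generator
) -> list[TranscriptModel]:
    """Lay out multi-exon genes in disjoint slots along each contig.

    The first gene of the first contig is the causal gene: long enough
    to host the causal residue, on the spec's strand.  Remaining genes
    alternate strand so both orientations are exercised.
    """
    models = []
    for ci, length in enumerate(spec.contig_lengths):
        contig = f"chr{ci + 1}"
        slot = length // spec.genes_per_contig
        for gi in range(spec.genes_per_contig):
            causal = ci == 0 and gi == 0
            if causal:
                n_codons = max(600, spec.causal.residue_index + 47)
                strand = spec.causal.strand
                gene = spec.causal.gene
            else:
                n_codons = int(rng.integers(100, 301))
                strand = "+" if gi % 2 == 0 else "-"
                gene = f"SYNG{ci + 1}_{gi + 1:02d}"
            n_exons = int(rng.integers(4, 8)) if causal else int(rng.integers(3, 6))
            exon_lengths = _partition(rng, 3 * n_codons, n_exons, 30)
            intron_lengths = [int(rng.integers(200, 1001)) for _ in range(n_exons - 1)]
            span = sum(exon_lengths) + sum(intron_lengths)
            margin = 1000
            if span + 2 * margin > slot:
                raise SimulationError(
                    f"contig {contig} too short for gene {gene}: slot {slot} bp, "
                    f"need >= {span + 2 * margin} bp "
                    f"(increase contig length to >= "
                    f"{(span + 2 * margin) * spec.genes_per_contig})"
                )
            start = gi * slot + margin + int(rng.integers(0, slot - span - 2 * margin + 1))
            ivs = []
            pos = start
            for k, el in enumerate(exon_lengths):
                ivs.append((pos, pos + el - 1))
                pos += el + (intron_lengths[k] if k < n_exons - 1 else 0)
            if strand == "-":
                ivs = ivs[::-1]
            models.append(
                TranscriptModel(f"tx-{gene}", gene, contig, strand, tuple(ivs))
            )
    return models


def _set_codon(
    contigs: dict[str, np.ndarray], tm: TranscriptModel, codon_index: int, codon: str
) -> None:
    """Write a codon (given in CDS orientation) into the reference."""
    for k in range(3):
        g = cds_to_genomic(tm, (codon_index - 1) * 3 + 1 + k)
        base = codon[k] if tm.strand == "+" else _revcomp(codon[k])
        contigs[tm.contig][g - 1] = base.encode()


def _read_codon(
    contigs: dict[str, np.ndarray], tm: TranscriptModel, codon_index: int
) -> str:
    out = []
    for k in range(3):
        g = cds_to_genomic(tm, (codon_index - 1) * 3 + 1 + k)
        b = contigs[tm.contig][g - 1].decode()
        out.append(b if tm.strand == "+" else _revcomp(b))
    return "".join(out)


# ---------------------------------------------------------------------------
# variant planting


@dataclass
class _Plant:
    contig: str
    pos: int
    ref: str
    alt: str
    category: str  # het_shared | hom_shared | background | singleton
    expected_class: str
    protein_changing: bool
    gene: str = ""
    owner: str = ""  # singleton owner sample


class _Planter:
    """Bookkeeping for collision-free variant placement."""

    def __init__(self, spec, rng, contigs, models):
        self.spec = spec
        self.rng = rng
        self.contigs = contigs
        self.models = models
        self.used: set[tuple[str, int]] = set()
        self.used_codons: dict[str, set[int]] = {
            tm.transcript_id: {1, tm.n_codons} for tm in models
        }
        self.spans: dict[str, list[tuple[int, int]]] = {}
        for tm in models:
            self.spans.setdefault(tm.contig, []).append(tm.span)
        self.plants: list[_Plant] = []

    def _claim(self, contig: str, pos: int) -> bool:
        if (contig, pos) in self.used:
            return False
        self.used.add((contig, pos))
        return True

    def _genomic_allele(self, tm: TranscriptModel, base: str) -> str:
        return base if tm.strand == "+" else _revcomp(base)

    def base_at(self, contig: str, pos: int) -> str:
        return self.contigs[contig][pos - 1].decode()

    # -- coding plants ------------------------------------------------

    def plant_causal(self, category: str) -> None:
        c = self.spec.causal
        tm = next(t for t in self.models if t.gene == c.gene)
        _set_codon(self.contigs, tm, c.residue_index, "CGA")
        self.used_codons[tm.transcript_id].add(c.residue_index)
        g = cds_to_genomic(tm, c.cds_pos)
        if not self._claim(tm.contig, g):
            raise SimulationError("causal locus collision (should be unreachable)")
        self.plants.append(
            _Plant(tm.contig, g, self._genomic_allele(tm, "G"),
                   self._genomic_allele(tm, "A"), category, "missense", True, tm.gene)
        )

    def plant_coding(self, category: str, want_changing: bool) -> None:
        """Plant a coding SNV that is (non-)synonymous as requested."""
        for _ in range(10_000):
            tm = self.models[int(self.rng.integers(len(self.models)))]
            codon_idx = int(self.rng.integers(2, tm.n_codons))
            if codon_idx in self.used_codons[tm.transcript_id]:
                continue
            ref_codon = _read_codon(self.contigs, tm, codon_idx)
            offsets = list(self.rng.permutation(3))
            found = None
            for off in offsets:
                alts = [b for b in "ACGT" if b != ref_codon[off]]
                self.rng.shuffle(alts)
                for alt_base in alts:
                    alt_codon = ref_codon[:off] + alt_base + ref_codon[off + 1 :]
                    ref_aa = _translate_codon(ref_codon, 1)
                    alt_aa = _translate_codon(alt_codon, 1)
                    changing = ref_aa != alt_aa
                    if changing != want_changing:
                        continue
                    if want_changing and (ref_aa == "Ter" or alt_aa == "Ter"):
                        # keep planted protein-changing variants missense so
                        # severity ranking fixtures stay predictable
                        continue
                    found = (off, alt_base, ref_aa, alt_aa)
                    break
                if found:
                    break
            if found is None:
                continue
            off, alt_base, ref_aa, alt_aa = found
            g = cds_to_genomic(tm, (codon_idx - 1) * 3 + 1 + off)
            if not self._claim(tm.contig, g):
                continue
            self.used_codons[tm.transcript_id].add(codon_idx)
            klass = "missense" if want_changing else "synonymous"
            self.plants.append(
                _Plant(tm.contig, g,
                       self._genomic_allele(tm, ref_codon[off]),
                       self._genomic_allele(tm, alt_base),
                       category, klass, want_changing, tm.gene)
            )
            return
        raise SimulationError("could not place coding variant after 10000 tries")

    # -- non-coding plants --------------------------------------------

    def _random_alt(self, ref: str) -> str:
        alts = [b for b in "ACGT" if b != ref]
        return alts[int(self.rng.integers(3))]

    def plant_intronic(self, category: str) -> None:
        for _ in range(10_000):
            tm = self.models[int(self.rng.integers(len(self.models)))]
            ivs = sorted(tm.cds_intervals)
            if len(ivs) < 2:
                continue
            k = int(self.rng.integers(len(ivs) - 1))
            lo, hi = ivs[k][1] + 1, ivs[k + 1][0] - 1
            if hi < lo:
                continue
            pos = int(self.rng.integers(lo, hi + 1))
            if not self._claim(tm.contig, pos):
                continue
            ref = self.base_at(tm.contig, pos)
            self.plants.append(
                _Plant(tm.contig, pos, ref, self._random_alt(ref),
                       category, "intronic", False, tm.gene)
            )
            return
        raise SimulationError("could not place intronic variant")

    def _in_any_gene(self, contig: str, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.spans.get(contig, ()))

    def plant_intergenic(self, category: str, anywhere: bool = False,
                         owner: str = "") -> None:
        n_contigs = len(self.spec.contig_lengths)
        for _ in range(100_000):
            ci = int(self.rng.integers(n_contigs))
            contig = f"chr{ci + 1}"
            pos = int(self.rng.integers(1, self.spec.contig_lengths[ci] + 1))
            if not anywhere and self._in_any_gene(contig, pos):
                continue
            if not self._claim(contig, pos):
                continue
            ref = self.base_at(contig, pos)
            klass = "" if anywhere else "intergenic"
            self.plants.append(
                _Plant(contig, pos, ref, self._random_alt(ref),
                       category, klass, False, owner=owner)
            )
            return
        raise SimulationError("could not place intergenic variant")


def _plant_category(planter: _Planter, rng: np.random.Generator,
                    category: str, n_total: int, n_protein_changing: int,
                    include_causal: bool) -> None:
    """Plant one case-exclusive category with its protein-changing subset.

    Non-protein-changing plants are a mix of intergenic (~80%), intronic
    (~15%) and synonymous-coding (~5%) sites so the annotator sees every
    benign class.
    """
    n_pc = n_protein_changing
    if include_causal:
        planter.plant_causal(category)
        n_pc -= 1
    for _ in range(n_pc):
        planter.plant_coding(category, want_changing=True)
    n_benign = n_total - n_protein_changing
    kinds = rng.choice(
        ["intergenic", "intronic", "synonymous"], size=n_benign,
        p=[0.80, 0.15, 0.05],
    )
    for kind in kinds:
        if kind == "intergenic":
            planter.plant_intergenic(category)
        elif kind == "intronic":
            planter.plant_intronic(category)
        else:
            planter.plant_coding(category, want_changing=False)


# ---------------------------------------------------------------------------
# cohort assembly


def _sample_sheet(spec: CohortSimSpec) -> SampleSheet:
    cases = [
        Sample(f"case_{i + 1}", "case", "Shetland Sheepdog", "F1")
        for i in range(spec.n_cases)
    ]
    controls = [
        Sample(f"ctrl_{i + 1:03d}", "control", "mixed panel")
        for i in range(spec.n_controls)
    ]
    return SampleSheet(cases + controls)


def _genotype_rows(spec: CohortSimSpec, rng: np.random.Generator,
                   plants: list[_Plant], sheet: SampleSheet) -> np.ndarray:
    n_samples = len(sheet)
    n_cases = spec.n_cases
    calls = np.zeros((len(plants), n_samples), dtype=np.int8)
    sample_index = {s.id: j for j, s in enumerate(sheet)}
    for i, p in enumerate(plants):
        if p.category == "het_shared":
            calls[i, :n_cases] = 1
        elif p.category == "hom_shared":
            calls[i, :n_cases] = 2
        elif p.category == "background":
            row = rng.choice([0, 1, 2], size=n_samples, p=[0.55, 0.30, 0.15])
            controls = row[n_cases:]
            if (controls == 0).all():
                controls[int(rng.integers(len(controls)))] = 1
                row[n_cases:] = controls
            calls[i] = row
        elif p.category == "singleton":
            calls[i, sample_index[p.owner]] = 1
        else:
            raise AssertionError(p.category)
    return calls


# ---------------------------------------------------------------------------
# pedigree + genotyping cohort (validation stage)


_PEDIGREE_ROWS = [
    # family, id, sire, dam, sex, phenotype, genotype (None = not sampled)
    ("F1", "gsire_1", "0", "0", "male", "unknown", None),
    ("F1", "gdam_1", "0", "0", "female", "unknown", None),
    ("F1", "sire_1", "0", "0", "male", "unaffected", 0),
    ("F1", "case_dam", "gsire_1", "gdam_1", "female", "affected", 1),
    ("F1", "case_sib1", "sire_1", "case_dam", "female", "affected", 1),
    ("F1", "case_sib2", "sire_1", "case_dam", "female", "affected", 1),
    ("F1", "sib_unknown", "sire_1", "case_dam", "female", "unknown", None),
    ("F2", "case_de", "0", "0", "female", "affected", 1),
]

OTHER_BREEDS = (
    "Labrador Retriever", "Border Collie", "Beagle", "Greyhound",
    "German Shepherd", "Golden Retriever", "Poodle", "Boxer",
)


def _write_pedigree(path: Path) -> dict[str, int]:
    """Write the family (three related cases + one unrelated) as PED.

    Returns the genotype map of the sampled family members.
    """
    sex_code = {"male": "1", "female": "2", "unknown": "0"}
    phe_code = {"affected": "2", "unaffected": "1", "unknown": "0"}
    genotypes = {}
    with open(path, "w") as fh:
        for fam, iid, sire, dam, sex, phe, g in _PEDIGREE_ROWS:
            fh.write(f"{fam}\t{iid}\t{sire}\t{dam}\t{sex_code[sex]}\t{phe_code[phe]}\n")
            if g is not None:
                genotypes[iid] = g
    return genotypes


def _genotyping_cohort(spec: CohortSimSpec) -> tuple[SampleSheet, dict[str, int]]:
    """The validation-stage cohort: every case het, every control hom-ref."""
    case_ids = ["case_dam", "case_sib1", "case_sib2", "case_de"][: spec.n_genotyped_cases]
    case_ids += [
        f"case_x{i}" for i in range(max(0, spec.n_genotyped_cases - len(case_ids)))
    ]
    samples = [Sample(cid, "case", "Shetland Sheepdog", "F1") for cid in case_ids]
    samples += [
        Sample(f"shet_ctrl_{i + 1:03d}", "control", "Shetland Sheepdog")
        for i in range(spec.n_breed_matched_controls)
    ]
    samples += [
        Sample(f"other_ctrl_{i + 1:03d}", "control",
               OTHER_BREEDS[i % len(OTHER_BREEDS)])
        for i in range(spec.n_other_controls)
    ]
    genotypes = {s.id: (1 if s.status == "case" else 0) for s in samples}
    return SampleSheet(samples), genotypes


# ---------------------------------------------------------------------------
# protein alignment


def simulate_msa(
    residue_index: int,
    n_species: int = 9,
    conserved: bool = True,
    n_mutated: int = 0,
    length: int | None = None,
    seed: int = 0,
    species: tuple[str, ...] = DEFAULT_SPECIES,
    ref_id: str = "dog",
) -> MultipleAlignment:
    """Simulate a protein multiple alignment around a target residue.

    The reference row is gapless; other rows diverge by random
    substitutions (25% of columns) and occasional gaps (3%).  The target
    column is strictly conserved when ``conserved``; otherwise exactly
    ``n_mutated`` non-reference rows are substituted there.
    """
    if n_species < 2:
        raise SimulationError("alignment needs >= 2 species")
    if not conserved and n_mutated >= n_species:
        raise SimulationError("cannot mutate every row including the reference")
    rng = np.random.default_rng(seed)
    length = length or residue_index + 47
    if length < residue_index:
        raise SimulationError("alignment shorter than target residue index")
    names = list(species[:n_species]) + [
        f"species_{i}" for i in range(max(0, n_species - len(species)))
    ]
    if ref_id not in names:
        names[0] = ref_id

    aa = np.array(list(_AA))
    ref_row = aa[rng.integers(len(aa), size=length)]
    ref_row[residue_index - 1] = "R"
    rows = {ref_id: "".join(ref_row)}
    others = [n for n in names if n != ref_id]
    mutated_rows = set(others[:n_mutated]) if not conserved else set()
    for name in others:
        row = ref_row.copy()
        sub = rng.random(length) < 0.25
        row[sub] = aa[rng.integers(len(aa), size=int(sub.sum()))]
        gap = rng.random(length) < 0.03
        row[gap] = "-"
        if name in mutated_rows:
            row[residue_index - 1] = "Q" if ref_row[residue_index - 1] != "Q" else "K"
        else:
            row[residue_index - 1] = ref_row[residue_index - 1]
        rows[name] = "".join(row)
    return MultipleAlignment(rows)


# ---------------------------------------------------------------------------
# top level


def simulate_fixture(spec: CohortSimSpec, outdir: str | Path) -> FixtureBundle:
    """Generate a complete fixture bundle under ``outdir``.

    Deterministic given ``spec.seed`` — identical bytes on re-run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    # reference + genes
    contigs = {
        f"chr{i + 1}": _BASES[rng.integers(4, size=length)].copy()
        for i, length in enumerate(spec.contig_lengths)
    }
    models = _place_genes(spec, rng)
    for tm in models:
        _set_codon(contigs, tm, 1, "ATG")
        _set_codon(contigs, tm, tm.n_codons, "TAA")

    # plant variants
    planter = _Planter(spec, rng, contigs, models)
    _plant_category(planter, rng, "het_shared", spec.het_shared,
                    spec.protein_changing_het, include_causal=True)
    _plant_category(planter, rng, "hom_shared", spec.hom_shared,
                    spec.protein_changing_hom, include_causal=False)
    for _ in range(spec.background_shared):
        planter.plant_intergenic("background", anywhere=True)
    sheet = _sample_sheet(spec)
    for s in sheet:
        for _ in range(spec.singletons_per_sample):
            planter.plant_intergenic("singleton", anywhere=True, owner=s.id)

    plants = sorted(planter.plants, key=lambda p: (p.contig, p.pos))
    calls = _genotype_rows(spec, rng, plants, sheet)

    # write files
    ref_path = outdir / "reference.fa"
    with open(ref_path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name].tobytes().decode()
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    gff_path = outdir / "genes.gff3"
    write_gene_models_gff3(models, gff_path)

    variants = [VariantRecord(p.contig, p.pos, p.ref, p.alt) for p in plants]
    matrix = GenotypeMatrix(variants, sheet.ids, calls)
    vcf_path = outdir / "cohort.vcf"
    write_vcf(matrix, sheet, vcf_path)

    sheet_path = outdir / "samples.tsv"
    sheet.write_tsv(sheet_path)

    ped_path = outdir / "pedigree.ped"
    _write_pedigree(ped_path)

    truth = pd.DataFrame(
        [
            {
                "contig": p.contig, "pos": p.pos, "ref": p.ref, "alt": p.alt,
                "category": p.category, "expected_class": p.expected_class,
                "protein_changing": p.protein_changing, "gene": p.gene,
                "owner": p.owner,
            }
            for p in plants
        ]
    )
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    msa = simulate_msa(
        spec.causal.residue_index,
        n_species=len(spec.msa_species),
        conserved=True,
        seed=spec.seed + 1,
        species=spec.msa_species,
    )
    msa_path = outdir / "protein_alignment.fa"
    msa.write_fasta(msa_path)

    gsheet, genotypes = _genotyping_cohort(spec)
    gsheet_path = outdir / "genotyping_samples.tsv"
    gsheet.write_tsv(gsheet_path)
    gts_path = outdir / "genotyping_genotypes.tsv"
    with open(gts_path, "w") as fh:
        fh.write("sample\talt_allele_count\n")
        for s in gsheet:
            fh.write(f"{s.id}\t{genotypes[s.id]}\n")
        # sampled family members outside the case/control cohort
        for row in _PEDIGREE_ROWS:
            iid, g = row[1], row[6]
            if g is not None and iid not in genotypes:
                fh.write(f"{iid}\t{g}\n")

    return FixtureBundle(
        directory=outdir,
        reference_fasta=ref_path,
        gene_models_gff3=gff_path,
        cohort_vcf=vcf_path,
        sample_sheet_tsv=sheet_path,
        pedigree_ped=ped_path,
        alignment_fasta=msa_path,
        truth_tsv=truth_path,
        genotyping_sheet_tsv=gsheet_path,
        genotypes_tsv=gts_path,
        truth=truth,
        transcripts=models,
        spec=spec,
    )


def read_genotypes_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column sample -> alt-allele-count TSV."""
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            sid, g = line.rstrip("\n").split("\t")[:2]
            out[sid] = int(g)
    return out
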